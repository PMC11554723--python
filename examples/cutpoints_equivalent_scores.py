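"""Distribution-free cutoffs: tolerance limits, Equivalent Scores, percentiles.

Computes the one-sided 95%/95% nonparametric tolerance ranks for a
normative sample, grades adjusted scores into ES0..ES4 and tabulates
percentiles.
"""

import numpy as np

from corsinorm import equivalent_scores, percentile_table, tolerance_ranks

ranks = tolerance_ranks(n=340, p=0.05, confidence=0.95)
print(f"n = 340: outer rank {ranks.outer_rank}, inner rank {ranks.inner_rank}")
# -> (11, 24): the 11th order statistic bounds the population 5th centile
# from below with 95% confidence; the 24th bounds it from above.

rng = np.random.default_rng(0)
adjusted = np.sort(rng.normal(5.0, 1.0, 340))  # stand-in adjusted scores
bands = equivalent_scores(adjusted, ranks)
for level, (interval, count) in enumerate(zip(bands.intervals(), bands.counts)):
    print(f"ES{level}: {interval}  ({count} participants)")
# ES0 (at or below the outer tolerance limit) is the impaired range;
# ES4 is everything above the sample median.

table = percentile_table(adjusted)
print(f"median adjusted score {np.median(adjusted):.2f} sits at percentile "
      f"{table.lookup(float(np.median(adjusted))):.1f}")
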