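"""Fit regression-based norms on a synthetic normative cohort.

Simulates a healthy cohort with the published demographic structure, then
runs the full chain — transform search, AIC model selection, coefficient
reversal, tolerance limits, Equivalent Scores, percentiles — and prints
the report.
"""

from corsinorm import HealthyCohortSpec, PipelineConfig, generate_healthy, run_pipeline

cohort = generate_healthy(HealthyCohortSpec(n=340, seed=7))
result = run_pipeline(cohort, PipelineConfig(seed=7))
print(result.report)
# The report lists, per test: the fitted model (n, R^2, AIC, omnibus p),
# the correction equation (reversed, mean-centered coefficients), the
# binomial tolerance ranks -- (11, 24) at n = 340 -- and the realized
# Equivalent-Score cutoffs (OTL = impairment cutoff, median = ES4 floor).
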