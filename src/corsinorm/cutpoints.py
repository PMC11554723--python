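"""Distribution-free cutpoints on adjusted scores.

The impairment cutoff of a regression-based norm is the *outer tolerance
limit* (OTL): a one-sided nonparametric 95% tolerance bound on the
population 5th centile, held with 95% confidence.  With ``X ~ Binomial(n,
p)`` counting sample values below the true p-th centile,

* ``outer_rank = max{ r : P(X <= r - 1) <= 1 - confidence }`` — the largest
  order statistic that lies below the p-th centile with the stated
  confidence, and
* ``inner_rank = min{ r : P(X <= r) >= confidence }`` — the smallest order
  statistic that lies above it with the stated confidence,

both from the exact binomial CDF (no normal approximation).  At n = 340,
p = 0.05, confidence 0.95 these are the 11th and 24th observations.

Adjusted scores are then graded into five rank-based Equivalent Scores:
ES0 at or below the OTL value (impaired range), ES4 above the sample
median, and ES1-ES3 splitting the ranks in between into three contiguous
equal-count bands (remainders to the lower bands).  Percentile ranks use
the Hazen convention ``100 * (rank - 0.5) / n`` with mean ranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy import stats

from .errors import DegenerateDistributionError, SampleTooSmallError

__all__ = [
    "ToleranceRanks",
    "ESBands",
    "PercentileTable",
    "CutpointSet",
    "tolerance_ranks",
    "equivalent_scores",
    "percentile_table",
]


@dataclass(frozen=True)
class ToleranceRanks:
    """Order-statistic ranks bracketing the population p-th centile."""

    n: int
    outer_rank: int
    inner_rank: int
    p: float = 0.05
    confidence: float = 0.95

    def __post_init__(self):
        if not 1 <= self.outer_rank < self.inner_rank <= self.n:
            raise ValueError(
                f"ranks ({self.outer_rank}, {self.inner_rank}) invalid for n={self.n}"
            )


def tolerance_ranks(n: int, p: float = 0.05, confidence: float = 0.95) -> ToleranceRanks:
    """Exact binomial one-sided tolerance-limit ranks for the p-th centile."""
    if not 0 < p < 1 or not 0 < confidence < 1:
        raise ValueError("p and confidence must lie in (0, 1)")
    cdf = stats.binom.cdf(np.arange(n + 1), n, p)  # cdf[k] = P(X <= k)
    outer_candidates = np.nonzero(cdf[:-1] <= 1.0 - confidence)[0]  # r-1 values
    if outer_candidates.size == 0:
        raise SampleTooSmallError(
            f"n={n} too small for a {confidence:.0%}-confidence bound on the "
            f"{p:.0%} centile (requires (1-p)^n <= 1-confidence)"
        )
    outer = int(outer_candidates.max()) + 1
    inner = int(np.nonzero(cdf >= confidence)[0].min())
    inner = max(inner, 1)
    return ToleranceRanks(n=n, outer_rank=outer, inner_rank=inner, p=p, confidence=confidence)


@dataclass
class ESBands:
    """Equivalent-Score bands realized on a normative sample.

    ``cutoffs = (otl, es1_upper, es2_upper, median)`` partition the line into
    ES0: (-inf, otl], ES1: (otl, es1], ES2: (es1, es2], ES3: (es2, median],
    ES4: (median, inf).  All boundaries are order statistics of the sample.
    For tests where lower scores are better set ``higher_is_better=False``;
    boundaries are then on the internally negated scale.
    """

    cutoffs: tuple
    otl_value: float
    itl_value: float
    median: float
    counts: tuple
    higher_is_better: bool = True

    def assign(self, score: float) -> int:
        s = score if self.higher_is_better else -score
        for level, bound in enumerate(self.cutoffs):
            if s <= bound:
                return level
        return 4

    def intervals(self) -> list:
        """Human-readable half-open band intervals, ES0..ES4."""
        c = self.cutoffs
        return [
            f"<= {c[0]:g}",
            f"({c[0]:g}, {c[1]:g}]",
            f"({c[1]:g}, {c[2]:g}]",
            f"({c[2]:g}, {c[3]:g}]",
            f"> {c[3]:g}",
        ]


def equivalent_scores(
    adjusted, ranks: ToleranceRanks, higher_is_better: bool = True
) -> ESBands:
    """Grade a normative sample of adjusted scores into ES0..ES4 bands.

    ES0 holds the values at or below the outer-rank order statistic, ES4 the
    values strictly above the median, and the ranks in between split into
    three contiguous bands as equal in count as possible (remainders going
    to the lower bands).  Ties at the OTL boundary fall into ES0.
    """
    x = np.asarray(adjusted, dtype=float)
    if x.size != ranks.n:
        raise ValueError(f"sample size {x.size} does not match ranks.n={ranks.n}")
    if np.ptp(x) == 0:
        raise DegenerateDistributionError("all adjusted scores identical")
    if not higher_is_better:
        x = -x
    xs = np.sort(x)
    otl = float(xs[ranks.outer_rank - 1])
    itl = float(xs[ranks.inner_rank - 1])
    med = float(np.median(xs))
    middle = xs[(xs > otl) & (xs <= med)]
    m = middle.size
    base, rem = divmod(m, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    b1 = float(middle[sizes[0] - 1]) if sizes[0] else otl
    b2 = float(middle[sizes[0] + sizes[1] - 1]) if sizes[1] else b1
    counts = (
        int((xs <= otl).sum()),
        sizes[0],
        sizes[1],
        sizes[2],
        int((xs > med).sum()),
    )
    return ESBands(
        cutoffs=(otl, b1, b2, med),
        otl_value=otl,
        itl_value=itl,
        median=med,
        counts=counts,
        higher_is_better=higher_is_better,
    )


@dataclass
class PercentileTable:
    """Non-decreasing mapping from adjusted score to percentile rank."""

    scores: np.ndarray
    percentiles: np.ndarray
    convention: str = "hazen"

    def lookup(self, score: float) -> float:
        """Percentile of an observed score; unseen scores take the percentile
        of the largest tabulated score not exceeding them (0 below the min)."""
        idx = np.searchsorted(self.scores, score, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.percentiles[idx])

    def as_dict(self) -> dict:
        return {float(s): float(p) for s, p in zip(self.scores, self.percentiles)}


def percentile_table(adjusted, convention: str = "hazen") -> PercentileTable:
    """Percentile ranks of each distinct adjusted score.

    ``hazen`` (default): ``100 * (rank - 0.5) / n`` with tied observations
    sharing their mean rank.  ``weibull`` (``100 * rank / (n + 1)``) and
    ``ecdf`` (``100 * rank / n``) are provided as alternatives.
    """
    x = np.asarray(adjusted, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    r = stats.rankdata(x, method="average")
    n = x.size
    if convention == "hazen":
        pct = 100.0 * (r - 0.5) / n
    elif convention == "weibull":
        pct = 100.0 * r / (n + 1)
    elif convention == "ecdf":
        pct = 100.0 * r / n
    else:
        raise ValueError(f"unknown percentile convention {convention!r}")
    order = np.argsort(x, kind="stable")
    xs, ps = x[order], pct[order]
    uniq, first = np.unique(xs, return_index=True)
    return PercentileTable(scores=uniq, percentiles=ps[first], convention=convention)


@dataclass
class CutpointSet:
    """The cutpoint artifacts of one test: ranks, ES bands, percentiles."""

    test: str
    ranks: ToleranceRanks
    bands: ESBands
    percentiles: PercentileTable
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "n": self.ranks.n,
            "p": self.ranks.p,
            "confidence": self.ranks.confidence,
            "outer_rank": self.ranks.outer_rank,
            "inner_rank": self.ranks.inner_rank,
            "otl_value": self.bands.otl_value,
            "itl_value": self.bands.itl_value,
            "median": self.bands.median,
            "es_cutoffs": list(self.bands.cutoffs),
            "es_counts": list(self.bands.counts),
            "higher_is_better": self.bands.higher_is_better,
            "percentile_convention": self.percentiles.convention,
            "percentiles": self.percentiles.as_dict(),
            **({"metadata": self.metadata} if self.metadata else {}),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutpointSet":
        ranks = ToleranceRanks(
            n=int(d["n"]),
            outer_rank=int(d["outer_rank"]),
            inner_rank=int(d["inner_rank"]),
            p=float(d["p"]),
            confidence=float(d["confidence"]),
        )
        cut = d["es_cutoffs"]
        bands = ESBands(
            cutoffs=tuple(cut),
            otl_value=float(d["otl_value"]),
            itl_value=float(d["itl_value"]),
            median=float(d["median"]),
            counts=tuple(d["es_counts"]),
            higher_is_better=bool(d["higher_is_better"]),
        )
        pct_map = {float(k): float(v) for k, v in d["percentiles"].items()}
        scores = np.array(sorted(pct_map))
        table = PercentileTable(
            scores=scores,
            percentiles=np.array([pct_map[s] for s in scores]),
            convention=d.get("percentile_convention", "hazen"),
        )
        return cls(
            test=d["test"],
            ranks=ranks,
            bands=bands,
            percentiles=table,
            metadata=d.get("metadata", {}),
        )
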