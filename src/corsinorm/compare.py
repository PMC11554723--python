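"""Comparing normative systems on a common cohort.

A *normative system* bundles a demographic adjustment (a correction
equation, or a legacy stratified cutoff table) with an impairment rule — a
threshold on the adjusted score, conventionally the outer tolerance limit
(ES0 boundary).  Two systems are compared by classifying the same cohort
and summarizing agreement (accuracy, Cohen's kappa, a 2x2 confusion
matrix) and discrimination against a ground truth (rank-based AUC).

Legacy supraspan norms only cover spans 4-6, so participants with spans
outside a system's applicable range are excluded from its classification
and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EmptyComparisonError, UndefinedAUCError, ValidationError
from .norming import CorrectionEquation

__all__ = [
    "NormativeSystem",
    "ClassificationResult",
    "ConfusionMatrix",
    "AgreementReport",
    "classify",
    "agreement_metrics",
    "auc",
]


@dataclass
class NormativeSystem:
    """An adjustment rule plus an impairment threshold on the adjusted score.

    Exactly one of ``equation`` (regression adjustment with a single
    ``cutoff``) or ``span_cutoffs`` (legacy table: span -> cutoff on the raw
    or legacy-adjusted score) should be provided.  ``applicable_span_range``
    restricts which spans the system covers (legacy CSSL norms: 4-6).
    Scores at or below the threshold count as impaired.
    """

    name: str
    equation: Optional[CorrectionEquation] = None
    cutoff: Optional[float] = None
    span_cutoffs: Optional[dict] = None
    applicable_span_range: Optional[tuple] = None

    def __post_init__(self):
        if self.equation is not None and self.cutoff is None:
            raise ValueError(f"system {self.name!r}: equation given without a cutoff")
        if self.equation is None and not self.span_cutoffs:
            raise ValueError(f"system {self.name!r}: neither equation nor span cutoffs")


@dataclass
class ClassificationResult:
    """Impairment labels on the covered subset, plus the excluded rows."""

    labels: pd.Series  # boolean, indexed like the covered cohort rows
    adjusted: pd.Series
    excluded: pd.Index

    @property
    def n_classified(self) -> int:
        return int(len(self.labels))


_SCORE_COLUMNS = {"cs": "cs_raw", "cssl": "cssl_raw", "cssr": "cssr_raw"}


def classify(cohort: pd.DataFrame, system: NormativeSystem, test: str) -> ClassificationResult:
    """Label each covered participant impaired/not under a normative system."""
    col = _SCORE_COLUMNS.get(test, test)
    needed = {col, "age", "education"}
    missing = needed - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort missing columns: {sorted(missing)}")
    spans = cohort["cs_raw"] if "cs_raw" in cohort.columns else None
    mask = pd.Series(True, index=cohort.index)
    if system.applicable_span_range is not None:
        if spans is None:
            raise ValidationError("span range restriction requires a cs_raw column")
        lo, hi = system.applicable_span_range
        mask = (spans >= lo) & (spans <= hi)
    covered = cohort.loc[mask]
    excluded = cohort.index[~mask]
    raw = covered[col].astype(float)
    if system.equation is not None:
        frame = covered.rename(columns={"cs_raw": "span"})
        adjusted = raw + system.equation.correction_array(frame)
        labels = adjusted <= system.cutoff
    else:
        adjusted = raw
        cutoffs = covered["cs_raw"].map(
            lambda s: system.span_cutoffs.get(int(s), np.nan)
        )
        if cutoffs.isna().any():
            bad = covered.loc[cutoffs.isna(), "cs_raw"].unique()
            raise ValidationError(
                f"system {system.name!r} has no cutoff for span(s) {sorted(bad)}"
            )
        labels = adjusted <= cutoffs.astype(float)
    return ClassificationResult(
        labels=labels, adjusted=pd.Series(adjusted, index=covered.index), excluded=excluded
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 agreement counts; 'positive' means labeled impaired."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementReport:
    accuracy: float
    kappa: float
    confusion: ConfusionMatrix


def agreement_metrics(labels_a, labels_b) -> AgreementReport:
    """Accuracy and Cohen's kappa between two binary classifications.

    ``labels_a`` is taken as the reference for the confusion-matrix naming
    (tp = both positive).  kappa = (po - pe) / (1 - pe) with the expected
    agreement pe computed from the marginals; if both raters are constant
    and identical, kappa is defined as 1.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.size != b.size:
        raise ValueError("label vectors differ in length")
    if a.size == 0:
        raise EmptyComparisonError("no overlapping participants to compare")
    n = a.size
    tp = int(np.sum(a & b))
    fp = int(np.sum(~a & b))
    fn = int(np.sum(a & ~b))
    tn = int(np.sum(~a & ~b))
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return AgreementReport(
        accuracy=po, kappa=float(kappa), confusion=ConfusionMatrix(tp, fp, fn, tn)
    )


def auc(scores, truth) -> float:
    """Rank-based (Mann-Whitney) AUC of adjusted scores against impairment.

    Oriented so that *lower* scores indicate impairment: the returned value
    is the probability that a randomly chosen impaired participant scores
    below a randomly chosen unimpaired one, ties counting half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both impaired and unimpaired cases required")
    r = rankdata(s)  # average ranks -> half credit for ties
    # sum of impaired ranks, low scores (low ranks) = impairment
    u = r[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(1.0 - u / (n_pos * n_neg))
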