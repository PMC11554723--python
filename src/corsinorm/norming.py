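"""Regression-based derivation of demographic correction equations.

The norming procedure works in three steps, all on ordinary least squares:

1. **Transformation search** — for each demographic predictor, bivariate
   regressions of the raw score on each candidate re-expression (identity,
   natural log, square root, reciprocal) are compared by AIC and the lowest
   wins.
2. **Model selection** — every non-empty subset of the candidate predictors
   (in their selected transformations) is fitted; among the models whose
   omnibus F test is significant at p < 0.05 the one with the lowest AIC is
   selected.  Ties break toward fewer predictors, then listed order.
3. **Coefficient reversal** — the selected model is refitted on deviations
   of each transformed predictor (and of the score) from its sample mean;
   negating the slopes yields the *correction equation*

   ``adjusted = raw + sum_j c_j * (T_j(x_j) - m_j)``

   which by construction corrects the average participant by zero.

AIC here is ``2k - 2 loglik`` with the full Gaussian log-likelihood and the
error variance counted in ``k``.  Only AIC differences matter for selection,
so conventions that drop additive constants rank models identically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    DivergenceError,
    EmptyFamilyError,
    NoSignificantModelError,
)
from .transforms import TransformSpec, admissible, family

__all__ = [
    "aic",
    "gaussian_loglik",
    "search_transform",
    "select_model",
    "derive_correction_equation",
    "required_sample_size",
    "CandidateModel",
    "CorrectionEquation",
    "CorrectionTerm",
    "PowerSpec",
]


def gaussian_loglik(residuals: np.ndarray) -> float:
    """Gaussian log-likelihood at the MLE variance, constants included."""
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    sigma2 = float(np.mean(residuals**2))
    if sigma2 <= 0:
        # perfect fit: the Gaussian likelihood diverges; represent as +inf
        return math.inf
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, ``2k - 2 loglik``."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return 2.0 * n_params - 2.0 * loglik


def _ols(y: np.ndarray, X: np.ndarray):
    """Least-squares fit with intercept prepended; returns (beta, fitted, resid)."""
    Xd = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta
    return beta, fitted, y - fitted


def _fit_stats(y: np.ndarray, X: np.ndarray):
    """OLS fit summary: beta, aic (variance counted), omnibus F p, R^2."""
    n = len(y)
    k_pred = X.shape[1] if X.ndim == 2 else 1
    beta, fitted, resid = _ols(y, X)
    ll = gaussian_loglik(resid)
    model_aic = aic(ll, k_pred + 2)  # slopes + intercept + error variance
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_num, df_den = k_pred, n - k_pred - 1
    if df_den <= 0:
        raise DegenerateDesignError("not enough observations for the requested model")
    if ss_res <= 0:
        p = 0.0
    else:
        f_stat = (ss_tot - ss_res) / df_num / (ss_res / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return beta, model_aic, p, r2


def search_transform(
    data: pd.DataFrame,
    dependent: str,
    predictor: str,
    family_names: Sequence[str] = family(),
) -> TransformSpec:
    """Pick the transform of ``predictor`` whose bivariate OLS fit of
    ``dependent`` has the lowest AIC.

    Transforms whose domain excludes any observed predictor value are
    skipped.  The returned spec carries the sample mean of the transformed
    predictor as its centering constant.  Ties break in family order.
    """
    sub = data[[dependent, predictor]].dropna()
    if len(sub) < 10:
        raise DegenerateDesignError(
            f"need >= 10 complete rows for transform search, got {len(sub)}"
        )
    y = sub[dependent].to_numpy(float)
    x = sub[predictor].to_numpy(float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"predictor {predictor!r} is constant")
    best = None
    for name in family(family_names):
        if not admissible(name, x):
            continue
        spec = TransformSpec(name).centered(x)
        _, model_aic, _, _ = _fit_stats(y, spec.apply(x).reshape(-1, 1))
        if best is None or model_aic < best[0] - 1e-12:
            best = (model_aic, spec)
    if best is None:
        raise EmptyFamilyError(
            f"no admissible transform for {predictor!r} among {list(family_names)}"
        )
    return best[1]


@dataclass
class CandidateModel:
    """A fitted OLS model of a raw score on transformed demographics."""

    dependent: str
    predictors: dict  # name -> TransformSpec (with centering constants)
    coefficients: dict  # 'intercept' + predictor names -> float
    aic: float
    omnibus_p: float
    r_squared: float
    n: int


def _design(data: pd.DataFrame, predictors: dict) -> np.ndarray:
    cols = [spec.apply(data[name].to_numpy(float)) for name, spec in predictors.items()]
    return np.column_stack(cols) if cols else np.empty((len(data), 0))


def select_model(
    data: pd.DataFrame,
    dependent: str,
    predictors: dict,
    alpha: float = 0.05,
    max_predictors: int = 4,
) -> CandidateModel:
    """Exhaustive best-subset selection by AIC with an omnibus significance gate.

    ``predictors`` maps candidate names to their chosen :class:`TransformSpec`.
    All non-empty subsets of up to ``max_predictors`` predictors are fitted;
    the lowest-AIC subset whose omnibus F-test p-value is below ``alpha``
    wins.  Subsets are enumerated smallest-first in listed order, and a
    strictly-lower-AIC rule makes ties resolve toward parsimony.
    """
    if not predictors:
        raise ValueError("at least one candidate predictor required")
    names = list(predictors)
    sub = data[[dependent] + names].dropna()
    y = sub[dependent].to_numpy(float)
    best = None
    for size in range(1, min(max_predictors, len(names)) + 1):
        for combo in itertools.combinations(names, size):
            chosen = {n: predictors[n].centered(sub[n].to_numpy(float)) for n in combo}
            X = _design(sub, chosen)
            try:
                beta, model_aic, p, r2 = _fit_stats(y, X)
            except DegenerateDesignError:
                continue
            if p >= alpha:
                continue
            if best is None or model_aic < best.aic - 1e-12:
                coeffs = {"intercept": float(beta[0])}
                coeffs.update({n: float(b) for n, b in zip(combo, beta[1:])})
                best = CandidateModel(
                    dependent=dependent,
                    predictors=chosen,
                    coefficients=coeffs,
                    aic=model_aic,
                    omnibus_p=p,
                    r_squared=r2,
                    n=len(sub),
                )
    if best is None:
        raise NoSignificantModelError(
            f"no predictor subset for {dependent!r} is significant at p < {alpha}"
        )
    return best


@dataclass(frozen=True)
class CorrectionTerm:
    """One covariate term ``coefficient * (T(x) - centering)`` of a correction."""

    variable: str
    transform: TransformSpec
    coefficient: float

    def evaluate(self, value):
        return self.coefficient * self.transform.deviation(value)


@dataclass
class CorrectionEquation:
    """The portable artifact of norming: reversed, mean-centered coefficients.

    ``correction(x) = sum_j c_j * (T_j(x_j) - m_j)``; adding it to the raw
    score yields the demographically adjusted score.  Evaluates to exactly
    zero when every covariate sits at its centering constant.
    """

    dependent: str
    terms: list = field(default_factory=list)
    r_squared: Optional[float] = None
    n: Optional[int] = None

    @property
    def variables(self) -> tuple:
        return tuple(t.variable for t in self.terms)

    @property
    def requires_span(self) -> bool:
        return "span" in self.variables

    def correction(self, **covariates) -> float:
        missing = [v for v in self.variables if covariates.get(v) is None]
        if missing:
            from .errors import MissingCovariateError

            raise MissingCovariateError(
                f"{self.dependent} correction needs covariate(s): {missing}"
            )
        return float(sum(t.evaluate(covariates[t.variable]) for t in self.terms))

    def correction_array(self, frame: pd.DataFrame) -> np.ndarray:
        """Vectorized correction for a participant table (columns by variable)."""
        out = np.zeros(len(frame), dtype=float)
        for t in self.terms:
            out += t.coefficient * t.transform.deviation(frame[t.variable].to_numpy(float))
        return out

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "r_squared": self.r_squared,
            "n": self.n,
            "terms": [
                {
                    "variable": t.variable,
                    "transform": t.transform.name,
                    "centering": t.transform.centering,
                    "coefficient": t.coefficient,
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionEquation":
        return cls(
            dependent=d["dependent"],
            r_squared=d.get("r_squared"),
            n=d.get("n"),
            terms=[
                CorrectionTerm(
                    variable=t["variable"],
                    transform=TransformSpec(t["transform"], float(t["centering"])),
                    coefficient=float(t["coefficient"]),
                )
                for t in d["terms"]
            ],
        )


def derive_correction_equation(data: pd.DataFrame, model: CandidateModel) -> CorrectionEquation:
    """Refit the selected model on mean deviations and reverse the slopes.

    Both the transformed predictors and the score enter as deviations from
    their sample means; the deviation regression has (numerically) the same
    slopes as the original fit, and negating them gives the correction
    coefficients.
    """
    names = list(model.predictors)
    sub = data[[model.dependent] + names].dropna()
    y = sub[model.dependent].to_numpy(float)
    ydev = y - y.mean()
    cols, terms_meta = [], []
    for name in names:
        spec = model.predictors[name].centered(sub[name].to_numpy(float))
        cols.append(spec.deviation(sub[name].to_numpy(float)))
        terms_meta.append((name, spec))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("deviation design is rank deficient")
    slopes, *_ = np.linalg.lstsq(X, ydev, rcond=None)
    terms = [
        CorrectionTerm(variable=name, transform=spec, coefficient=-float(b))
        for (name, spec), b in zip(terms_meta, slopes)
    ]
    return CorrectionEquation(
        dependent=model.dependent, terms=terms, r_squared=model.r_squared, n=len(sub)
    )


@dataclass(frozen=True)
class PowerSpec:
    """A priori power-analysis request for a multiple-regression omnibus F test."""

    f_squared: float
    n_predictors: int
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not self.f_squared > 0:
            raise ValueError("f_squared must be > 0")
        if self.n_predictors < 1:
            raise ValueError("n_predictors must be >= 1")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")


def regression_power(n: int, spec: PowerSpec) -> float:
    """Power of the omnibus F test at sample size ``n``.

    Noncentral-F with numerator df u, denominator df n-u-1 and noncentrality
    ``lambda = f^2 * n`` (the G*Power convention).
    """
    u = spec.n_predictors
    v = n - u - 1
    if v < 1:
        return 0.0
    fcrit = stats.f.ppf(1.0 - spec.alpha, u, v)
    return float(stats.ncf.sf(fcrit, u, v, spec.f_squared * n))


def required_sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest N whose omnibus-F power reaches the requested power."""
    lo = spec.n_predictors + 2  # smallest admissible design (1 denominator df)
    if regression_power(lo, spec) >= spec.power:
        return lo
    hi = lo
    while regression_power(hi, spec) < spec.power:
        hi *= 2
        if hi > n_max:
            raise DivergenceError(f"power {spec.power} not reachable for N <= {n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if regression_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
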