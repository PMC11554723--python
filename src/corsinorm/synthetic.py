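"""Synthetic cohorts emulating the normative study's data structure.

No raw participant data ship with the published norms, so every other stage
of this package is exercised on simulated cohorts:

* :func:`generate_healthy` emulates the healthy normative sample — 340
  adults, ages 21-89 (mean 51.6, SD 19.4), education 4-25 years (mean 13.1,
  SD 4.6), sex ratio 177 F : 163 M — with the published pairwise
  correlations among age, education and the three raw scores (e.g.
  age-education -0.60, CS-CSSL 0.47, CSSL-CSSR 0.61).  Dependence comes
  from a Gaussian copula whose latent correlation matrix is iteratively
  calibrated so that the *observed* correlations (after rounding ages,
  discretizing CS to 2..8 and censoring CSSR at its 1.62 ceiling) hit the
  targets.  The CSSR ceiling pile-up (47.4% of the sample at 1.62) is
  produced by censoring a wider latent normal at the maximum.
* With ``generating_equations`` set, scores are instead produced exactly
  from known correction equations (``raw = mean - correction + noise``), so
  that the norming engine's parameter recovery can be tested against a
  known truth; with zero noise the equations are reproduced identically.
* :func:`generate_impaired` draws a memory-impaired cohort from
  user-supplied score means/SDs (the shipped defaults are a synthetic
  fixture, not published patient values) and rank-reorders CSSL against CS
  until their sample correlation hits a target (default r = 0.22).

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ConvergenceError, InvalidSpecError
from .norming import CorrectionEquation

__all__ = [
    "COHORT_VARIABLES",
    "DEFAULT_CORRELATIONS",
    "HealthyCohortSpec",
    "ImpairedCohortSpec",
    "generate_healthy",
    "generate_impaired",
]

COHORT_VARIABLES = ("age", "education", "cs", "cssl", "cssr")

#: Published pairwise correlations of the normative sample.
DEFAULT_CORRELATIONS = np.array(
    [
        #  age    edu     cs    cssl   cssr
        [1.00, -0.60, -0.46, -0.45, -0.40],  # age
        [-0.60, 1.00, 0.45, 0.49, 0.38],     # education
        [-0.46, 0.45, 1.00, 0.47, 0.36],     # cs
        [-0.45, 0.49, 0.47, 1.00, 0.61],     # cssl
        [-0.40, 0.38, 0.36, 0.61, 1.00],     # cssr
    ]
)

# Latent CSSR normal whose censoring to [0, 1.62] reproduces the observed
# ceiling fraction (47.4%) and mean (1.14) of the normative sample.
_CSSR_LATENT_MEAN = 1.537
_CSSR_LATENT_SD = 1.271


def _check_corr(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (5, 5):
        raise InvalidSpecError(f"correlation matrix must be 5x5, got {m.shape}")
    if not np.allclose(m, m.T):
        raise InvalidSpecError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise InvalidSpecError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-8:
        raise InvalidSpecError("correlation matrix is not positive semi-definite")
    return m


def _psd_project(m: np.ndarray) -> np.ndarray:
    """Nearest-ish correlation matrix: clip eigenvalues, renormalize diagonal."""
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, 1e-6, None)
    m2 = (v * w) @ v.T
    d = np.sqrt(np.diag(m2))
    return m2 / np.outer(d, d)


@dataclass(frozen=True)
class HealthyCohortSpec:
    """Specification of a simulated healthy normative cohort."""

    n: int = 340
    seed: int = 0
    age_mean: float = 51.6
    age_sd: float = 19.4
    age_range: tuple = (21, 89)
    edu_mean: float = 13.1
    edu_sd: float = 4.6
    edu_range: tuple = (4, 25)
    sex_ratio: tuple = (177, 163)  # females : males
    cs_mean: float = 4.97
    cs_sd: float = 1.03
    cs_range: tuple = (2, 8)
    cssl_mean: float = 18.67
    cssl_sd: float = 7.18
    cssl_range: tuple = (0.0, 29.16)
    cssr_range: tuple = (0.0, 1.62)
    target_correlations: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATIONS.copy())
    #: optional known truth: dependent -> CorrectionEquation; switches the
    #: generator to equation mode (see module docstring)
    generating_equations: Optional[dict] = None
    #: score means used in equation mode: dependent -> float
    score_means: Optional[dict] = None
    #: residual noise SD per score in equation mode
    noise_sd: Optional[dict] = None

    def __post_init__(self):
        if self.n < 1:
            raise InvalidSpecError("n must be positive")
        for name in ("age_range", "edu_range", "cs_range", "cssl_range", "cssr_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidSpecError(f"{name} must be ordered, got {(lo, hi)}")
        _check_corr(self.target_correlations)


def _margin_map(spec: HealthyCohortSpec):
    """Per-variable maps from latent standard normals to observed scales."""

    def age(z):
        return np.clip(np.rint(spec.age_mean + spec.age_sd * z), *spec.age_range)

    def edu(z):
        return np.clip(np.rint(spec.edu_mean + spec.edu_sd * z), *spec.edu_range)

    def cs(z):
        return np.clip(np.rint(spec.cs_mean + spec.cs_sd * z), *spec.cs_range)

    def cssl(z):
        return np.clip(spec.cssl_mean + spec.cssl_sd * z, *spec.cssl_range)

    def cssr(z):
        return np.clip(_CSSR_LATENT_MEAN + _CSSR_LATENT_SD * z, *spec.cssr_range)

    return {"age": age, "education": edu, "cs": cs, "cssl": cssl, "cssr": cssr}


def _draw(latent_corr: np.ndarray, n: int, rng: np.random.Generator, maps) -> dict:
    L = np.linalg.cholesky(_psd_project(latent_corr))
    z = rng.standard_normal((n, 5)) @ L.T
    return {var: maps[var](z[:, i]) for i, var in enumerate(COHORT_VARIABLES)}


def _calibrate_latent(spec: HealthyCohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Adjust the latent copula correlations so observed margins hit the targets.

    Rounding, discretization and censoring attenuate Pearson correlations;
    a few fixed-point iterations on a large calibration sample compensate.
    """
    target = _check_corr(spec.target_correlations)
    maps = _margin_map(spec)
    latent = target.copy()
    n_cal = 20000
    for _ in range(6):
        cols = _draw(latent, n_cal, rng, maps)
        sample = np.corrcoef(np.column_stack([cols[v] for v in COHORT_VARIABLES]).T)
        latent = latent + 0.9 * (target - sample)
        np.fill_diagonal(latent, 1.0)
        latent = _psd_project(np.clip(latent, -0.985, 0.985))
        np.fill_diagonal(latent, 1.0)
    return latent


def _sex_column(n: int, ratio: tuple, rng: np.random.Generator) -> np.ndarray:
    f, m = ratio
    n_f = int(round(n * f / (f + m)))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    return rng.permutation(sex)


def _finalize(columns: dict, sex: np.ndarray) -> pd.DataFrame:
    n = len(sex)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "age": columns["age"].astype(int)
            if np.allclose(columns["age"], np.rint(columns["age"]))
            else columns["age"],
            "education": columns["education"].astype(int)
            if np.allclose(columns["education"], np.rint(columns["education"]))
            else columns["education"],
            "sex": sex,
            "cs_raw": columns["cs"],
            "cssl_raw": columns["cssl"],
            "cssr_raw": columns["cssr"],
        }
    )


def generate_healthy(spec: HealthyCohortSpec) -> pd.DataFrame:
    """Simulate a healthy normative cohort as a participant table."""
    rng = np.random.default_rng(spec.seed)
    if spec.generating_equations:
        return _generate_from_equations(spec, rng)
    cal_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCA11]))
    latent = _calibrate_latent(spec, cal_rng)
    cols = _draw(latent, spec.n, rng, _margin_map(spec))
    return _finalize(cols, _sex_column(spec.n, spec.sex_ratio, rng))


def _generate_from_equations(spec: HealthyCohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Equation mode: scores are a known deterministic function of the
    demographics plus optional Gaussian noise (``raw = mean - correction + noise``)."""
    rho = float(spec.target_correlations[0, 1])  # age-education
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    z = rng.standard_normal((spec.n, 2)) @ L.T
    maps = _margin_map(spec)
    cols = {"age": maps["age"](z[:, 0]), "education": maps["education"](z[:, 1])}
    means = dict(spec.score_means or {})
    defaults = {"cs": spec.cs_mean, "cssl": spec.cssl_mean, "cssr": 1.14}
    noise = dict(spec.noise_sd or {})
    frame = pd.DataFrame({"age": cols["age"], "education": cols["education"]})
    for dep in ("cs", "cssl", "cssr"):
        eq = spec.generating_equations.get(dep)
        if eq is None:
            cols[dep] = maps[dep](rng.standard_normal(spec.n))
        else:
            if not isinstance(eq, CorrectionEquation):
                raise InvalidSpecError(f"generating equation for {dep!r} must be a CorrectionEquation")
            frame_cov = frame.copy()
            if eq.requires_span:
                frame_cov["span"] = cols["cs"]
            raw = means.get(dep, defaults[dep]) - eq.correction_array(frame_cov)
            sd = float(noise.get(dep, 0.0))
            if sd > 0:
                raw = raw + sd * rng.standard_normal(spec.n)
            cols[dep] = raw
    return _finalize(cols, _sex_column(spec.n, spec.sex_ratio, rng))


@dataclass(frozen=True)
class ImpairedCohortSpec:
    """Specification of a simulated memory-impaired cohort.

    The score means and SDs default to a synthetic fixture (they are NOT
    published patient values; supply the moments of a reference clinical
    sample for a real comparison).  CS and CSSL are made to correlate at
    ``target_r`` by rank reordering; other pairs are left independent.
    """

    n: int = 100
    seed: int = 0
    cs_mean: float = 3.5
    cs_sd: float = 1.2
    cssl_mean: float = 8.0
    cssl_sd: float = 4.5
    cssr_mean: float = 0.45
    cssr_sd: float = 0.40
    age_mean: float = 70.0
    age_sd: float = 8.0
    age_range: tuple = (40, 89)
    edu_mean: float = 10.0
    edu_sd: float = 4.0
    edu_range: tuple = (4, 25)
    cs_range: tuple = (2, 8)
    cssl_range: tuple = (0.0, 29.16)
    cssr_range: tuple = (0.0, 1.62)
    target_r: float = 0.22
    tolerance: float = 0.03

    def __post_init__(self):
        if self.n < 3:
            raise InvalidSpecError("n must be >= 3")
        for name in ("cs_sd", "cssl_sd", "cssr_sd", "age_sd", "edu_sd"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0")
        if not abs(self.target_r) < 1:
            raise InvalidSpecError("|target_r| must be < 1")


def generate_impaired(spec: ImpairedCohortSpec) -> pd.DataFrame:
    """Simulate an impaired cohort with a target CS-CSSL correlation.

    Each score is drawn from its clipped normal marginal; CSSL is then
    reordered (a pure permutation, so its marginal is untouched) against CS
    ranks until the sample Pearson correlation is within ``tolerance`` of
    ``target_r``.  The latent blending weight is found by bisection.
    """
    rng = np.random.default_rng(spec.seed)
    age = np.clip(np.rint(spec.age_mean + spec.age_sd * rng.standard_normal(spec.n)), *spec.age_range)
    edu = np.clip(np.rint(spec.edu_mean + spec.edu_sd * rng.standard_normal(spec.n)), *spec.edu_range)
    cs = np.clip(np.rint(spec.cs_mean + spec.cs_sd * rng.standard_normal(spec.n)), *spec.cs_range)
    cssl = np.clip(spec.cssl_mean + spec.cssl_sd * rng.standard_normal(spec.n), *spec.cssl_range)
    cssr = np.clip(spec.cssr_mean + spec.cssr_sd * rng.standard_normal(spec.n), *spec.cssr_range)

    cssl_sorted = np.sort(cssl)
    noise = rng.standard_normal(spec.n)
    cs_jitter = cs + 1e-9 * rng.standard_normal(spec.n)  # break rank ties deterministically
    z_cs = norm.ppf((rankdata(cs_jitter) - 0.5) / spec.n)

    def reorder(rho: float) -> np.ndarray:
        key = rho * z_cs + np.sqrt(max(1.0 - rho**2, 0.0)) * noise
        out = np.empty(spec.n)
        out[np.argsort(key)] = cssl_sorted
        return out

    def corr_at(rho: float) -> float:
        return float(np.corrcoef(cs, reorder(rho))[0, 1])

    lo, hi = -0.999, 0.999
    c_lo, c_hi = corr_at(lo), corr_at(hi)
    if not c_lo <= spec.target_r <= c_hi:
        raise ConvergenceError(
            f"target_r={spec.target_r} outside the reachable range [{c_lo:.3f}, {c_hi:.3f}]"
        )
    best = None
    for _ in range(80):
        mid = (lo + hi) / 2.0
        c = corr_at(mid)
        if best is None or abs(c - spec.target_r) < abs(best[1] - spec.target_r):
            best = (mid, c)
        if abs(c - spec.target_r) <= spec.tolerance:
            best = (mid, c)
            break
        if c < spec.target_r:
            lo = mid
        else:
            hi = mid
    rho, achieved = best
    if abs(achieved - spec.target_r) > spec.tolerance:
        raise ConvergenceError(
            f"CS-CSSL correlation {achieved:.3f} not within {spec.tolerance} of "
            f"{spec.target_r} after bisection (heavy clipping?)"
        )
    cssl_final = reorder(rho)
    return pd.DataFrame(
        {
            "participant_id": [f"S{i + 1:04d}" for i in range(spec.n)],
            "age": age.astype(int),
            "education": edu.astype(int),
            "sex": rng.permutation(np.array(["F", "M"])[np.arange(spec.n) % 2]),
            "cs_raw": cs,
            "cssl_raw": cssl_final,
            "cssr_raw": cssr,
        }
    )
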