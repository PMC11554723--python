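"""Demographic variable transformations used in regression-based norming.

The candidate family is the set of monotone re-expressions that appear in
published correction equations for this family of tests: the identity, the
natural logarithm, the square root, and the reciprocal.  Each fitted
transformation carries a *centering constant* — the sample mean of the
transformed variable in the normative cohort — so that a correction equation
evaluates to zero for the average participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["TransformSpec", "TRANSFORM_NAMES"]

TRANSFORM_NAMES = ("identity", "log", "sqrt", "reciprocal")

_ALIASES = {
    "identity": "identity",
    "natural-log": "log",
    "log": "log",
    "ln": "log",
    "square-root": "sqrt",
    "sqrt": "sqrt",
    "reciprocal": "reciprocal",
    "inverse": "reciprocal",
}


def _identity(x):
    return x


def _log(x):
    return np.log(x)


def _sqrt(x):
    return np.sqrt(x)


def _reciprocal(x):
    return 1.0 / x


_FUNCS = {"identity": _identity, "log": _log, "sqrt": _sqrt, "reciprocal": _reciprocal}


def canonical_name(name: str) -> str:
    try:
        return _ALIASES[name]
    except KeyError:
        raise ValueError(f"unknown transform {name!r}; expected one of {sorted(_ALIASES)}")


def admissible(name: str, x) -> bool:
    """Whether every value of ``x`` lies in the domain of the named transform.

    log and sqrt require strictly positive input (education 0 is rejected
    rather than silently offset); reciprocal requires nonzero input.
    """
    x = np.asarray(x, dtype=float)
    name = canonical_name(name)
    if name in ("log", "sqrt"):
        return bool(np.all(x > 0))
    if name == "reciprocal":
        return bool(np.all(x != 0))
    return True


@dataclass(frozen=True)
class TransformSpec:
    """A named transformation plus the centering constant of the fitted norm.

    ``centering`` is the normative-sample mean of the transformed variable;
    by convention the transform of a covariate enters a correction equation
    only as the deviation ``T(x) - centering``.
    """

    name: str
    centering: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "name", canonical_name(self.name))

    def apply(self, x):
        """Transform ``x`` (scalar or array); raises DomainError off-domain."""
        arr = np.asarray(x, dtype=float)
        if not admissible(self.name, arr):
            raise DomainError(f"value(s) outside domain of {self.name!r} transform")
        out = _FUNCS[self.name](arr)
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out)
        return out

    def deviation(self, x):
        """``T(x) - centering``, the centered transformed covariate."""
        out = self.apply(x)
        if isinstance(out, float):
            return out - self.centering
        return out - self.centering

    def centered(self, sample) -> "TransformSpec":
        """Return a copy with centering set to the sample mean of T(sample)."""
        return TransformSpec(self.name, float(np.mean(self.apply(np.asarray(sample, float)))))


def transform_value(name: str, x: float) -> float:
    """Convenience scalar transform without centering."""
    if not admissible(name, x):
        raise DomainError(f"{x!r} outside domain of {name!r} transform")
    return float(_FUNCS[canonical_name(name)](x))


# retained for introspection by the model-search code
def family(names=TRANSFORM_NAMES) -> tuple[str, ...]:
    return tuple(canonical_name(n) for n in names)


def ftransform(name: str):
    return _FUNCS[canonical_name(name)]
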