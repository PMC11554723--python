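"""Correction grids: tabulated demographic corrections for bedside use.

A grid evaluates a correction equation on an age x education (x span)
lattice and rounds to two decimals, matching the layout of the published
tables (education rows by age columns, one block per span).  Clinical
lookup picks the nearest lattice point on each axis; exact ties round
toward the lower value.  Downstream computation always uses the unrounded
equation — the grid is a display artifact.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MissingCovariateError
from .norming import CorrectionEquation
from .published import GRID_AGES, GRID_EDUCATIONS, GRID_SPANS

__all__ = [
    "GridLattice",
    "CorrectionGrid",
    "OutOfRangeWarning",
    "apply_correction",
    "build_grid",
    "lookup_correction",
    "round_half_away",
    "write_grid_csv",
]


class OutOfRangeWarning(UserWarning):
    """Query outside the normed lattice; the exact equation is used instead."""


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of the printed grids).

    Uses the shortest decimal representation of ``x`` so that e.g. 1.005
    (stored just below the midpoint in binary) still rounds up.
    """
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class GridLattice:
    """Strictly increasing display axes for a correction grid."""

    ages: tuple = GRID_AGES
    educations: tuple = GRID_EDUCATIONS
    spans: Optional[tuple] = None

    def __post_init__(self):
        for name in ("ages", "educations", "spans"):
            axis = getattr(self, name)
            if axis is None:
                continue
            axis = tuple(axis)
            object.__setattr__(self, name, axis)
            if any(b <= a for a, b in zip(axis, axis[1:])):
                raise ValueError(f"{name} axis must be strictly increasing: {axis}")
            if axis and min(axis) <= 0:
                raise ValueError(f"{name} axis values must be positive: {axis}")

    @classmethod
    def for_equation(cls, equation: CorrectionEquation) -> "GridLattice":
        spans = GRID_SPANS if equation.requires_span else None
        return cls(GRID_AGES, GRID_EDUCATIONS, spans)


def apply_correction(
    raw: float,
    age: float,
    education: float,
    equation: CorrectionEquation,
    span: Optional[float] = None,
) -> float:
    """Adjusted score = raw + correction(age, education[, span]), unrounded."""
    if equation.requires_span and span is None:
        raise MissingCovariateError(
            f"{equation.dependent} equation adjusts for span; none supplied"
        )
    cov = {"age": age, "education": education}
    if equation.requires_span:
        cov["span"] = span
    return float(raw) + equation.correction(**cov)


@dataclass
class CorrectionGrid:
    """A correction equation evaluated on a lattice, rounded for display."""

    equation: CorrectionEquation
    lattice: GridLattice
    cells: pd.DataFrame  # columns: [span?], education, age, correction

    def cell(self, age: float, education: float, span: Optional[float] = None) -> float:
        q = (self.cells["age"] == age) & (self.cells["education"] == education)
        if "span" in self.cells.columns:
            q &= self.cells["span"] == span
        hit = self.cells.loc[q, "correction"]
        if hit.empty:
            raise KeyError(f"no grid cell at age={age}, education={education}, span={span}")
        return float(hit.iloc[0])


def build_grid(equation: CorrectionEquation, lattice: Optional[GridLattice] = None) -> CorrectionGrid:
    """Tabulate the correction on the lattice, two-decimal half-away rounding."""
    lattice = lattice or GridLattice.for_equation(equation)
    spans: Sequence = lattice.spans if equation.requires_span else (None,)
    if equation.requires_span and lattice.spans is None:
        raise MissingCovariateError("lattice has no span axis for a span-bearing equation")
    rows = []
    for span in spans:
        for edu in lattice.educations:
            for age in lattice.ages:
                corr = apply_correction(0.0, age, edu, equation, span)
                rec = {"education": edu, "age": age, "correction": round_half_away(corr, 2)}
                if span is not None:
                    rec = {"span": span, **rec}
                rows.append(rec)
    return CorrectionGrid(equation=equation, lattice=lattice, cells=pd.DataFrame(rows))


def _nearest(axis: Sequence[float], value: float) -> float:
    """Nearest axis value; exact midpoints resolve toward the lower value."""
    axis = np.asarray(axis, dtype=float)
    dist = np.abs(axis - value)
    best = dist.min()
    candidates = axis[np.isclose(dist, best)]
    return float(candidates.min())


def lookup_correction(
    grid: CorrectionGrid,
    age: float,
    education: float,
    span: Optional[float] = None,
) -> float:
    """Clinical nearest-value lookup on the grid.

    Queries farther outside an axis than half its edge spacing fall back to
    the exact equation with an :class:`OutOfRangeWarning` — the printed norms
    claim validity for the sampled ranges only.
    """
    axes = {"age": (grid.lattice.ages, age), "education": (grid.lattice.educations, education)}
    if grid.equation.requires_span:
        if span is None:
            raise MissingCovariateError("span required for this grid")
        axes["span"] = (grid.lattice.spans, span)
    for name, (axis, value) in axes.items():
        half_step = max((axis[1] - axis[0]) if len(axis) > 1 else 0.0,
                        (axis[-1] - axis[-2]) if len(axis) > 1 else 0.0) / 2.0
        if value < axis[0] - half_step or value > axis[-1] + half_step:
            warnings.warn(
                f"{name}={value} outside the normed lattice {axis[0]}-{axis[-1]}; "
                "using the exact correction equation",
                OutOfRangeWarning,
                stacklevel=2,
            )
            return apply_correction(0.0, age, education, grid.equation, span)
    snapped = {name: _nearest(axis, value) for name, (axis, value) in axes.items()}
    return grid.cell(
        age=snapped["age"],
        education=snapped["education"],
        span=snapped.get("span"),
    )


def write_grid_csv(grid: CorrectionGrid, path) -> None:
    """Write the grid in the printed-table layout: education rows x age columns,
    one block per span."""
    frames = []
    if "span" in grid.cells.columns:
        for span, block in grid.cells.groupby("span", sort=True):
            piv = block.pivot(index="education", columns="age", values="correction")
            piv.insert(0, "span", span)
            frames.append(piv)
    else:
        frames.append(grid.cells.pivot(index="education", columns="age", values="correction"))
    out = pd.concat(frames)
    out.to_csv(path, float_format="%.2f")
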