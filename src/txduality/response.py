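"""Fold-change curves, monotonicity classification, and regime maps.

A dose response is reduced to a fold-change curve ``F(u) = r(u) / r(u0)``
over an ordered input grid (TF concentration, site number, unbinding rate,
or affinity), classified as flat / increasing / decreasing / nonmonotonic
from the signs of successive differences of ``log F`` (differences below a
tolerance count as zero, making classification invariant to monotone
rescaling).  Regime maps sweep a second parameter and record the class of
each slice, reproducing affinity-vs-concentration and affinity-vs-site-
number duality diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

MonotonicityClass = Literal["flat", "increasing", "decreasing", "nonmonotonic"]


def classify_monotonicity(F: Sequence[float], rtol: float = 1e-6) -> tuple[MonotonicityClass, int | None]:
    """Classify a positive fold-change sequence on an ordered grid.

    Differences of ``log F`` with magnitude <= rtol are treated as zero.
    Returns ``(class, peak_index)``; the peak index is reported for
    nonmonotonic sequences with a single +/- sign change (a bell), else None.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 1 or F.size < 3:
        raise ValueError("need at least 3 grid points to classify")
    if np.any(F <= 0) or not np.all(np.isfinite(F)):
        raise ValueError("fold changes must be finite and strictly positive")
    d = np.diff(np.log(F))
    signs = np.sign(d)
    signs[np.abs(d) <= rtol] = 0
    nonzero = signs[signs != 0]
    if nonzero.size == 0:
        return "flat", None
    if np.all(nonzero > 0):
        return "increasing", None
    if np.all(nonzero < 0):
        return "decreasing", None
    # nonmonotonic; locate the peak for a single up->down pattern
    changes = np.flatnonzero(np.diff(nonzero) != 0)
    peak = None
    if changes.size == 1 and nonzero[0] > 0:
        peak = int(np.argmax(F))
    return "nonmonotonic", peak


@dataclass(frozen=True)
class ResponseCurve:
    """Fold-change response over one input with its monotonicity class."""

    input_name: str
    input_grid: np.ndarray
    F: np.ndarray
    monotonicity: MonotonicityClass
    peak_input: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.input_name: self.input_grid, "fold_change": self.F})


def fold_change_curve(
    evaluator: Callable[[np.ndarray], np.ndarray],
    input_grid: np.ndarray,
    basal_input: float = 0.0,
    input_name: str = "x",
    rtol: float = 1e-6,
) -> ResponseCurve:
    """Evaluate rates over a grid and normalize to the basal input.

    ``evaluator`` maps an array of input values to strictly positive
    steady-state rates; the basal input (prepended, not part of the grid)
    defines the normalization r(u)/r(u0).
    """
    grid = np.asarray(input_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 3:
        raise ValueError("input grid must be 1-D with at least 3 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("input grid must be strictly increasing")
    rates = np.asarray(evaluator(np.concatenate(([basal_input], grid))), dtype=float)
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("evaluator returned nonpositive or nonfinite rates")
    F = rates[1:] / rates[0]
    cls, peak_idx = classify_monotonicity(F, rtol=rtol)
    peak = float(grid[peak_idx]) if peak_idx is not None else None
    return ResponseCurve(input_name=input_name, input_grid=grid, F=F, monotonicity=cls, peak_input=peak)


@dataclass(frozen=True)
class RegimeMap:
    """Classes of fold-change slices over a 2-D parameter grid.

    Each row fixes ``axis1`` and classifies F along ``axis2``; ``F_grid``
    holds the fold-change values themselves.
    """

    axis1_name: str
    axis1_grid: np.ndarray
    axis2_name: str
    axis2_grid: np.ndarray
    classes: tuple[MonotonicityClass, ...]
    peak_inputs: tuple[float | None, ...]
    F_grid: np.ndarray | None = None

    @property
    def class_set(self) -> set[str]:
        return set(self.classes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a1 in enumerate(self.axis1_grid):
            rows.append(
                {
                    self.axis1_name: a1,
                    "class": self.classes[i],
                    "peak_" + self.axis2_name: self.peak_inputs[i],
                }
            )
        return pd.DataFrame(rows)

    def fold_change_frame(self) -> pd.DataFrame:
        if self.F_grid is None:
            raise ValueError("map was built without fold-change storage")
        df = pd.DataFrame(self.F_grid, index=self.axis1_grid, columns=self.axis2_grid)
        df.index.name = self.axis1_name
        df.columns.name = self.axis2_name
        return df


def regime_map(
    slice_fold_change: Callable[[float, np.ndarray], np.ndarray],
    axis1_name: str,
    axis1_grid: np.ndarray,
    axis2_name: str,
    axis2_grid: np.ndarray,
    rtol: float = 1e-6,
    keep_F: bool = True,
) -> RegimeMap:
    """Classify fold-change slices over a 2-D sweep.

    ``slice_fold_change(a1, axis2_grid)`` returns the fold-change values of
    the slice at fixed axis1 value ``a1`` (already normalized to that
    slice's basal input).
    """
    a1 = np.asarray(axis1_grid, dtype=float)
    a2 = np.asarray(axis2_grid, dtype=float)
    # axis2 may be a short integer grid (site numbers run 1..6)
    if a1.size < 8 or a2.size < 3:
        raise ValueError("regime maps need >= 8 points on axis1 and >= 3 on axis2")
    classes: list[MonotonicityClass] = []
    peaks: list[float | None] = []
    F_rows = []
    for v in a1:
        F = np.asarray(slice_fold_change(float(v), a2), dtype=float)
        cls, peak_idx = classify_monotonicity(F, rtol=rtol)
        classes.append(cls)
        peaks.append(float(a2[peak_idx]) if peak_idx is not None else None)
        if keep_F:
            F_rows.append(F)
    return RegimeMap(
        axis1_name=axis1_name,
        axis1_grid=a1,
        axis2_name=axis2_name,
        axis2_grid=a2,
        classes=tuple(classes),
        peak_inputs=tuple(peaks),
        F_grid=np.array(F_rows) if keep_F else None,
    )


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

#: Default biologically plausible ranges (log-uniform), bracketing reported
#: figure-caption values by about two orders of magnitude.
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = {
    "binding": (1e-4, 1.0),      # nM^-1 s^-1
    "unbinding": (1e-3, 1e2),    # s^-1
    "cycle": (1e-3, 10.0),       # s^-1
    "epsilon": (1e-2, 1e2),      # dimensionless
}


def sample_parameters(
    ranges: Mapping[str, tuple[float, float]],
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Log-uniform draws for each named range; deterministic under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        cols[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    return pd.DataFrame(cols)


def log_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """Log-spaced grid used throughout for concentration and rate sweeps."""
    if not (0 < lo < hi) or n < 2:
        raise ValueError("need 0 < lo < hi and n >= 2")
    return np.logspace(np.log10(lo), np.log10(hi), n)
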