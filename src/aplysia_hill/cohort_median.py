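"""Median-individual selection across a cohort of fitted muscles.

Population averaging of nonlinear model parameters can land in parameter
space no real individual occupies, so the shipped model is built from the
*individual closest to the median*: each animal's fitted curve is evaluated
on a shared grid, the pointwise median curve is taken, the curve family is
refitted to that median, and the individual with the lowest sum of squared
error to the median fit wins.

Grid conventions: normalized lengths at 0.001 spacing, normalized
velocities at 0.0005 per second spacing; force--frequency uses the shared
measured frequencies directly (no interpolation needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "CohortCurveSet",
    "GRID_SPACING",
    "build_grid",
    "pointwise_median",
    "select_representative",
]

GRID_SPACING = {"length_tension": 0.001, "force_velocity": 0.0005}


@dataclass
class CohortCurveSet:
    """Per-individual curves evaluated on a shared grid."""

    family: str
    grid: np.ndarray
    curves: np.ndarray  # shape (n_individuals, n_grid)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape[1] != self.grid.size:
            raise ValueError("curves and grid sizes disagree")


def build_grid(family: str, data_min: float, data_max: float) -> np.ndarray:
    """Shared evaluation grid for one curve family.

    Length and velocity families use inclusive arithmetic grids at the
    family spacing; the force--frequency family returns the measured
    frequency set unchanged (pass it as (min, max) = the full set via
    ``data_min=data_max=None`` is not supported — call with the set).
    """
    if family == "force_frequency":
        raise ValueError(
            "force-frequency uses the shared measured frequencies; "
            "pass them directly instead of building a grid"
        )
    if family not in GRID_SPACING:
        raise ValueError(f"unknown family {family!r}")
    if not data_min < data_max:
        raise ValueError(f"inverted range [{data_min}, {data_max}]")
    step = GRID_SPACING[family]
    n = int(round((data_max - data_min) / step))
    return data_min + step * np.arange(n + 1)


def pointwise_median(curves) -> np.ndarray:
    """Per-grid-point median across individuals.

    Even cohort sizes take the mean of the two central values (numpy's
    convention), which matters for the n = 4 force--velocity cohort.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if curves.shape[0] < 1:
        raise ValueError("need at least one curve")
    return np.median(curves, axis=0)


def select_representative(
    curve_set: CohortCurveSet,
    refit: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> dict:
    """Pick the individual closest to the fitted median curve.

    Parameters
    ----------
    curve_set : CohortCurveSet
        Individual fitted curves on the shared grid.
    refit : callable (grid, median_values) -> curve values on grid
        Fits the family's functional form to the median values and returns
        the fitted curve evaluated on the grid (the coefficients, if
        needed, are the caller's to keep).

    Returns
    -------
    dict with ``best_index`` (ties broken by lowest index), ``sse`` per
    individual (discrete sum over the grid), ``median_curve`` and
    ``median_fit_curve``.
    """
    y_med = pointwise_median(curve_set.curves)
    fit_curve = np.asarray(refit(curve_set.grid, y_med), dtype=float)
    if fit_curve.shape != curve_set.grid.shape:
        raise ValueError("refit must return values on the shared grid")
    sse = np.sum((curve_set.curves - fit_curve[None, :]) ** 2, axis=1)
    best = int(np.argmin(sse))  # argmin takes the first minimum: lowest index
    return {
        "best_index": best,
        "sse": sse,
        "median_curve": y_med,
        "median_fit_curve": fit_curve,
        "n_individuals": curve_set.curves.shape[0],
    }
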