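"""Change-point calibration of contamination-index thresholds.

The contamination index stays flat at a plasma baseline over low
contaminant cell counts and rises once counts exceed a critical level.
That relationship is fit with a single-knot continuous broken-stick
("segmented spline") model on the log10(count + 1) axis:

    index(x) = b                      for x <= c
    index(x) = b + s * (x - c)        for x >  c

The knot c is located by exhaustive grid search over candidate positions
(the observed transformed counts plus a uniform refinement grid), with
the baseline b and slope s solved by least squares under the continuity
constraint at each candidate.  The index value at the knot (the fitted
baseline) becomes the flagging threshold: samples whose index strictly
exceeds it are flagged as potentially contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contamination_index import ContaminationReport

__all__ = ["ChangePointFit", "fit_changepoint", "flag_with_threshold"]

MIN_POINTS = 5


@dataclass(frozen=True)
class ChangePointFit:
    """Segmented-regression fit of contamination index versus cell count.

    ``knot_log10_count`` is the change point on the log10(count + 1) axis;
    ``threshold_index`` is the fitted index at the knot (equal to the
    baseline under the flat-then-rising model).  ``degenerate`` marks a
    zero-variance fit, ``boundary`` a knot pinned to an end of the
    observed count range (no flat or no rising segment).
    """

    knot_log10_count: float
    baseline_index: float
    slope: float
    r_squared: float
    threshold_index: float
    n_points: int
    degenerate: bool = False
    boundary: bool = False
    rss: float = 0.0
    grid_step: float = 0.0


def _segment_lstsq(x: np.ndarray, y: np.ndarray, knot: float) -> tuple[float, float, float]:
    """Least-squares (baseline, slope, RSS) for a fixed knot."""
    h = np.maximum(x - knot, 0.0)
    if h.max() == 0.0:  # knot at or beyond the largest count: flat model
        b = float(y.mean())
        return b, 0.0, float(((y - b) ** 2).sum())
    X = np.column_stack([np.ones_like(x), h])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float((resid**2).sum())


def fit_changepoint(
    counts: Sequence[float],
    indices: Sequence[float],
    n_grid: int = 201,
) -> ChangePointFit:
    """Fit the flat-then-rising broken-stick model to (count, index) data.

    Counts may be zero (pure platelet-poor plasma); they are transformed
    as log10(count + 1).  Candidate knots are the observed transformed
    counts plus ``n_grid`` uniformly spaced refinement points; the knot
    minimising the residual sum of squares wins (ties go to the smallest
    knot).  Zero variance in the indices yields a degenerate flat fit
    with r_squared = 1 by convention and the knot at the upper boundary.
    """
    x_all = np.asarray(counts, dtype=float)
    y = np.asarray(indices, dtype=float)
    if x_all.shape != y.shape:
        raise ValueError("counts and indices must have equal length")
    if len(x_all) < MIN_POINTS:
        raise ValueError(f"change-point fit requires at least {MIN_POINTS} points, got {len(x_all)}")
    if np.any(x_all < 0):
        raise ValueError("cell counts must be non-negative")

    order = np.argsort(x_all, kind="mergesort")  # fit is order-invariant; sort for stability
    x = np.log10(x_all[order] + 1.0)
    y = y[order]
    grid_step = float((x.max() - x.min()) / max(n_grid - 1, 1))

    ybar = y.mean()
    tss = float(((y - ybar) ** 2).sum())
    if np.ptp(y) == 0.0:  # zero variance: degenerate flat fit
        return ChangePointFit(
            knot_log10_count=float(x.max()),
            baseline_index=float(ybar),
            slope=0.0,
            r_squared=1.0,
            threshold_index=float(ybar),
            n_points=len(x),
            degenerate=True,
            boundary=True,
            rss=0.0,
            grid_step=grid_step,
        )

    candidates = np.unique(np.concatenate([x, np.linspace(x.min(), x.max(), n_grid)]))
    best = None
    for c in candidates:
        b, s, rss = _segment_lstsq(x, y, float(c))
        if best is None or rss < best[2] - 1e-15:
            best = (float(c), (b, s), rss)
    knot, (baseline, slope), rss = best
    r2 = 1.0 - rss / tss
    boundary = bool(knot <= x.min() or knot >= x.max())
    return ChangePointFit(
        knot_log10_count=knot,
        baseline_index=baseline,
        slope=slope,
        r_squared=r2,
        threshold_index=baseline,
        n_points=len(x),
        degenerate=False,
        boundary=boundary,
        rss=rss,
        grid_step=grid_step,
    )


def flag_with_threshold(
    report: ContaminationReport,
    fit: ChangePointFit,
    contamination_type: str,
) -> ContaminationReport:
    """Apply a fitted change-point threshold to a contamination report.

    Sets the threshold for the given type to the fit's index-at-knot and
    recomputes the flags (strict ``index > threshold``).  Degenerate fits
    carry no usable change point and are refused.
    """
    if fit.degenerate:
        raise ValueError(
            "change-point fit is degenerate (no index variation); set a threshold manually"
        )
    return report.with_threshold(contamination_type, fit.threshold_index)
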