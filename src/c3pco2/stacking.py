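"""LOESS stacking of scattered multi-section series onto a regular age grid.

Samples from all sections are pooled and smoothed with classical LOESS —
degree-1 local polynomial, tricube kernel over the span-nearest
neighbours — evaluated at every point of a regular 0.002 Myr age grid.
Each gridpoint carries the fitted central value, the standard error of
the fitted value (from the local weighted residual variance and the
equivalent-kernel norm), and the local sample count.  The smoothing span
is either supplied or chosen by k-fold cross-validation over a log-spaced
span grid.  Gridpoints outside the data span are left missing — the
smoother never extrapolates.

Robustness re-fits mirror the usual checks on compilation-driven stacks:
re-fitting on random 80% subsamples, and leave-one-section-out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StackedCurve", "make_age_grid", "fit_stack", "cv_select_span", "robustness_refits"]

logger = logging.getLogger(__name__)

GRID_STEP = 0.002  # Myr
MIN_SAMPLES = 10


def default_span_grid(n: int) -> tuple[float, ...]:
    """Log-spaced CV candidate spans, floored at 4 neighbours (or 1% of n).

    The floor adapts to the sample count so cross-validation can reach
    near-interpolation smoothing when the data are dense and clean, while
    the upper end still covers heavy smoothing for noisy sparse data.
    """
    lo = max(4.0 / n, 0.01)
    return tuple(np.geomspace(min(lo, 0.999), 1.0, 10))


@dataclass(frozen=True)
class StackedCurve:
    """Regular-grid stack: central value, standard error, local n, span used."""

    age_grid: np.ndarray  # Ma, strictly decreasing, step GRID_STEP
    center: np.ndarray
    se: np.ndarray
    n_local: np.ndarray
    span: float

    def __post_init__(self) -> None:
        n = len(self.age_grid)
        if not (len(self.center) == len(self.se) == len(self.n_local) == n):
            raise ValueError("all stack arrays must have equal length")
        ok = self.n_local > 0
        if np.any(self.se[ok] < 0):
            raise ValueError("se must be >= 0")
        if np.any(~np.isfinite(self.center[ok])):
            raise ValueError("center must be finite wherever n_local > 0")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_ma": self.age_grid,
                "center": self.center,
                "se": self.se,
                "n_local": self.n_local,
            }
        )


def make_age_grid(age_old: float, age_young: float, step: float = GRID_STEP) -> np.ndarray:
    """Regular decreasing age grid, half-open at the young end.

    The grid is integer-indexed (age_old − i·step) so float step error
    never accumulates into the point count.
    """
    if age_old <= age_young:
        raise ValueError("age_old must exceed age_young")
    n = int(round((age_old - age_young) / step))
    return age_old - step * np.arange(n)


def _loess_at(x0: float, x: np.ndarray, y: np.ndarray, span: float):
    """Local degree-1 tricube fit at x0 → (fitted, se, n_local)."""
    n = len(x)
    k = max(2, min(n, int(np.ceil(span * n))))
    d = np.abs(x - x0)
    idx = np.argpartition(d, k - 1)[:k]
    dk = d[idx]
    dmax = dk.max()
    if dmax == 0.0:
        # all selected samples sit exactly at x0: weighted mean, equal weights
        w = np.ones(k)
    else:
        w = np.clip(1.0 - (dk / dmax) ** 3, 0.0, None) ** 3
        if w.sum() == 0.0:  # k == 1 pathologies
            w = np.ones(k)
    xs = x[idx] - x0
    ys = y[idx]
    sw, swx, swxx = w.sum(), (w * xs).sum(), (w * xs * xs).sum()
    det = sw * swxx - swx * swx
    if det <= 1e-14 * max(sw * swxx, 1e-300):
        # degenerate design (all xs equal): weighted mean
        l = w / sw
        fitted = float(l @ ys)
        resid = ys - fitted
    else:
        # equivalent kernel of the intercept of the local linear fit
        l = w * (swxx - swx * xs) / det
        fitted = float(l @ ys)
        slope = float((sw * (w * xs * ys).sum() - swx * (w * ys).sum()) / det)
        resid = ys - (fitted + slope * xs)
    nw = int((w > 0).sum())
    dof = max(sw - 2.0 * (w * w).sum() / sw, 1e-12)
    sigma2 = float((w * resid**2).sum() / dof)
    se = float(np.sqrt(max(sigma2, 0.0) * (l @ l)))
    return fitted, se, nw


def _fit_curve(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> StackedCurve:
    lo, hi = x.min(), x.max()
    center = np.full(len(grid), np.nan)
    se = np.full(len(grid), np.nan)
    n_local = np.zeros(len(grid), dtype=int)
    inside = (grid >= lo) & (grid <= hi)
    for i in np.flatnonzero(inside):
        center[i], se[i], n_local[i] = _loess_at(grid[i], x, y, span)
    return StackedCurve(grid, center, se, n_local, span)


def loess_predict(x: np.ndarray, y: np.ndarray, x_new: np.ndarray, span: float) -> np.ndarray:
    """Point predictions at arbitrary locations (NaN outside the data span)."""
    out = np.full(len(x_new), np.nan)
    lo, hi = x.min(), x.max()
    for i, x0 in enumerate(x_new):
        if lo <= x0 <= hi:
            out[i], _, _ = _loess_at(x0, x, y, span)
    return out


def cv_select_span(
    x: np.ndarray,
    y: np.ndarray,
    span_grid=None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the span minimising k-fold cross-validated squared error.

    Returns (best span, CV table with columns span / cv_mse).
    """
    rng = np.random.default_rng(seed)
    n = len(x)
    if span_grid is None:
        span_grid = default_span_grid(n)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    rows = []
    for span in span_grid:
        errs = []
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            if mask.sum() < MIN_SAMPLES:
                continue
            pred = loess_predict(x[mask], y[mask], x[fold], span)
            ok = np.isfinite(pred)
            if ok.any():
                errs.append(np.mean((pred[ok] - y[fold][ok]) ** 2))
        rows.append({"span": float(span), "cv_mse": float(np.mean(errs)) if errs else np.inf})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["cv_mse"].idxmin(), "span"])
    return best, table


def fit_stack(
    samples: pd.DataFrame,
    grid: np.ndarray,
    span: float | None = None,
    k_folds: int = 5,
    span_grid=None,
    cv_seed: int = 0,
) -> StackedCurve:
    """LOESS-stack pooled samples onto the grid.

    ``samples`` needs columns ``age_ma`` and ``value`` (sections are
    pooled — stacking is invariant to section labels and sample order).
    If ``span`` is None it is selected by cross-validation.
    """
    x = samples["age_ma"].to_numpy(dtype=float)
    y = samples["value"].to_numpy(dtype=float)
    if len(x) < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {len(x)}")
    if span is None:
        span, _ = cv_select_span(x, y, span_grid, k_folds, cv_seed)
    return _fit_curve(x, y, grid, float(span))


def robustness_refits(
    samples: pd.DataFrame,
    grid: np.ndarray,
    mode: str,
    n_reps: int = 20,
    seed: int = 0,
    subsample_frac: float = 0.8,
    span: float | None = None,
) -> dict[str, StackedCurve]:
    """Re-fit the stack under data perturbations.

    mode='subsample80' draws ``n_reps`` seeded random subsets of
    ``subsample_frac`` of the samples; mode='leave_section_out' refits
    once per excluded ``section_id``.  Refits left with fewer than 10
    samples are skipped and logged.  Returns label → StackedCurve.
    """
    if span is None:
        span, _ = cv_select_span(
            samples["age_ma"].to_numpy(float), samples["value"].to_numpy(float)
        )
    out: dict[str, StackedCurve] = {}
    if mode == "subsample80":
        rng = np.random.default_rng(seed)
        n = len(samples)
        m = int(round(subsample_frac * n))
        for rep in range(n_reps):
            idx = rng.choice(n, size=m, replace=False)
            sub = samples.iloc[np.sort(idx)]
            if len(sub) < MIN_SAMPLES:
                logger.warning("subsample rep %d has %d < %d samples; skipped", rep, len(sub), MIN_SAMPLES)
                continue
            out[f"subsample_{rep:03d}"] = fit_stack(sub, grid, span=span)
    elif mode == "leave_section_out":
        if "section_id" not in samples.columns:
            raise ValueError("leave_section_out requires a section_id column")
        for sec in pd.unique(samples["section_id"]):
            sub = samples[samples["section_id"] != sec]
            if len(sub) < MIN_SAMPLES:
                logger.warning("refit without %s has %d < %d samples; skipped", sec, len(sub), MIN_SAMPLES)
                continue
            out[f"without_{sec}"] = fit_stack(sub, grid, span=span)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'subsample80' or 'leave_section_out'")
    return out
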