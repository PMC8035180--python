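"""Monte Carlo propagation of input uncertainties through the proxy chain.

Every input is treated as Gaussian: the proxy parameters (B, the
reference pCO2, the reference plant δ13C) are sampled once per draw —
they are systematic across the record — while the stacked δ13C_p,
δ13C_carb and SST values are sampled independently per gridstep from
their LOESS centers and standard errors (measurement-level error).  Each
draw is chained through DIC → atmospheric δ13C_CO2 → Δ(Δ13C) → the
hyperbola inversion; draws that land beyond the proxy asymptote or
outside (0, 10⁶] ppmv are excluded, and the per-gridstep median with
16th/84th percentiles (type-7, linear interpolation between order
statistics) of the survivors forms the 68% band.  The positive error at
a gridstep is p84 − median; the negative error is median − p16.

The reference state defaults to the three stacks evaluated at a
pre-event reference age (the oldest gridpoint covered by all three),
matching how a self-contained record anchors its own baseline; a fixed
externally measured plant baseline (e.g. −24.42 ± 0.5‰) can be used
instead via ``plant_ref='params'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .proxy import ProxyParams, big_delta, d13c_co2_from_dic, d13c_dic_from_carb
from .stacking import StackedCurve

__all__ = ["PCO2Reconstruction", "mc_reconstruct", "report_interval", "sensitivity_sweep"]

DEFAULT_BOUNDS = (0.0, 1.0e6)  # ppmv, exclusive lower / inclusive upper
SWEEPABLE = ("B", "pco2_ref", "d13c_p_ref", "carb_cie", "sst_rise")


@dataclass(frozen=True)
class PCO2Reconstruction:
    """Per-gridstep Monte Carlo summary of the reconstructed pCO2."""

    age_grid: np.ndarray  # Ma
    median: np.ndarray  # ppmv
    p16: np.ndarray  # ppmv
    p84: np.ndarray  # ppmv
    n_valid: np.ndarray  # retained draws per gridstep
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        ok = self.n_valid > 0
        if np.any(self.p16[ok] > self.median[ok]) or np.any(self.median[ok] > self.p84[ok]):
            raise ValueError("percentile ordering violated (p16 <= median <= p84)")
        if np.any(self.n_valid > self.n_draws):
            raise ValueError("n_valid cannot exceed n_draws")

    @property
    def excluded_fraction(self) -> np.ndarray:
        return 1.0 - self.n_valid / self.n_draws

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_ma": self.age_grid,
                "median_ppmv": self.median,
                "p16_ppmv": self.p16,
                "p84_ppmv": self.p84,
                "n_valid": self.n_valid,
            }
        )


def _check_grids(*stacks: StackedCurve) -> np.ndarray:
    g0 = stacks[0].age_grid
    for s in stacks[1:]:
        if len(s.age_grid) != len(g0) or not np.allclose(s.age_grid, g0):
            raise ValueError("stacks must share the same age grid")
    return g0


def _reference_index(*stacks: StackedCurve) -> int:
    covered = np.ones(len(stacks[0].age_grid), dtype=bool)
    for s in stacks:
        covered &= (s.n_local > 0) & np.isfinite(s.center)
    if not covered.any():
        raise ValueError("no gridpoint is covered by all three stacks")
    return int(np.flatnonzero(covered)[0])  # oldest covered gridpoint


def mc_reconstruct(
    plant_stack: StackedCurve,
    carb_stack: StackedCurve,
    sst_stack: StackedCurve,
    params: ProxyParams | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    reference_age: float | None = None,
    plant_ref: str = "stack",
    shared_params: bool = True,
) -> PCO2Reconstruction:
    """Reconstruct pCO2 with full uncertainty propagation.

    Parameters
    ----------
    plant_stack, carb_stack, sst_stack
        LOESS stacks of plant δ13C (‰), carbonate δ13C (‰) and SST (°C)
        on a shared age grid.
    params
        Proxy constants with uncertainties.
    n_draws
        Monte Carlo sample size (default 10,000; minimum 100).
    bounds
        Validity window for reconstructed pCO2, exclusive below and
        inclusive above; out-of-window draws are excluded.
    reference_age
        Age (Ma) of the pre-event reference gridstep; defaults to the
        oldest gridpoint covered by all three stacks.
    plant_ref
        'stack' anchors δ13C_p(t=0) on the plant stack at the reference
        age; 'params' uses the fixed ``params.d13c_p_ref ± sd``.
    shared_params
        If True (default) B, pCO2(t=0) and the reference state are drawn
        once per draw (systematic); if False they are redrawn per
        gridstep (fully independent errors).
    """
    p = params if params is not None else ProxyParams()
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if plant_ref not in ("stack", "params"):
        raise ValueError("plant_ref must be 'stack' or 'params'")
    grid = _check_grids(plant_stack, carb_stack, sst_stack)
    n_grid = len(grid)

    if reference_age is None:
        ref_i = _reference_index(plant_stack, carb_stack, sst_stack)
    else:
        ref_i = int(np.argmin(np.abs(grid - reference_age)))

    rng = np.random.default_rng(seed)

    def draws(mean, sd, size):
        return mean + sd * rng.standard_normal(size)

    shape_sys = (n_draws, 1) if shared_params else (n_draws, n_grid)
    a = draws(p.a, p.a_sd, shape_sys)
    b = draws(p.b, p.b_sd, shape_sys)
    pco2_ref = draws(p.pco2_ref, p.pco2_ref_sd, shape_sys)
    if plant_ref == "params":
        plant0 = draws(p.d13c_p_ref, p.d13c_p_ref_sd, shape_sys)
    else:
        plant0 = draws(plant_stack.center[ref_i], plant_stack.se[ref_i], shape_sys)
    carb0 = draws(carb_stack.center[ref_i], carb_stack.se[ref_i], shape_sys)
    sst0 = draws(sst_stack.center[ref_i], sst_stack.se[ref_i], shape_sys)

    covered = np.ones(n_grid, dtype=bool)
    for s in (plant_stack, carb_stack, sst_stack):
        covered &= (s.n_local > 0) & np.isfinite(s.center)

    plant_t = draws(plant_stack.center, plant_stack.se, (n_draws, n_grid))
    carb_t = draws(carb_stack.center, carb_stack.se, (n_draws, n_grid))
    sst_t = draws(sst_stack.center, sst_stack.se, (n_draws, n_grid))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # out-of-bounds SST draws are handled by exclusion
        co2_0 = d13c_co2_from_dic(d13c_dic_from_carb(carb0), sst0)
        co2_t = d13c_co2_from_dic(d13c_dic_from_carb(carb_t), sst_t)
    big0 = big_delta(co2_0, np.clip(plant0, -999.0, None))
    bigt = big_delta(co2_t, np.clip(plant_t, -999.0, None))
    ddc = bigt - big0

    # hyperbola inversion, inlined for per-draw A, B
    param_ok = (a > 4.4) & (b > 0) & (pco2_ref > 0)
    a_safe = np.where(a > 4.4, a, 4.4 + 1e-9)
    b_safe = np.where(b > 0, b, 1e-12)
    c = a_safe * 4.4 / ((a_safe - 4.4) * b_safe)
    num = (
        ddc * a_safe**2
        + ddc * a_safe * b_safe * pco2_ref
        + 2.0 * ddc * a_safe * b_safe * c
        + ddc * b_safe**2 * c * pco2_ref
        + ddc * b_safe**2 * c**2
        + a_safe**2 * b_safe * pco2_ref
    )
    den = a_safe**2 * b_safe - ddc * a_safe * b_safe - ddc * b_safe**2 * pco2_ref - ddc * b_safe**2 * c
    valid = param_ok & (den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pco2 = np.where(valid, num / np.where(den > 0, den, 1.0), np.nan)
    lo, hi = bounds
    valid = valid & (pco2 > lo) & (pco2 <= hi) & covered[None, :]
    pco2 = np.where(valid, pco2, np.nan)

    n_valid = valid.sum(axis=0)
    med = np.full(n_grid, np.nan)
    p16 = np.full(n_grid, np.nan)
    p84 = np.full(n_grid, np.nan)
    has = n_valid > 0
    if not np.all(has | ~covered):
        warnings.warn("some covered gridsteps retained zero valid draws", stacklevel=2)
    if has.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q = np.nanpercentile(pco2[:, has], [16.0, 50.0, 84.0], axis=0)  # type-7
        p16[has], med[has], p84[has] = q[0], q[1], q[2]
    return PCO2Reconstruction(grid, med, p16, p84, n_valid, n_draws, seed)


def report_interval(recon: PCO2Reconstruction, age: float) -> tuple[float, float, float]:
    """(median, +error, −error) at an age; off-grid ages snap with a warning."""
    i = int(np.argmin(np.abs(recon.age_grid - age)))
    step = float(np.median(np.abs(np.diff(recon.age_grid)))) if len(recon.age_grid) > 1 else 0.0
    if abs(recon.age_grid[i] - age) > 0.5001 * step:
        warnings.warn(
            f"age {age} Ma is off-grid; using nearest gridpoint {recon.age_grid[i]} Ma",
            stacklevel=2,
        )
    return (
        float(recon.median[i]),
        float(recon.p84[i] - recon.median[i]),
        float(recon.median[i] - recon.p16[i]),
    )


def _scale_anomaly(stack: StackedCurve, ref_i: int, target_excursion: float, peak_fn) -> StackedCurve:
    ref = stack.center[ref_i]
    current = peak_fn(stack.center) - ref
    if current == 0:
        raise ValueError("stack has no excursion to rescale")
    scale = target_excursion / current
    return StackedCurve(
        stack.age_grid, ref + (stack.center - ref) * scale, stack.se, stack.n_local, stack.span
    )


def sensitivity_sweep(
    plant_stack: StackedCurve,
    carb_stack: StackedCurve,
    sst_stack: StackedCurve,
    parameter: str,
    values,
    params: ProxyParams | None = None,
    n_draws: int = 2_000,
    seed: int = 0,
    **mc_kwargs,
) -> pd.DataFrame:
    """One-at-a-time sweep of a proxy input; all else (and the seed) fixed.

    ``parameter`` ∈ {'B', 'pco2_ref', 'd13c_p_ref', 'carb_cie',
    'sst_rise'}.  For the two excursion parameters the corresponding
    stack anomaly (relative to the reference gridstep) is rescaled to the
    requested excursion.  Returns a table of (value, peak_median,
    band_width) where peak_median is the maximum gridstep median and
    band_width is p84 − p16 at that gridstep.
    """
    p = params if params is not None else ProxyParams()
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown parameter {parameter!r}; choose from {SWEEPABLE}")
    ref_i = _reference_index(plant_stack, carb_stack, sst_stack)
    rows = []
    for v in values:
        ps, cs, ss, pp = plant_stack, carb_stack, sst_stack, p
        if parameter == "B":
            pp = replace(p, b=float(v))
        elif parameter == "pco2_ref":
            pp = replace(p, pco2_ref=float(v))
        elif parameter == "d13c_p_ref":
            pp = replace(p, d13c_p_ref=float(v))
        elif parameter == "carb_cie":
            cs = _scale_anomaly(carb_stack, ref_i, float(v), np.nanmin)
        elif parameter == "sst_rise":
            ss = _scale_anomaly(sst_stack, ref_i, float(v), np.nanmax)
        recon = mc_reconstruct(ps, cs, ss, pp, n_draws=n_draws, seed=seed, **mc_kwargs)
        i_peak = int(np.nanargmax(recon.median))
        rows.append(
            {
                "value": float(v),
                "peak_median": float(recon.median[i_peak]),
                "band_width": float(recon.p84[i_peak] - recon.p16[i_peak]),
            }
        )
    return pd.DataFrame(rows)
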