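"""Carbon-isotope mass balance of the excursion and climate metrics.

A single-box mass balance attributes a negative carbon isotope excursion
of magnitude CIE (‰, negative) in a surface reservoir of mass
M_background (Gt C) and composition δ13C_background to the addition of
isotopically light carbon:

    M_added = (−CIE · M_background) / (δ13C_peak − δ13C_added)

with δ13C_peak = δ13C_background + CIE.  Candidate sources span volcanic
CO2 (−6‰), oxidised organic matter (−25‰), thermogenic methane (−40‰)
and biogenic methane hydrate (−60‰).  The implied atmospheric rise uses
the Earth-system scaling 1 Gt C = 0.3 ppmv, and each scenario is placed
below / within / above the proxy's asymmetric 68% pCO2-rise band.

Climate metrics: Earth system sensitivity ESS = ΔT / log2(pCO2_peak /
pCO2_background) (°C per CO2 doubling), and the Pearson correlation of
the reconstructed median pCO2 against the stacked SST.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .montecarlo import PCO2Reconstruction
from .stacking import StackedCurve

__all__ = [
    "MassBalanceScenario",
    "ClimateMetrics",
    "mass_added",
    "ppmv_rise",
    "scenario_table",
    "compare_with_proxy",
    "earth_system_sensitivity",
    "pco2_sst_correlation",
    "DEFAULT_SOURCES",
    "DEFAULT_RESERVOIRS",
    "PPMV_PER_GT",
]

PPMV_PER_GT = 0.3  # ppmv CO2 per Gt C added
DEFAULT_SOURCES = (-6.0, -25.0, -40.0, -60.0)  # permil: volcanic, organic, thermogenic, biogenic
DEFAULT_RESERVOIRS = (66_000.0, 82_000.0)  # Gt C, background DIC reservoir bounds
DEFAULT_D13C_BACKGROUND = 2.2  # permil, pre-event DIC composition


@dataclass(frozen=True)
class MassBalanceScenario:
    cie: float  # permil, negative
    m_background: float  # Gt C
    d13c_background: float  # permil
    d13c_added: float  # permil
    m_added: float  # Gt C (NaN if infeasible)
    feasible: bool = True

    @property
    def d13c_peak(self) -> float:
        return self.d13c_background + self.cie

    @property
    def ppmv_rise(self) -> float:
        return ppmv_rise(self.m_added) if self.feasible else float("nan")


@dataclass(frozen=True)
class ClimateMetrics:
    ess: float  # degC per CO2 doubling
    delta_t: float
    pco2_peak: float
    pco2_background: float
    r_pco2_sst: float
    p_value: float
    n_pairs: int


def mass_added(
    cie: float,
    m_background: float,
    d13c_background: float = DEFAULT_D13C_BACKGROUND,
    d13c_added: float = -25.0,
) -> float:
    """Mass of added carbon (Gt C) required to produce the excursion.

    Requires a negative CIE and a source lighter than the post-event
    reservoir (δ13C_added < δ13C_peak); otherwise no finite positive mass
    can generate the excursion.
    """
    if cie >= 0:
        raise ValueError(f"CIE must be negative; got {cie}")
    if m_background <= 0:
        raise ValueError("m_background must be positive")
    d13c_peak = d13c_background + cie
    if d13c_added >= d13c_peak:
        raise ValueError(
            f"source at {d13c_added} permil is not lighter than the post-event "
            f"reservoir ({d13c_peak} permil): source cannot produce a negative CIE"
        )
    return (-cie * m_background) / (d13c_peak - d13c_added)


def ppmv_rise(m_added: float) -> float:
    """Atmospheric pCO2 rise (ppmv) from added carbon at 1 Gt C = 0.3 ppmv."""
    if m_added < 0:
        raise ValueError("m_added must be >= 0")
    return PPMV_PER_GT * m_added


def scenario_table(
    cie_grid=tuple(np.arange(-1.0, -8.5, -0.5)),
    sources=DEFAULT_SOURCES,
    reservoirs=DEFAULT_RESERVOIRS,
    d13c_background: float = DEFAULT_D13C_BACKGROUND,
) -> pd.DataFrame:
    """Full cross-product of CIE magnitudes × sources × reservoir sizes.

    Rows whose source is not lighter than the post-event reservoir are
    kept but flagged infeasible (m_added, ppmv_rise = NaN) rather than
    dropped silently.
    """
    if not (len(tuple(cie_grid)) and len(tuple(sources)) and len(tuple(reservoirs))):
        raise ValueError("cie_grid, sources and reservoirs must be non-empty")
    rows = []
    for cie, src, m_bg in product(cie_grid, sources, reservoirs):
        try:
            m = mass_added(cie, m_bg, d13c_background, src)
            rows.append((cie, src, m_bg, m, ppmv_rise(m), True))
        except ValueError:
            rows.append((cie, src, m_bg, np.nan, np.nan, False))
    return pd.DataFrame(
        rows,
        columns=["cie_permil", "source_permil", "m_background_gt", "m_added_gt", "ppmv_rise", "feasible"],
    )


def compare_with_proxy(
    table: pd.DataFrame, rise_median: float, neg_err: float, pos_err: float
) -> pd.DataFrame:
    """Classify each scenario against the proxy's asymmetric 68% rise band.

    The band is [median − neg_err, median + pos_err]; classification is
    'below', 'within' or 'above' (infeasible rows get 'infeasible').
    """
    lo, hi = rise_median - neg_err, rise_median + pos_err
    if not lo <= rise_median <= hi:
        raise ValueError("band is invalid: need low <= mid <= high")
    out = table.copy()
    r = out["ppmv_rise"]
    out["band_flag"] = np.select(
        [~out["feasible"], r < lo, r > hi], ["infeasible", "below", "above"], default="within"
    )
    return out


def earth_system_sensitivity(delta_t: float, pco2_peak: float, pco2_background: float) -> float:
    """ESS = ΔT / log2(pCO2_peak / pCO2_background), °C per CO2 doubling."""
    if pco2_peak <= 0 or pco2_background <= 0:
        raise ValueError("pCO2 values must be positive")
    if pco2_peak == pco2_background:
        raise ValueError("peak and background pCO2 must differ")
    return delta_t / np.log2(pco2_peak / pco2_background)


def pco2_sst_correlation(recon: PCO2Reconstruction, sst_stack: StackedCurve) -> dict:
    """Pearson correlation of median pCO2 vs. stacked SST on the shared grid.

    Missing gridsteps on either side are dropped.  Constant inputs make r
    undefined; reported as not-computable instead of raised.
    """
    if len(recon.age_grid) != len(sst_stack.age_grid) or not np.allclose(
        recon.age_grid, sst_stack.age_grid
    ):
        raise ValueError("reconstruction and SST stack must share the age grid")
    x = recon.median
    y = sst_stack.center
    ok = np.isfinite(x) & np.isfinite(y) & (sst_stack.n_local > 0) & (recon.n_valid > 0)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 paired gridsteps; got {n}")
    if np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
        return {"computable": False, "reason": "constant input", "n": n}
    r, p = stats.pearsonr(x[ok], y[ok])
    return {"computable": True, "r": float(r), "p": float(p), "n": n}
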