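"""Closed-form C3-plant carbon-isotope proxy for atmospheric pCO2.

Photosynthetic fractionation in C3 plants, Δ13C, increases hyperbolically
with the CO2 mixing ratio:

    Δ13C(pCO2) = A·B·(pCO2 + C) / (A + B·(pCO2 + C))

with curve parameters A (the saturation fractionation, ‰), B (curvature)
and C = A·4.4/((A − 4.4)·B), which pins Δ13C(0) = 4.4‰, the diffusive
fractionation floor.  Because absolute δ13C_p can carry diagenetic and
preparation offsets, the proxy is inverted on the *relative* change

    Δ(Δ13C) = Δ13C(t) − Δ13C(t=0)

between the time of interest and a pre-event reference, which cancels any
constant offset.  Solving the hyperbola difference for pCO2(t) gives a
rational expression whose denominator vanishes when the demanded
fractionation meets the asymptote A; such draws are flagged invalid rather
than raised, so the Monte Carlo layer can count and drop them.

Atmospheric δ13C_CO2 is obtained from marine carbonate via δ13C_DIC =
δ13C_carb − 1‰ and a temperature-dependent DIC/CO2 fractionation (an
abundance-weighted mix of the bicarbonate and carbonate-ion terms).

All δ values are ‰ VPDB floats throughout; pCO2 is ppmv.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProxyParams",
    "AtmosState",
    "compute_c",
    "frac_forward",
    "big_delta",
    "d13c_dic_from_carb",
    "d13c_co2_from_dic",
    "delta_delta",
    "invert_pco2",
]

#: Diffusive fractionation at pCO2 = 0, ‰ (built into C).
DIFFUSIVE_FLOOR = 4.4

#: Sanity bounds for sea-surface temperature, °C.
SST_SANITY_BOUNDS = (-5.0, 60.0)

#: Carbonate-to-DIC carbon isotope offset, ‰ (temperature independent).
CARB_DIC_OFFSET = 1.0


def compute_c(a, b):
    """Curve parameter C = A·4.4/((A − 4.4)·B), in ppmv.

    Accepts scalars or arrays (the Monte Carlo layer samples B per draw).

    Raises
    ------
    ValueError
        If any ``a <= 4.4`` (the hyperbola would not reach the diffusive
        floor) or any ``b <= 0``.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any(a_arr <= DIFFUSIVE_FLOOR):
        raise ValueError(f"parameter A must exceed {DIFFUSIVE_FLOOR}; got A={a}")
    if np.any(b_arr <= 0):
        raise ValueError(f"parameter B must be positive; got B={b}")
    out = a_arr * DIFFUSIVE_FLOOR / ((a_arr - DIFFUSIVE_FLOOR) * b_arr)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProxyParams:
    """Proxy constants with 1σ uncertainties.

    Defaults are the curve fit A = 28.26 ± 0, B = 0.22 ± 0.028, the
    stomatal pre-event baseline pCO2(t=0) = 425 ± 68 ppmv and the
    pre-event plant baseline δ13C_p(t=0) = −24.42 ± 0.5‰.  A's sd is
    exactly zero but A is still treated as a samplable parameter (with
    zero variance) for uniformity in the Monte Carlo layer.
    """

    a: float = 28.26
    a_sd: float = 0.0
    b: float = 0.22
    b_sd: float = 0.028
    pco2_ref: float = 425.0
    pco2_ref_sd: float = 68.0
    d13c_p_ref: float = -24.42
    d13c_p_ref_sd: float = 0.5

    def __post_init__(self) -> None:
        compute_c(self.a, self.b)  # validates a, b
        if self.pco2_ref <= 0:
            raise ValueError(f"pco2_ref must be positive; got {self.pco2_ref}")
        for name in ("a_sd", "b_sd", "pco2_ref_sd", "d13c_p_ref_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def c(self) -> float:
        """Derived curve parameter C, ppmv."""
        return compute_c(self.a, self.b)


@dataclass(frozen=True)
class AtmosState:
    """Atmospheric/marine isotopic state at one instant (all with 1σ sd)."""

    d13c_co2: float
    d13c_co2_sd: float = 0.0
    d13c_dic: float = 0.0
    d13c_dic_sd: float = 0.0
    sst: float = 25.0
    sst_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d13c_co2_sd", "d13c_dic_sd", "sst_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def frac_forward(pco2, a: float = 28.26, b: float = 0.22):
    """Δ13C (‰) predicted by the hyperbola at ``pco2`` (ppmv).

    Strictly increasing in pCO2, equal to 4.4‰ at pCO2 = 0 and bounded
    above by the asymptote A.  Vectorised over ``pco2``.
    """
    pco2 = np.asarray(pco2, dtype=float)
    if np.any(pco2 < 0):
        raise ValueError("pco2 must be >= 0")
    c = compute_c(a, b)
    bpc = b * (pco2 + c)
    out = a * bpc / (a + bpc)
    return float(out) if out.ndim == 0 else out


def big_delta(d13c_co2, d13c_p):
    """Fractionation Δ13C = (δ13C_CO2 − δ13C_p)/(1 + δ13C_p/1000), ‰.

    Zero iff the two compositions are equal.  Vectorised.
    """
    d13c_co2 = np.asarray(d13c_co2, dtype=float)
    d13c_p = np.asarray(d13c_p, dtype=float)
    if np.any(d13c_p <= -1000):
        raise ValueError("d13c_p must exceed -1000 permil")
    out = (d13c_co2 - d13c_p) / (1.0 + d13c_p / 1000.0)
    return float(out) if out.ndim == 0 else out


def d13c_dic_from_carb(d13c_carb):
    """δ13C of DIC from marine carbonate: subtract the constant 1‰ offset."""
    out = np.asarray(d13c_carb, dtype=float) - CARB_DIC_OFFSET
    return float(out) if out.ndim == 0 else out


def d13c_co2_from_dic(d13c_dic, sst, *, sst_bounds=SST_SANITY_BOUNDS):
    """δ13C of atmospheric CO2 from δ13C_DIC and SST (°C).

    δ13C_CO2 = δ13C_DIC − [0.91·(−0.1141·T + 10.78) + 0.08·(−0.052·T + 7.22)]

    The bracket is the DIC–CO2 fractionation: 10.3874‰ at 0 °C, shrinking
    by 0.107991‰ per °C.  SSTs outside ``sst_bounds`` trigger a warning
    (they are sanity bounds, not physics) but the value is still returned.
    """
    d13c_dic = np.asarray(d13c_dic, dtype=float)
    sst = np.asarray(sst, dtype=float)
    lo, hi = sst_bounds
    if np.any((sst < lo) | (sst > hi)):
        warnings.warn(
            f"SST outside sanity bounds [{lo}, {hi}] degC; value computed anyway",
            stacklevel=2,
        )
    eps = 0.91 * (-0.1141 * sst + 10.78) + 0.08 * (-0.052 * sst + 7.22)
    out = d13c_dic - eps
    return float(out) if out.ndim == 0 else out


def delta_delta(d13c_co2_t, d13c_p_t, d13c_co2_ref, d13c_p_ref):
    """Δ(Δ13C) = Δ13C(t) − Δ13C(t=0), ‰; antisymmetric under t ↔ ref."""
    return big_delta(d13c_co2_t, d13c_p_t) - big_delta(d13c_co2_ref, d13c_p_ref)


def invert_pco2(ddc, pco2_ref, a: float = 28.26, b: float = 0.22):
    """Invert Δ(Δ13C) (‰) to pCO2(t) (ppmv) given the reference pCO2.

    Evaluates the rational rearrangement of the hyperbola difference; it
    is the exact algebraic inverse of ``frac_forward(p) −
    frac_forward(pco2_ref)`` on the valid branch.

    Returns
    -------
    (pco2_t, valid)
        ``pco2_t`` carries NaN where ``valid`` is False, i.e. where the
        denominator A²B − ddc·A·B − ddc·B²·pco2_ref − ddc·B²·C is ≤ 0
        (fractionation at or beyond the proxy asymptote).  Scalar inputs
        yield scalars.
    """
    ddc = np.asarray(ddc, dtype=float)
    pco2_ref = np.asarray(pco2_ref, dtype=float)
    c = compute_c(a, b)
    num = (
        ddc * a**2
        + ddc * a * b * pco2_ref
        + 2.0 * ddc * a * b * c
        + ddc * b**2 * c * pco2_ref
        + ddc * b**2 * c**2
        + a**2 * b * pco2_ref
    )
    den = a**2 * b - ddc * a * b - ddc * b**2 * pco2_ref - ddc * b**2 * c
    valid = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(valid, num / np.where(valid, den, 1.0), np.nan)
    if out.ndim == 0:
        return float(out), bool(valid)
    return out, valid
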