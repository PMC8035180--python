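"""Synthetic multi-section isotope records with a known true history.

The generator fabricates the kind of dataset the reconstruction consumes —
several stratigraphic sections of plant δ13C, marine-carbonate δ13C and
SST, scattered unevenly in age — from a prescribed "true" history of
atmospheric pCO2, carbonate δ13C and sea-surface temperature.  The true
history follows the canonical four-stage anatomy of a negative carbon
isotope excursion (CIE): a pre-event plateau, a rapid onset ramp (default
75 kyr), an elevated excursion body, and a recovery stage.

Default levels mirror the Permian–Triassic event: pCO2 ramping from
425 to 2507 ppmv, a −3.5‰ carbonate CIE from a +2.2‰ background, and a
+10 °C SST rise co-timed with the pCO2 ramp.  Plant δ13C is not free:
it is forward-modelled from the truth through the proxy equations, so the
plant CIE comes out amplified (≈ −7‰) relative to the carbonate CIE — the
signature the reconstruction exploits.

Trajectories are piecewise linear in time; injection is prescribed, not
modelled (no carbon-cycle dynamics, no facies realism).  Ages are Ma
before present, decreasing toward younger; grids are half-open on the
young end and integer-indexed to avoid float-step accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .proxy import (
    ProxyParams,
    big_delta,
    d13c_co2_from_dic,
    d13c_dic_from_carb,
    frac_forward,
)

__all__ = [
    "StageConfig",
    "SamplingPlan",
    "TrueHistory",
    "generate_true_history",
    "forward_model_plant_d13c",
    "sample_sections",
    "truth_frame",
    "generate_dataset",
]

STAGES = ("pre_cie", "onset", "body", "post_cie")


@dataclass(frozen=True)
class StageConfig:
    """Stage boundaries (Ma) and endpoint levels of the true history.

    Ages decrease toward younger rocks; the three boundaries split the
    span into pre-CIE / onset / body / post-CIE.  The default onset
    duration is 75 kyr.  ``pco2_dip`` switches on a single transient
    drop (to ``pco2_dip_level``) in the middle of the body stage.
    """

    age_old: float = 252.30
    boundary_pre_onset: float = 252.10
    boundary_onset_body: float = 252.025
    boundary_body_post: float = 251.90
    age_young: float = 251.80
    grid_step: float = 0.002

    pco2_background: float = 425.0
    pco2_peak: float = 2507.0
    pco2_recovery: float = 700.0

    d13c_carb_background: float = 2.2
    carb_cie: float = -3.5
    d13c_carb_recovery: float = 0.5

    sst_background: float = 25.0
    sst_rise: float = 10.0
    sst_recovery: float = 30.0

    pco2_dip: bool = False
    pco2_dip_level: float = 1300.0

    def __post_init__(self) -> None:
        b = (
            ("age_old", self.age_old),
            ("boundary_pre_onset", self.boundary_pre_onset),
            ("boundary_onset_body", self.boundary_onset_body),
            ("boundary_body_post", self.boundary_body_post),
            ("age_young", self.age_young),
        )
        for (n1, a1), (n2, a2) in zip(b, b[1:]):
            if not a1 > a2:
                raise ValueError(
                    f"stage boundaries misordered: {n2}={a2} must be strictly "
                    f"younger (smaller age) than {n1}={a1}"
                )
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        for name in ("pco2_background", "pco2_peak", "pco2_recovery"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return (
            self.boundary_pre_onset,
            self.boundary_onset_body,
            self.boundary_body_post,
        )


@dataclass(frozen=True)
class SamplingPlan:
    """How the true history is sampled into noisy section records.

    Section counts default to the study layout: four terrestrial plant
    sections, ten marine carbonate sections, five SST localities.  Noise
    is i.i.d. Gaussian per measurement (analytical plus geological
    scatter, no autocorrelation); ``seed`` fixes the whole dataset
    bit-for-bit.
    """

    n_plant_sections: int = 4
    n_carb_sections: int = 10
    n_sst_sections: int = 5
    samples_per_section: int = 40
    age_jitter: float = 0.005
    noise_sd_plant: float = 0.5
    noise_sd_carb: float = 0.3
    noise_sd_sst: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_section < 2:
            raise ValueError("samples_per_section must be >= 2")
        for name in ("noise_sd_plant", "noise_sd_carb", "noise_sd_sst"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.age_jitter < 0:
            raise ValueError("age_jitter must be >= 0")


@dataclass(frozen=True)
class TrueHistory:
    """True pCO2 / carbonate δ13C / SST trajectories on a regular age grid."""

    age_grid: np.ndarray  # Ma, strictly decreasing
    pco2_true: np.ndarray  # ppmv
    d13c_carb_true: np.ndarray  # permil VPDB
    sst_true: np.ndarray  # degC
    config: StageConfig

    def __post_init__(self) -> None:
        n = len(self.age_grid)
        if not (len(self.pco2_true) == len(self.d13c_carb_true) == len(self.sst_true) == n):
            raise ValueError("all truth arrays must have equal length")
        if not np.all(np.diff(self.age_grid) < 0):
            raise ValueError("age_grid must be strictly decreasing (young toward the end)")
        if np.any(self.pco2_true <= 0):
            raise ValueError("pco2_true must be positive everywhere")

    def stage_labels(self) -> np.ndarray:
        """Stage of each gridpoint; a boundary age belongs to the older stage."""
        b1, b2, b3 = self.config.boundaries
        return np.where(
            self.age_grid >= b1,
            "pre_cie",
            np.where(
                self.age_grid >= b2, "onset", np.where(self.age_grid >= b3, "body", "post_cie")
            ),
        ).astype(str)


def _age_grid(cfg: StageConfig) -> np.ndarray:
    n = int(round((cfg.age_old - cfg.age_young) / cfg.grid_step))
    return cfg.age_old - cfg.grid_step * np.arange(n)


def _piecewise(age: np.ndarray, cfg: StageConfig, background: float, peak: float,
               recovery: float) -> np.ndarray:
    """Piecewise-linear trajectory: plateau, ramp, hold, linear recovery."""
    b1, b2, b3 = cfg.boundaries
    # breakpoint ages (decreasing) and levels
    knots_age = np.array([cfg.age_old, b1, b2, b3, cfg.age_young])
    knots_val = np.array([background, background, peak, peak, recovery])
    # np.interp wants increasing x: use elapsed time
    t = cfg.age_old - age
    return np.interp(t, cfg.age_old - knots_age, knots_val)


def generate_true_history(config: StageConfig | None = None) -> TrueHistory:
    """Build the true history on the regular grid from a stage configuration."""
    cfg = config if config is not None else StageConfig()
    age = _age_grid(cfg)
    pco2 = _piecewise(age, cfg, cfg.pco2_background, cfg.pco2_peak, cfg.pco2_recovery)
    carb = _piecewise(
        age,
        cfg,
        cfg.d13c_carb_background,
        cfg.d13c_carb_background + cfg.carb_cie,
        cfg.d13c_carb_recovery,
    )
    sst = _piecewise(
        age, cfg, cfg.sst_background, cfg.sst_background + cfg.sst_rise, cfg.sst_recovery
    )
    if cfg.pco2_dip:
        # one triangular transient drop centred mid-body, 20% of body duration wide
        b2, b3 = cfg.boundary_onset_body, cfg.boundary_body_post
        mid = 0.5 * (b2 + b3)
        half_w = 0.1 * (b2 - b3)
        w = np.clip(1.0 - np.abs(age - mid) / half_w, 0.0, 1.0)
        pco2 = pco2 + w * (cfg.pco2_dip_level - pco2)
    return TrueHistory(age, pco2, carb, sst, cfg)


def forward_model_plant_d13c(truth: TrueHistory, params: ProxyParams | None = None) -> np.ndarray:
    """Plant δ13C implied by the truth through the proxy chain.

    δ13C_CO2 comes from the carbonate truth (DIC = carb − 1‰) and SST;
    Δ13C comes from the pCO2 truth through the hyperbola; then

        δ13C_p = (δ13C_CO2 − Δ13C) / (1 + Δ13C/1000)

    which is the exact algebraic inverse of the Δ13C definition, so the
    reconstruction round-trips to the true pCO2 on noise-free data.
    """
    p = params if params is not None else ProxyParams()
    d13c_co2 = d13c_co2_from_dic(d13c_dic_from_carb(truth.d13c_carb_true), truth.sst_true)
    delta = frac_forward(truth.pco2_true, p.a, p.b)
    return (d13c_co2 - delta) / (1.0 + delta / 1000.0)


def _section_ages(rng: np.random.Generator, cfg: StageConfig, n: int, jitter: float) -> np.ndarray:
    """Uneven sample ages: stratified uniform draws plus Gaussian jitter."""
    edges = np.linspace(cfg.age_young, cfg.age_old, n + 1)
    ages = rng.uniform(edges[:-1], edges[1:])
    if jitter > 0:
        ages = ages + rng.normal(0.0, jitter, size=n)
    ages = np.clip(ages, cfg.age_young, cfg.age_old)
    return np.sort(ages)[::-1]


def sample_sections(
    truth: TrueHistory,
    plant_d13c: np.ndarray,
    plan: SamplingPlan | None = None,
) -> pd.DataFrame:
    """Draw noisy per-section samples from the truth curves.

    Returns the pipeline's sample table: columns ``section_id``,
    ``substrate`` (plant_cuticle | plant_wood | carbonate | sst),
    ``age_ma``, ``value``, ``sd``.  Values are linear interpolations of
    the true curves at unevenly spaced ages plus i.i.d. Gaussian noise;
    fully deterministic under the plan's seed.
    """
    plan = plan if plan is not None else SamplingPlan()
    rng = np.random.default_rng(plan.seed)
    cfg = truth.config
    t_grid = cfg.age_old - truth.age_grid  # increasing

    def interp(curve: np.ndarray, ages: np.ndarray) -> np.ndarray:
        return np.interp(cfg.age_old - ages, t_grid, curve)

    rows: list[pd.DataFrame] = []

    def emit(section_id: str, substrate_of, curve: np.ndarray, sd: float) -> None:
        ages = _section_ages(rng, cfg, plan.samples_per_section, plan.age_jitter)
        vals = interp(curve, ages)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=len(ages))
        sub = substrate_of(rng, len(ages))
        rows.append(
            pd.DataFrame(
                {
                    "section_id": section_id,
                    "substrate": sub,
                    "age_ma": ages,
                    "value": vals,
                    "sd": sd,
                }
            )
        )

    plant_mix = lambda rng, n: rng.choice(["plant_cuticle", "plant_wood"], size=n)
    for i in range(plan.n_plant_sections):
        emit(f"plant_{i + 1:02d}", plant_mix, plant_d13c, plan.noise_sd_plant)
    const = lambda name: (lambda rng, n: np.full(n, name))
    for i in range(plan.n_carb_sections):
        emit(f"carb_{i + 1:02d}", const("carbonate"), truth.d13c_carb_true, plan.noise_sd_carb)
    for i in range(plan.n_sst_sections):
        emit(f"sst_{i + 1:02d}", const("sst"), truth.sst_true, plan.noise_sd_sst)

    return pd.concat(rows, ignore_index=True)


def truth_frame(truth: TrueHistory) -> pd.DataFrame:
    """Truth table written alongside the samples, for downstream oracles."""
    return pd.DataFrame(
        {
            "age_ma": truth.age_grid,
            "pco2_true": truth.pco2_true,
            "d13c_carb_true": truth.d13c_carb_true,
            "sst_true": truth.sst_true,
        }
    )


def generate_dataset(
    config: StageConfig | None = None,
    plan: SamplingPlan | None = None,
    params: ProxyParams | None = None,
) -> tuple[TrueHistory, pd.DataFrame]:
    """One-call convenience: truth, forward-modelled plants, sampled sections."""
    truth = generate_true_history(config)
    plant = forward_model_plant_d13c(truth, params)
    samples = sample_sections(truth, plant, plan)
    return truth, samples
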