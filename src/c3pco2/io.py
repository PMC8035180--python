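"""CSV dialects and run configuration.

All tables are plain UTF-8 CSV with one header row and decimal points;
floats are written at full repr precision so write-then-read round-trips
exactly.  Dialects:

samples:         section_id, substrate, age_ma, value, sd
truth:           age_ma, pco2_true, d13c_carb_true, sst_true
stacked curve:   age_ma, center, se, n_local, span
reconstruction:  age_ma, median_ppmv, p16_ppmv, p84_ppmv, n_valid

The run configuration is YAML; every constant defaults to the standard
value (A 28.26, B 0.22 ± 0.028, pCO2(t=0) 425 ± 68 ppmv, δ13C_p(t=0)
−24.42 ± 0.5‰, 0.002 Myr grid, 10,000 draws, validity bounds (0, 10⁶]
ppmv, DIC offset 1.0‰, 0.3 ppmv per Gt C) and the parsed config is
echoed verbatim into the output directory.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montecarlo import PCO2Reconstruction
from .stacking import StackedCurve

__all__ = [
    "default_config",
    "load_config",
    "config_hash",
    "read_samples",
    "write_samples",
    "read_stack",
    "write_stack",
    "read_recon",
    "write_recon",
]

SUBSTRATES = ("plant_cuticle", "plant_wood", "bulk_om", "carbonate", "sst")

SAMPLE_COLUMNS = ("section_id", "substrate", "age_ma", "value", "sd")
STACK_COLUMNS = ("age_ma", "center", "se", "n_local", "span")
RECON_COLUMNS = ("age_ma", "median_ppmv", "p16_ppmv", "p84_ppmv", "n_valid")


def default_config() -> dict:
    return {
        "synthetic": {"stage": {}, "plan": {}},
        "proxy": {
            "a": 28.26,
            "a_sd": 0.0,
            "b": 0.22,
            "b_sd": 0.028,
            "pco2_ref": 425.0,
            "pco2_ref_sd": 68.0,
            "d13c_p_ref": -24.42,
            "d13c_p_ref_sd": 0.5,
        },
        "stacking": {"grid_step": 0.002, "span": None, "k_folds": 5},
        "mc": {
            "n_draws": 10_000,
            "seed": 0,
            "lower_bound": 0.0,
            "upper_bound": 1.0e6,
            "plant_ref": "stack",
        },
        "massbalance": {
            "cie_grid": [-1.0, -2.0, -3.0, -3.5, -4.0, -5.0, -6.0, -7.0, -8.0],
            "sources": [-6.0, -25.0, -40.0, -60.0],
            "reservoirs": [66_000.0, 82_000.0],
            "d13c_background": 2.2,
        },
        "inputs": {"samples": None},
        "output_dir": "c3pco2_out",
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML file, then validated."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        cfg = _merge(cfg, user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    mc = cfg["mc"]
    if not isinstance(mc["n_draws"], int) or mc["n_draws"] < 100:
        raise ValueError(f"mc.n_draws must be an integer >= 100; got {mc['n_draws']}")
    if not 0 <= mc["lower_bound"] < mc["upper_bound"]:
        raise ValueError("mc bounds must satisfy 0 <= lower < upper")
    if mc["plant_ref"] not in ("stack", "params"):
        raise ValueError("mc.plant_ref must be 'stack' or 'params'")
    if cfg["stacking"]["grid_step"] <= 0:
        raise ValueError("stacking.grid_step must be positive")


def config_hash(cfg: dict) -> str:
    """Stable short hash of the canonicalised configuration."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _require_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric value(s) in '{c}' at file row(s) {rows}")
        df[c] = coerced
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SAMPLE_COLUMNS, path)
    df = _require_numeric(df, ("age_ma", "value", "sd"), path)
    bad = set(df["substrate"]) - set(SUBSTRATES)
    if bad:
        raise ValueError(f"{path}: unknown substrate(s) {sorted(bad)}")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, index=False)


def write_stack(stack: StackedCurve, path: str | Path) -> None:
    df = stack.frame()
    df["span"] = stack.span
    df.to_csv(path, index=False)


def read_stack(path: str | Path) -> StackedCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, STACK_COLUMNS, path)
    df = _require_numeric(df, STACK_COLUMNS[:-1], path)
    ages = df["age_ma"].to_numpy(float)
    if len(np.unique(ages)) != len(ages):
        dup = pd.Series(ages)[pd.Series(ages).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated gridpoint at age_ma={dup}")
    return StackedCurve(
        ages,
        df["center"].to_numpy(float),
        df["se"].to_numpy(float),
        df["n_local"].to_numpy(int),
        float(df["span"].iloc[0]),
    )


def write_recon(recon: PCO2Reconstruction, path: str | Path) -> None:
    recon.frame().to_csv(path, index=False)


def read_recon(path: str | Path, n_draws: int | None = None, seed: int = 0) -> PCO2Reconstruction:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, RECON_COLUMNS, path)
    df = _require_numeric(df, RECON_COLUMNS, path)
    n = int(df["n_valid"].max()) if n_draws is None else n_draws
    return PCO2Reconstruction(
        df["age_ma"].to_numpy(float),
        df["median_ppmv"].to_numpy(float),
        df["p16_ppmv"].to_numpy(float),
        df["p84_ppmv"].to_numpy(float),
        df["n_valid"].to_numpy(int),
        max(n, 1),
        seed,
    )
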