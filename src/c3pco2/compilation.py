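"""CIE-stage segmentation, excursion magnitudes and substrate statistics.

The carbon isotope excursion (CIE) is summarised per section as the
difference between the peak (most negative) value inside the excursion
and the background immediately before it:

    magnitude = δ13C_peak − δ13C_background

Background is a trailing mean over the last few pre-CIE samples (default
five; the literature definition — "immediately before" — names no window,
so the window length is a knob).  Peak is the raw pointwise minimum over
the onset and body stages; no smoothing is applied before picking it.

Group comparison across substrates (marine carbonate vs. terrestrial bulk
organic matter vs. plant tissue) uses the non-parametric Kruskal–Wallis
test across all groups and a two-sided Wilcoxon rank-sum (Mann–Whitney U)
test for marine vs. pooled terrestrial — exact for small groups, normal
approximation above 20 per group — plus quartile summaries per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IsotopeSeries",
    "CIEMagnitude",
    "assign_stages",
    "cie_magnitude",
    "compare_substrate_magnitudes",
]

STAGES = ("pre_cie", "onset", "body", "post_cie")

#: switch from the exact rank-sum null to the normal approximation above this n
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class IsotopeSeries:
    """Age-tagged measurements from one section and substrate.

    ``samples`` is a DataFrame with columns ``age_ma``, ``value``,
    optional ``sd`` (≥ 0) and optional ``stage``.
    """

    section_id: str
    substrate: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples
        for col in ("age_ma", "value"):
            if col not in df.columns:
                raise ValueError(f"samples must have a '{col}' column")
        if not np.all(np.isfinite(df["age_ma"])):
            raise ValueError("ages must be finite")
        if "sd" in df.columns and np.any(df["sd"].dropna() < 0):
            raise ValueError("sd must be >= 0 where present")
        if "stage" in df.columns:
            bad = set(df["stage"].dropna()) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stage labels: {sorted(bad)}")


@dataclass(frozen=True)
class CIEMagnitude:
    section_id: str
    substrate: str
    d13c_background: float
    d13c_peak: float

    @property
    def magnitude(self) -> float:
        return self.d13c_peak - self.d13c_background


def assign_stages(series: IsotopeSeries, boundaries) -> IsotopeSeries:
    """Label every sample with its CIE stage from three boundary ages.

    ``boundaries`` are (pre/onset, onset/body, body/post) ages in Ma,
    strictly decreasing.  A sample exactly on a boundary goes to the
    older (larger-age) stage.  Boundaries outside the sampled span are
    legal and produce the degenerate labelings (all post-CIE when the
    boundaries are older than every sample, all pre-CIE when younger).
    """
    b1, b2, b3 = boundaries
    if not (b1 > b2 > b3):
        raise ValueError(f"boundaries must be strictly decreasing in age; got {boundaries}")
    ages = series.samples["age_ma"].to_numpy()
    stage = np.where(
        ages >= b1, "pre_cie", np.where(ages >= b2, "onset", np.where(ages >= b3, "body", "post_cie"))
    )
    out = series.samples.copy()
    out["stage"] = stage
    return IsotopeSeries(series.section_id, series.substrate, out)


def cie_magnitude(series: IsotopeSeries, background_window: int = 5) -> CIEMagnitude:
    """CIE magnitude of one staged series: peak minus trailing background.

    Background is the mean of the youngest ``background_window`` pre-CIE
    samples; peak is the minimum value over onset ∪ body.  Negative for a
    negative excursion.  Raises if a required stage has no samples.
    """
    df = series.samples
    if "stage" not in df.columns:
        raise ValueError("series has no stage labels; run assign_stages first")
    pre = df[df["stage"] == "pre_cie"]
    exc = df[df["stage"].isin(("onset", "body"))]
    if len(pre) == 0:
        raise ValueError(f"section {series.section_id}: no pre_cie samples")
    if len(exc) == 0:
        raise ValueError(f"section {series.section_id}: no onset or body samples")
    tail = pre.sort_values("age_ma").tail(background_window)  # youngest pre-CIE
    background = float(tail["value"].mean())
    peak = float(exc["value"].min())
    return CIEMagnitude(series.section_id, series.substrate, background, peak)


def _quartiles(values: np.ndarray) -> dict:
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return {"q25": float(q25), "median": float(q50), "q75": float(q75), "n": int(len(values))}


def compare_substrate_magnitudes(groups: dict[str, list[float]], marine_key: str = "carbonate") -> dict:
    """Substrate comparison statistics for CIE magnitudes.

    Parameters
    ----------
    groups
        Mapping substrate → CIE magnitudes (‰), e.g. keys ``carbonate``,
        ``bulk_om``, ``plant``.  At least two groups of ≥ 2 values each.
    marine_key
        Which group is marine; all others are pooled as terrestrial for
        the two-group rank-sum test.

    Returns
    -------
    dict with keys ``kruskal`` (H, p), ``ranksum`` (U, p, method) for
    marine vs. pooled terrestrial, and ``quartiles`` per group.
    Degenerate groups (n < 2 or all values tied across groups) are
    reported as not-testable rather than raised.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least two substrate groups")
    report: dict = {"quartiles": {k: _quartiles(v) for k, v in clean.items() if len(v) > 0}}

    testable = {k: v for k, v in clean.items() if len(v) >= 2}
    pooled = np.concatenate(list(clean.values()))
    if len(testable) < 2 or np.all(pooled == pooled[0]):
        report["kruskal"] = {"testable": False, "reason": "degenerate groups (n<2 or all ties)"}
    else:
        h, p = stats.kruskal(*testable.values())
        report["kruskal"] = {"testable": True, "H": float(h), "p": float(p)}

    marine = clean.get(marine_key, np.empty(0))
    terr = np.concatenate([v for k, v in clean.items() if k != marine_key]) if len(clean) > 1 else np.empty(0)
    if len(marine) < 2 or len(terr) < 2 or (np.all(marine == marine[0]) and np.all(terr == marine[0])):
        report["ranksum"] = {"testable": False, "reason": "degenerate marine/terrestrial split"}
    else:
        method = "exact" if max(len(marine), len(terr)) <= EXACT_RANKSUM_MAX_N else "asymptotic"
        try:
            res = stats.mannwhitneyu(marine, terr, alternative="two-sided", method=method)
        except ValueError:
            # exact method refuses ties; fall back to the tie-corrected normal approximation
            method = "asymptotic"
            res = stats.mannwhitneyu(marine, terr, alternative="two-sided", method=method)
        report["ranksum"] = {
            "testable": True,
            "U": float(res.statistic),
            "p": float(res.pvalue),
            "method": method,
        }
    return report
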