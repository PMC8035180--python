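"""Tests for stage assignment, CIE magnitudes and substrate statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from c3pco2 import (
    IsotopeSeries,
    SamplingPlan,
    assign_stages,
    cie_magnitude,
    compare_substrate_magnitudes,
    sample_sections,
)


def make_series(ages, values, section="s1", substrate="carbonate"):
    return IsotopeSeries(section, substrate, pd.DataFrame({"age_ma": ages, "value": values}))


class TestAssignStages:
    def test_all_boundaries_older_gives_post_cie(self):
        s = make_series([250.0, 249.5, 249.0], [1.0, 2.0, 3.0])
        out = assign_stages(s, (252.1, 252.0, 251.9))
        assert (out.samples["stage"] == "post_cie").all()

    def test_boundary_sample_goes_to_older_stage(self):
        s = make_series([252.3, 252.1, 252.0, 251.9, 251.8], np.zeros(5))
        out = assign_stages(s, (252.1, 252.0, 251.9))
        assert list(out.samples["stage"]) == ["pre_cie", "pre_cie", "onset", "body", "post_cie"]

    def test_matches_generator_stages(self, truth):
        s = make_series(truth.age_grid, truth.d13c_carb_true)
        out = assign_stages(s, truth.config.boundaries)
        assert list(out.samples["stage"]) == list(truth.stage_labels())

    def test_misordered_boundaries_rejected(self):
        s = make_series([252.3, 251.8], [0.0, 0.0])
        with pytest.raises(ValueError, match="decreasing"):
            assign_stages(s, (252.0, 252.1, 251.9))

    def test_all_boundaries_younger_gives_pre_cie(self):
        s = make_series([252.3, 252.2], [0.0, 0.0])
        out = assign_stages(s, (251.0, 250.9, 250.8))
        assert (out.samples["stage"] == "pre_cie").all()


class TestCIEMagnitude:
    def test_reference_magnitude(self):
        ages = np.linspace(252.3, 251.9, 9)[::1]
        values = [-25.0] * 5 + [-28.0, -32.0, -30.0, -29.0]
        s = make_series(ages, values, substrate="plant_cuticle")
        out = assign_stages(s, (252.125, 252.05, 251.92))
        m = cie_magnitude(out)
        assert m.d13c_background == pytest.approx(-25.0)
        assert m.d13c_peak == pytest.approx(-32.0)
        assert m.magnitude == pytest.approx(-7.0)

    def test_flat_series_zero_magnitude(self):
        s = make_series(np.linspace(252.3, 251.9, 20), np.full(20, 2.2))
        m = cie_magnitude(assign_stages(s, (252.2, 252.1, 252.0)))
        assert m.magnitude == 0.0

    def test_noise_free_synthetic_carbonate_recovers_configured_cie(
        self, truth, noisefree_samples
    ):
        carb = noisefree_samples[noisefree_samples.section_id == "carb_01"]
        s = IsotopeSeries("carb_01", "carbonate", carb.reset_index(drop=True))
        m = cie_magnitude(assign_stages(s, truth.config.boundaries))
        assert m.magnitude == pytest.approx(-3.5, abs=1e-9)

    def test_missing_stage_rejected_by_name(self):
        s = make_series([252.3, 252.25], [1.0, 1.0])
        out = assign_stages(s, (252.24, 252.1, 252.0))  # everything pre-CIE
        with pytest.raises(ValueError, match="onset"):
            cie_magnitude(out)

    @given(st.floats(-50, 50))
    def test_translation_equivariance(self, c):
        ages = np.linspace(252.3, 251.9, 12)
        values = np.concatenate([np.full(6, -25.0), np.linspace(-26, -31, 6)])
        s1 = make_series(ages, values)
        s2 = make_series(ages, values + c)
        b = (252.15, 252.0, 251.91)
        m1 = cie_magnitude(assign_stages(s1, b))
        m2 = cie_magnitude(assign_stages(s2, b))
        assert m1.magnitude == pytest.approx(m2.magnitude, abs=1e-9)


def exhaustive_ranksum_p(group_a, group_b):
    """Two-sided rank-sum p by enumerating every label assignment."""
    pooled = np.asarray(list(group_a) + list(group_b), dtype=float)
    na = len(group_a)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:na].sum()
    sums = [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), na)]
    sums = np.asarray(sums)
    mean = sums.mean()
    # two-sided: assignments at least as extreme (in |deviation|) as observed
    return float(np.mean(np.abs(sums - mean) >= np.abs(observed - mean) - 1e-12))


class TestCompareSubstrates:
    def test_identical_groups_p_one(self):
        rep = compare_substrate_magnitudes(
            {"carbonate": [-3.0, -3.5, -4.0], "plant": [-3.0, -3.5, -4.0]}
        )
        assert rep["ranksum"]["testable"]
        assert rep["ranksum"]["p"] == pytest.approx(1.0)

    def test_ranksum_matches_exhaustive_permutation_oracle(self):
        marine = [-3.0, -3.5, -4.7]
        terrestrial = [-5.2, -6.5, -7.1]
        rep = compare_substrate_magnitudes({"carbonate": marine, "plant": terrestrial})
        oracle = exhaustive_ranksum_p(marine, terrestrial)
        assert oracle == pytest.approx(2 / 20)  # fully separated groups, C(6,3)=20
        assert rep["ranksum"]["method"] == "exact"
        assert rep["ranksum"]["p"] == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_permutation_oracle_on_random_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(-4.0, 1.0, 5).round(2).tolist()
        b = rng.normal(-6.0, 1.0, 5).round(2).tolist()
        rep = compare_substrate_magnitudes({"carbonate": a, "plant": b})
        assert rep["ranksum"]["p"] == pytest.approx(exhaustive_ranksum_p(a, b), abs=1e-12)

    def test_separated_substrates_highly_significant(self):
        rng = np.random.default_rng(1)
        marine = rng.normal(-3.5, 0.5, 30)
        plant = rng.normal(-7.0, 0.7, 30)
        rep = compare_substrate_magnitudes({"carbonate": marine, "plant": plant})
        assert rep["kruskal"]["p"] < 0.001
        assert rep["ranksum"]["p"] < 0.001
        q = rep["quartiles"]
        assert q["plant"]["median"] < q["carbonate"]["median"]

    def test_degenerate_group_reported_not_raised(self):
        rep = compare_substrate_magnitudes({"carbonate": [-3.0], "plant": [-6.0, -7.0]})
        assert rep["ranksum"]["testable"] is False
        assert rep["kruskal"]["testable"] is False

    def test_quartile_summaries(self):
        rep = compare_substrate_magnitudes(
            {"carbonate": [-3.0, -4.0, -5.0, -6.0], "plant": [-6.0, -7.0, -8.0]}
        )
        assert rep["quartiles"]["carbonate"]["median"] == pytest.approx(-4.5)
        assert rep["quartiles"]["carbonate"]["n"] == 4


class TestEndToEndCompilation:
    def test_synthetic_compilation_magnitudes_differ_by_substrate(
        self, truth, plant_true
    ):
        """Marine vs plant CIE magnitudes from a noisy synthetic compilation."""
        plan = SamplingPlan(n_plant_sections=6, n_carb_sections=8, seed=5)
        df = sample_sections(truth, plant_true, plan)
        groups = {"carbonate": [], "plant": []}
        for sec, sub in (("carb", "carbonate"), ("plant", "plant")):
            for sid in df.section_id.unique():
                if not sid.startswith(sec):
                    continue
                sdf = df[df.section_id == sid].reset_index(drop=True)
                s = IsotopeSeries(sid, sub, sdf[["age_ma", "value"]])
                m = cie_magnitude(assign_stages(s, truth.config.boundaries))
                groups[sub].append(m.magnitude)
        rep = compare_substrate_magnitudes(groups)
        assert rep["ranksum"]["p"] < 0.001
        assert np.mean(groups["plant"]) < np.mean(groups["carbonate"]) < 0
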