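"""Tests for Monte Carlo propagation, intervals and sensitivity sweeps."""

import numpy as np
import pytest

from c3pco2 import (
    PCO2Reconstruction,
    ProxyParams,
    StackedCurve,
    mc_reconstruct,
    report_interval,
    sensitivity_sweep,
)

ZERO_SD_PARAMS = ProxyParams(b_sd=0.0, pco2_ref_sd=0.0, d13c_p_ref_sd=0.0)


def constant_stacks(n=50, plant=-27.0, carb=2.2, sst=25.0, se=0.0):
    g = 252.3 - 0.002 * np.arange(n)
    ones = np.ones(n, dtype=int)

    def mk(v):
        return StackedCurve(g, np.full(n, float(v)), np.full(n, float(se)), ones, 0.2)

    return mk(plant), mk(carb), mk(sst)


class TestMCReconstruct:
    def test_degenerate_all_sds_zero(self):
        recon = mc_reconstruct(*constant_stacks(), ZERO_SD_PARAMS, n_draws=200, seed=0)
        assert np.allclose(recon.median, 425.0)
        assert np.allclose(recon.p16, 425.0)
        assert np.allclose(recon.p84, 425.0)
        assert np.all(recon.n_valid == 200)

    def test_reference_prior_median(self):
        """With zero fractionation change, only the pCO2(t=0) prior spreads the draws."""
        params = ProxyParams(b_sd=0.0, d13c_p_ref_sd=0.0)  # keep pco2_ref_sd = 68
        recon = mc_reconstruct(*constant_stacks(), params, n_draws=10_000, seed=0)
        tol = 3 * 1.2533 * 68.0 / np.sqrt(10_000)  # 3x asymptotic sd of a Gaussian median
        assert abs(recon.median[0] - 425.0) < tol
        spread = recon.p84[0] - recon.p16[0]
        assert spread == pytest.approx(2 * 68.0, rel=0.05)

    def test_truth_stacks_recover_truth_exactly(self, truth, truth_stacks):
        recon = mc_reconstruct(*truth_stacks, ZERO_SD_PARAMS, n_draws=200, seed=0)
        rel = np.abs(recon.median - truth.pco2_true) / truth.pco2_true
        assert np.nanmax(rel) < 1e-12

    def test_deterministic_under_seed(self):
        a = mc_reconstruct(*constant_stacks(se=0.3), ProxyParams(), n_draws=500, seed=7)
        b = mc_reconstruct(*constant_stacks(se=0.3), ProxyParams(), n_draws=500, seed=7)
        assert np.array_equal(a.median, b.median)
        assert np.array_equal(a.n_valid, b.n_valid)

    def test_halving_draws_stable_median(self):
        params = ProxyParams(b_sd=0.0, d13c_p_ref_sd=0.0)
        big = mc_reconstruct(*constant_stacks(), params, n_draws=10_000, seed=1)
        small = mc_reconstruct(*constant_stacks(), params, n_draws=5_000, seed=2)
        sigma_mc = 1.2533 * 68.0 / np.sqrt(5_000)
        assert abs(big.median[0] - small.median[0]) < 3 * sigma_mc * np.sqrt(2)

    def test_mismatched_grids_rejected(self):
        p, c, s = constant_stacks(50)
        _, _, s_bad = constant_stacks(40)
        with pytest.raises(ValueError, match="age grid"):
            mc_reconstruct(p, c, s_bad, ProxyParams(), n_draws=200)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="n_draws"):
            mc_reconstruct(*constant_stacks(), ProxyParams(), n_draws=50)

    def test_exclusion_grows_toward_asymptote(self):
        """Draws beyond the proxy asymptote are dropped; more so at larger ddc."""
        base_plant = -27.0
        fractions = []
        for shift in (-4.0, -6.5):  # plant excursion pushes ddc toward the asymptote
            p, c, s = constant_stacks(20, plant=base_plant + shift, se=0.2)
            ref = constant_stacks(20, plant=base_plant, se=0.2)
            stacks = (
                StackedCurve(
                    p.age_grid,
                    np.where(np.arange(20) < 2, ref[0].center, p.center),
                    p.se,
                    p.n_local,
                    p.span,
                ),
                c,
                s,
            )
            recon = mc_reconstruct(*stacks, ProxyParams(), n_draws=4000, seed=3)
            fractions.append(recon.excluded_fraction[5:].mean())
        assert fractions[1] > fractions[0]

    def test_default_synthetic_exclusion_below_half(self, default_recon):
        ok = default_recon.n_valid > 0
        assert np.all(default_recon.excluded_fraction[ok] < 0.5)

    def test_band_asymmetry_at_peak(self, default_recon):
        i = int(np.nanargmax(default_recon.median))
        med, pos, neg = report_interval(
            default_recon, float(default_recon.age_grid[i])
        )
        assert pos > neg > 0


class TestReportInterval:
    def make_recon(self):
        g = 252.3 - 0.002 * np.arange(3)
        # gridstep percentiles hand-computed from draws {100, 200, ..., 1000}:
        # type-7: p16 at rank 1+0.16*9 -> 244, median 550, p84 -> 856
        return PCO2Reconstruction(
            g,
            np.array([550.0, 550.0, 550.0]),
            np.array([244.0, 244.0, 244.0]),
            np.array([856.0, 856.0, 856.0]),
            np.array([10, 10, 10]),
            10,
            0,
        )

    def test_hand_percentiles_roundtrip(self):
        draws = np.arange(100.0, 1001.0, 100.0)
        q = np.percentile(draws, [16, 50, 84])  # same type-7 rule as the module
        assert list(q) == [244.0, 550.0, 856.0]

    def test_interval_arithmetic(self):
        med, pos, neg = report_interval(self.make_recon(), 252.3)
        assert (med, pos, neg) == (550.0, 306.0, 306.0)

    def test_off_grid_age_warns_and_snaps(self):
        with pytest.warns(UserWarning, match="off-grid"):
            med, _, _ = report_interval(self.make_recon(), 251.0)
        assert med == 550.0

    def test_degenerate_zero_errors(self):
        recon = mc_reconstruct(*constant_stacks(), ZERO_SD_PARAMS, n_draws=200, seed=0)
        med, pos, neg = report_interval(recon, float(recon.age_grid[3]))
        assert (pos, neg) == (0.0, 0.0)


class TestSensitivitySweep:
    def test_single_value_matches_direct_reconstruction(self, truth_stacks):
        sweep = sensitivity_sweep(
            *truth_stacks, "pco2_ref", [425.0], n_draws=400, seed=5
        )
        direct = mc_reconstruct(*truth_stacks, ProxyParams(), n_draws=400, seed=5)
        assert sweep.loc[0, "peak_median"] == pytest.approx(np.nanmax(direct.median))

    def test_peak_increases_with_reference_pco2(self, truth_stacks):
        sweep = sensitivity_sweep(
            *truth_stacks, "pco2_ref", [300.0, 425.0, 600.0], n_draws=400, seed=5
        )
        assert sweep["peak_median"].is_monotonic_increasing

    def test_curvature_direction_matches_bisection_oracle(self, truth_stacks):
        """At fixed fractionation change, larger B demands more CO2.

        The hyperbola saturates sooner with a larger curvature parameter,
        so the same measured ddc inverts to a higher peak — verified
        independently by root-bracketing the forward curve.
        """
        from scipy.optimize import brentq

        from c3pco2 import frac_forward

        ddc = frac_forward(2507.0) - frac_forward(425.0)
        oracle = {}
        for b in (0.22, 0.25):
            target = frac_forward(425.0, 28.26, b) + ddc
            oracle[b] = brentq(
                lambda p: frac_forward(p, 28.26, b) - target, 1.0, 1e9, xtol=1e-8
            )
        assert oracle[0.25] > oracle[0.22]
        sweep = sensitivity_sweep(*truth_stacks, "B", [0.22, 0.25], n_draws=400, seed=5)
        assert sweep.loc[1, "peak_median"] > sweep.loc[0, "peak_median"]

    def test_unknown_parameter_rejected(self, truth_stacks):
        with pytest.raises(ValueError, match="unknown parameter"):
            sensitivity_sweep(*truth_stacks, "gamma", [1.0])
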