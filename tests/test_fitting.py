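"""Nonlinear saturation fitting: recovery, invariances, oracles, bootstrap."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from starchkin import (BindingDataset, GranuleModel, NoiseModel, RateDataset,
                       SiteClass, bootstrap_ci, fit_langmuir, fit_saturation,
                       gen_binding_dataset, grid_oracle)


def _sat(x, v, k):
    return v * x / (k + x)


LOADS = np.linspace(10.0, 300.0, 12)


class TestFitSaturation:
    def test_noise_free_recovery(self):
        y = _sat(LOADS, 1200.0, 105.2)
        fit = fit_saturation(LOADS, y)
        assert fit.converged
        assert fit.vmax == pytest.approx(1200.0, rel=1e-6)
        assert fit.k == pytest.approx(105.2, rel=1e-6)

    def test_linear_regime_flagged(self):
        x = np.linspace(1.0, 10.0, 8)
        y = 3.0 * x  # K far above the design range
        fit = fit_saturation(x, y)
        assert fit.k >= x.max()
        assert "saturation_not_reached" in fit.flags

    def test_constant_response_degenerate(self):
        x = np.linspace(1.0, 10.0, 6)
        fit = fit_saturation(x, np.full(6, 7.0))
        assert not fit.converged
        assert "degenerate" in fit.flags

    def test_scale_equivariance(self, rng):
        y = _sat(LOADS, 900.0, 60.0) * (1 + 0.03 * rng.standard_normal(12))
        f1 = fit_saturation(LOADS, y)
        f2 = fit_saturation(LOADS, 100.0 * y)
        assert f2.vmax == pytest.approx(100.0 * f1.vmax, rel=1e-9)
        assert f2.k == pytest.approx(f1.k, rel=1e-9)

    def test_permutation_invariance(self, rng):
        y = _sat(LOADS, 900.0, 60.0) * (1 + 0.05 * rng.standard_normal(12))
        perm = rng.permutation(12)
        f1 = fit_saturation(LOADS, y)
        f2 = fit_saturation(LOADS[perm], y[perm])
        # identical up to float summation order in the SSE
        assert f2.vmax == pytest.approx(f1.vmax, rel=1e-6)
        assert f2.k == pytest.approx(f1.k, rel=1e-6)

    def test_matches_scipy_curve_fit(self, rng):
        """Independent optimizer agrees on a noisy dataset."""
        y = _sat(LOADS, 1500.0, 120.0) * (1 + 0.05 * rng.standard_normal(12))
        ours = fit_saturation(LOADS, y)
        (v_sp, k_sp), _ = curve_fit(_sat, LOADS, y, p0=[1.1 * y.max(), 100.0])
        assert ours.vmax == pytest.approx(v_sp, rel=1e-6)
        assert ours.k == pytest.approx(k_sp, rel=1e-6)

    def test_too_few_distinct_x_rejected(self):
        with pytest.raises(ValueError):
            fit_saturation([1.0, 1.0, 2.0, 3.0], [0.1, 0.1, 0.2, 0.3])

    def test_noise_recovery_median_error(self):
        """5% CV, n=3: median |rel error| of K over seeds stays under 15%."""
        errs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = np.repeat(LOADS, 3)
            y = _sat(x, 1000.0, 105.2) * (1 + 0.05 * rng.standard_normal(x.size))
            fit = fit_saturation(x, y)
            errs.append(abs(fit.k - 105.2) / 105.2)
        assert np.median(errs) <= 0.15


class TestGridOracle:
    def test_exact_grid_recovers_generator(self):
        y = _sat(LOADS, 1200.0, 105.2)
        res = grid_oracle(LOADS, y, np.array([1000.0, 1200.0, 1400.0]),
                          np.array([90.0, 105.2, 120.0]))
        assert res.vmax == 1200.0 and res.k == 105.2
        assert res.sse == pytest.approx(0.0, abs=1e-18)

    def test_refinement_monotone(self, rng):
        y = _sat(LOADS, 1100.0, 80.0) * (1 + 0.05 * rng.standard_normal(12))
        coarse = grid_oracle(LOADS, y, np.linspace(500, 2000, 16),
                             np.linspace(10, 300, 16))
        fine = grid_oracle(LOADS, y, np.linspace(500, 2000, 61),
                           np.linspace(10, 300, 61))
        assert fine.sse <= coarse.sse

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_oracle(LOADS, _sat(LOADS, 1.0, 1.0), np.array([]), np.array([1.0]))

    def test_nls_beats_oracle_over_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v, k = rng.uniform(500, 2000), rng.uniform(30, 250)
            y = _sat(LOADS, v, k) * (1 + 0.05 * rng.standard_normal(12))
            fit = fit_saturation(LOADS, y)
            oracle = grid_oracle(LOADS, y, np.linspace(0.5 * v, 2 * v, 60),
                                 np.linspace(0.3 * k, 3 * k, 60))
            assert fit.sse <= oracle.sse + 1e-9


class TestLangmuirFit:
    def test_noise_free_isotherm_recovery(self):
        model = GranuleModel(
            classes=(SiteClass("s", gamma=36.0, kd_site=1500.0, kcat_site=0.0),),
            mass_load=25.0)
        data = gen_binding_dataset(np.linspace(0.2, 7.0, 10), model)
        fit = fit_langmuir(data)
        assert fit.vmax == pytest.approx(36.0, rel=1e-6)
        assert fit.k == pytest.approx(1.5, rel=1e-6)  # Kd in µM

    def test_noisy_isotherm_within_ten_percent(self):
        model = GranuleModel(
            classes=(SiteClass("s", gamma=36.0, kd_site=1500.0, kcat_site=0.0),),
            mass_load=25.0)
        data = gen_binding_dataset(
            np.linspace(0.2, 7.0, 10), model,
            NoiseModel(cv=0.03, n_replicates=3, seed=1))
        fit = fit_langmuir(data)
        assert fit.vmax == pytest.approx(36.0, rel=0.10)

    def test_flat_coverage_flagged_degenerate(self):
        data = BindingDataset(e0=np.array([1.0, 2.0, 3.0, 4.0]),
                              e_free=np.array([0.9, 1.9, 2.9, 3.9]),
                              mass_s0=np.full(4, 25.0))
        fit = fit_langmuir(data)
        assert "degenerate" in fit.flags


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, rng):
        x = np.repeat(LOADS, 3)
        y = _sat(x, 1000.0, 105.2) * (1 + 0.05 * rng.standard_normal(x.size))
        a = bootstrap_ci(x, y, n_boot=100, seed=7)
        b = bootstrap_ci(x, y, n_boot=100, seed=7)
        assert a == b

    def test_noise_free_interval_is_tight(self):
        x = np.repeat(LOADS, 3)
        y = _sat(x, 1000.0, 105.2)
        res = bootstrap_ci(x, y, n_boot=60, seed=0)
        assert res.ci_k[1] - res.ci_k[0] < 1e-6 * 105.2
        assert res.ci_vmax[1] - res.ci_vmax[0] < 1e-6 * 1000.0
        assert not res.high_dropout


class TestRateDatasetInvariants:
    def test_cmm_requires_constant_enzyme(self):
        with pytest.raises(ValueError, match="constant enzyme"):
            RateDataset(mode="CMM", enzyme="E", substrate="S",
                        e0=[1.0, 2.0, 1.0, 1.0], mass_s0=[1, 2, 3, 4],
                        v0=[0.1, 0.2, 0.3, 0.4])

    def test_imm_requires_constant_load(self):
        with pytest.raises(ValueError, match="constant substrate"):
            RateDataset(mode="IMM", enzyme="E", substrate="S",
                        e0=[1.0, 2.0, 4.0, 8.0], mass_s0=[25, 25, 30, 25],
                        v0=[0.1, 0.2, 0.3, 0.4])

    def test_binding_free_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            BindingDataset(e0=np.array([1.0, 2.0]),
                           e_free=np.array([1.1, 1.0]),
                           mass_s0=np.array([25.0, 25.0]))
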