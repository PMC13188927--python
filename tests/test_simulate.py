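"""Mechanistic granule simulator: partitioning, limits, progress curves."""

import numpy as np
import pytest

from starchkin import (CMMParams, GranuleModel, IMMParams, NoiseModel,
                       SiteClass, cmm_rate, fit_saturation, gen_binding_dataset,
                       gen_rate_dataset, imm_rate, mechanistic_rate,
                       model_from_printed, simulate_progress,
                       solve_partitioning)


def _single_class_quadratic(e0, sigma, kd):
    """Closed-form free-enzyme root for one site class (test oracle)."""
    b = kd + sigma - e0
    return (-b + np.sqrt(b * b + 4.0 * kd * e0)) / 2.0


def _model(gamma=40.0, kd=40.0, kcat=100.0, load=25.0, capacity=1.0):
    return GranuleModel(
        classes=(SiteClass("s", gamma=gamma, kd_site=kd, kcat_site=kcat,
                           capacity=capacity),),
        mass_load=load)


class TestPartitioning:
    def test_zero_enzyme(self):
        part = solve_partitioning(0.0, _model())
        assert part.e_free == 0.0
        assert np.all(part.complexes == 0.0)

    @pytest.mark.parametrize("e0,gamma,kd,load", [
        (10.0, 40.0, 40.0, 25.0),    # σ = 1000 ≫ e0
        (500.0, 2.0, 30.0, 25.0),    # e0 ≫ σ = 50
        (100.0, 4.0, 10.0, 25.0),    # comparable regime
    ])
    def test_matches_quadratic_oracle(self, e0, gamma, kd, load):
        part = solve_partitioning(e0, _model(gamma=gamma, kd=kd, load=load))
        ef = _single_class_quadratic(e0, gamma * load, kd)
        assert part.e_free == pytest.approx(ef, rel=1e-9)
        assert abs(part.residual) < 1e-9 * e0

    def test_substrate_excess_complex(self):
        # σ=1000 ≫ e0=10, kd=40: complex ≈ 10·1000/1040
        part = solve_partitioning(10.0, _model(gamma=40.0, kd=40.0, load=25.0))
        assert part.complexes.sum() == pytest.approx(9.615, abs=5e-3)

    def test_weak_second_class_reduces_to_single(self):
        strong = SiteClass("a", gamma=40.0, kd_site=40.0, kcat_site=1.0,
                           capacity=0.5)
        weak = SiteClass("b", gamma=5.0, kd_site=1e9, kcat_site=1.0,
                         capacity=0.5)
        two = GranuleModel(classes=(strong, weak), mass_load=25.0)
        one = GranuleModel(classes=(strong,), mass_load=25.0)
        p2 = solve_partitioning(10.0, two)
        p1 = solve_partitioning(10.0, one)
        assert p2.e_free == pytest.approx(p1.e_free, rel=1e-6)


class TestMechanisticRate:
    def test_substrate_excess_limb_approaches_cmm(self):
        site = model_from_printed(k_half=105.2, gamma=0.38, conv_kcat=100.0)
        cmm = CMMParams(conv_kcat=100.0, k_half=105.2)
        for sep, tol in ((1e2, 5e-3), (1e3, 5e-4)):
            errs = []
            for load in (50.0, 105.2, 250.0):
                e0 = 0.38 * load / sep  # σ/E0 = sep
                model = GranuleModel(classes=(site,), mass_load=load)
                v = mechanistic_rate(e0, model)
                errs.append(abs(v - cmm_rate(e0, load, cmm)) / v)
            assert max(errs) < tol

    def test_enzyme_excess_limb_approaches_imm(self):
        site = model_from_printed(k_half=105.2, gamma=0.38, conv_kcat=100.0)
        model = GranuleModel(classes=(site,), mass_load=25.0)
        sigma = 0.38 * 25.0
        imm = IMMParams(inv_vmax=100.0 * sigma, k_m_inverse=site.kd_site)
        for sep, tol in ((1e2, 5e-3), (1e3, 5e-4)):
            e0 = sigma * sep
            v = mechanistic_rate(e0, model)
            assert abs(v - imm_rate(e0, imm)) / v < tol

    def test_dead_site_class_gives_zero_rate(self):
        model = _model(kcat=0.0)
        assert mechanistic_rate(10.0, model) == 0.0


class TestGenerators:
    def test_ideal_round_trip_and_determinism(self):
        params = CMMParams(conv_kcat=100.0, k_half=105.2)
        loads = np.linspace(10, 300, 12)
        clean = gen_rate_dataset("ideal_CMM", loads=loads, e0=12.0,
                                 params=params)
        fit = fit_saturation(clean.mass_s0, clean.v0)
        assert fit.k == pytest.approx(105.2, rel=1e-6)
        noise = NoiseModel(cv=0.05, n_replicates=3, seed=11)
        a = gen_rate_dataset("ideal_CMM", loads=loads, e0=12.0, params=params,
                             noise=noise)
        b = gen_rate_dataset("ideal_CMM", loads=loads, e0=12.0, params=params,
                             noise=noise)
        np.testing.assert_array_equal(a.v0, b.v0)
        assert a.v0.size == 36

    def test_mechanistic_enzyme_depletion_biases_cmm(self):
        """With σ comparable to E0 the apparent K_1/2 exceeds kd/gamma:
        bound enzyme no longer tracks the ideal hyperbola."""
        site = model_from_printed(k_half=105.2, gamma=0.38, conv_kcat=100.0)
        model = GranuleModel(classes=(site,), mass_load=25.0)
        loads = np.linspace(10, 300, 12)
        ds = gen_rate_dataset("CMM", loads=loads, e0=30.0, model=model)
        fit = fit_saturation(ds.mass_s0, ds.v0)
        assert fit.k > 105.2  # reproducible deviation, fixed sign

    def test_binding_single_class_exact_langmuir(self):
        model = _model(gamma=36.0, kd=1500.0, kcat=0.0)
        ds = gen_binding_dataset(np.linspace(0.2, 7.0, 10), model)
        fit = fit_saturation(ds.e_free, ds.coverage())
        assert fit.vmax == pytest.approx(36.0, rel=1e-6)
        assert fit.k == pytest.approx(1.5, rel=1e-6)

    def test_binding_design_spans_saturation(self):
        model = _model(gamma=36.0, kd=1500.0, kcat=0.0, load=25.0)
        ds = gen_binding_dataset(np.linspace(0.2, 7.0, 10), model)
        frac = ds.coverage() / 36.0
        assert frac.min() < 0.2 and frac.max() > 0.75

    def test_two_class_isotherm_deviates_from_single_langmuir(self):
        two = GranuleModel(classes=(
            SiteClass("tight", gamma=18.0, kd_site=50.0, kcat_site=0.0,
                      capacity=0.5),
            SiteClass("loose", gamma=18.0, kd_site=20000.0, kcat_site=0.0,
                      capacity=0.5)),
            mass_load=25.0)
        one = _model(gamma=36.0, kd=1500.0, kcat=0.0)
        e0 = np.geomspace(0.05, 7.0, 12)
        r2_two = fit_saturation(gen_binding_dataset(e0, two).e_free,
                                gen_binding_dataset(e0, two).coverage()).r_squared
        r2_one = fit_saturation(gen_binding_dataset(e0, one).e_free,
                                gen_binding_dataset(e0, one).coverage()).r_squared
        assert r2_one > 0.999999
        assert r2_two < r2_one


class TestProgress:
    def _fast_capacity_model(self):
        fast = SiteClass("amylose", gamma=0.38, kd_site=40.0,
                         kcat_site=5000.0, capacity=0.14)
        slow = SiteClass("ap-helix", gamma=0.2, kd_site=200.0,
                         kcat_site=0.01, capacity=0.8)
        return GranuleModel(classes=(fast, slow), mass_load=100.0)

    def test_plateau_at_class_capacity(self):
        model = self._fast_capacity_model()
        t = np.linspace(0.0, 8 * 3600.0, 33)
        res = simulate_progress(model, 3000.0, t)
        assert res.dh[-1] == pytest.approx(14.0, abs=0.1)
        assert np.all(np.diff(res.dh) >= -1e-12)

    def test_zero_enzyme_no_hydrolysis(self):
        model = self._fast_capacity_model()
        res = simulate_progress(model, 0.0, np.linspace(0, 3600, 5))
        np.testing.assert_allclose(res.dh, 0.0)

    def test_mass_conservation(self):
        model = self._fast_capacity_model()
        t = np.linspace(0.0, 4 * 3600.0, 17)
        res = simulate_progress(model, 3000.0, t)
        init = sum(c.capacity for c in model.classes) * model.mass_load
        total = res.residual_mass.sum(axis=1) + res.hydrolyzed
        np.testing.assert_allclose(total, init, rtol=1e-9)

    def test_plateau_equals_total_capacity_single_class(self):
        model = GranuleModel(
            classes=(SiteClass("only", gamma=0.38, kd_site=40.0,
                               kcat_site=5000.0, capacity=0.14),),
            mass_load=100.0)
        res = simulate_progress(model, 3000.0, np.linspace(0, 8 * 3600, 17))
        assert res.dh[-1] == pytest.approx(14.0, abs=0.05)

    def test_bad_time_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_progress(self._fast_capacity_model(), 10.0,
                              np.array([0.0, 10.0, 5.0]))
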