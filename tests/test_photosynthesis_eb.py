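import numpy as np
import pytest

import herbwue as h
from herbwue.photosynthesis_eb import (
    DEFAULT_CONFIG,
    KineticParams,
    arrhenius_factor,
    eb_results_frame,
    vcmax_one_point,
)
from herbwue.synthetic_data import DEFAULT_VCMAX_COEFS


def bisection_oracle(kinetics, gt, ca, tol=1e-12):
    """Independent solver: bisection on the scalar balance in c_i.

    At the solution the diffusion supply gt*(ca - ci) equals the
    Rubisco-limited demand Ac(ci); the difference is monotone in ci.
    """
    def f(ci):
        demand = (kinetics.vcmax * (ci - kinetics.gamma_star)
                  / (ci + kinetics.km) - kinetics.rd)
        return gt * (ca - ci) - demand

    lo, hi = 1e-9, ca * (1 + 1e-6) + kinetics.rd / gt + 1.0
    assert f(lo) > 0 > f(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    ci = 0.5 * (lo + hi)
    return gt * (ca - ci), ci


KIN25 = h.kinetics_at(25.0, 66.8)


class TestKinetics:
    def test_reference_temperature_is_identity(self):
        kin = h.kinetics_at(25.0, 80.0)
        assert kin.vcmax == pytest.approx(80.0)
        assert kin.kc == pytest.approx(DEFAULT_CONFIG.kc25)
        assert kin.ko == pytest.approx(DEFAULT_CONFIG.ko25)
        assert kin.gamma_star == pytest.approx(DEFAULT_CONFIG.gamma_star25)
        assert kin.rd == pytest.approx(0.015 * 80.0)

    def test_warming_raises_every_parameter(self):
        k25, k29 = h.kinetics_at(25.0, 80.0), h.kinetics_at(29.0, 80.0)
        assert k29.vcmax > k25.vcmax
        assert k29.kc > k25.kc and k29.ko > k25.ko
        assert k29.gamma_star > k25.gamma_star

    def test_forward_inverse_round_trip(self):
        cfg = DEFAULT_CONFIG
        for ha in (cfg.ha_vcmax, cfg.ha_kc, cfg.ha_ko, cfg.ha_gamma_star):
            back = arrhenius_factor(ha, 29.0) * (1.0 / arrhenius_factor(ha, 29.0))
            assert back == pytest.approx(1.0, abs=1e-12)
        v29 = 80.0 * arrhenius_factor(cfg.ha_vcmax, 29.0)
        assert v29 / arrhenius_factor(cfg.ha_vcmax, 29.0) == pytest.approx(
            80.0, rel=1e-12)

    def test_km_exceeds_gamma_star(self):
        assert KIN25.km > KIN25.gamma_star
        assert KIN25.km == pytest.approx(404.9 * (1 + 210 / 278.4), rel=1e-12)

    def test_temperature_bounds(self):
        with pytest.raises(ValueError):
            h.kinetics_at(-5.0, 50.0)


class TestOnePointVcmax:
    def test_hand_value(self):
        assert vcmax_one_point(15.0, 280.0, KIN25) == pytest.approx(66.8, abs=0.1)

    def test_zero_assimilation_gives_zero_vcmax(self):
        assert vcmax_one_point(0.0, 280.0, KIN25) == 0.0

    def test_compensation_point_rejected(self):
        with pytest.raises(ValueError):
            vcmax_one_point(10.0, KIN25.gamma_star, KIN25)


class TestConductances:
    def test_gs_ratio_default(self):
        assert h.gs_from_gsmax(1.0) == pytest.approx(0.51)
        assert h.gs_from_gsmax(0.0) == 0.0
        assert h.gs_from_gsmax(2.0, ratio=1.0) == 2.0

    def test_total_conductance_hand_values(self):
        gc, gt = h.total_conductance(0.5)
        assert gc == pytest.approx(0.3125)
        assert gt == pytest.approx(0.27027, abs=1e-5)
        gc, gt = h.total_conductance(1.6)
        assert gc == pytest.approx(1.0)
        assert gt == pytest.approx(2.0 / 3.0)

    def test_infinite_boundary_layer_limit(self):
        gc, gt = h.total_conductance(0.5, gcb=1e9)
        assert gt == pytest.approx(gc, rel=1e-8)

    def test_nonpositive_gs_rejected(self):
        with pytest.raises(ValueError):
            h.total_conductance(0.0)


class TestSolveAssimilation:
    def test_hand_parameterisation(self):
        a, ci = h.solve_assimilation(KIN25, 0.27027, 400.0)
        assert a == pytest.approx(17.7, abs=0.1)
        assert ci == pytest.approx(334.7, abs=0.3)
        a_o, ci_o = bisection_oracle(KIN25, 0.27027, 400.0)
        assert a == pytest.approx(a_o, abs=1e-8)

    def test_no_diffusive_limitation_limit(self):
        a, ci = h.solve_assimilation(KIN25, 1e8, 400.0)
        assert ci == pytest.approx(400.0, abs=1e-4)
        expected = (KIN25.vcmax * (400 - KIN25.gamma_star)
                    / (400 + KIN25.km) - KIN25.rd)
        assert a == pytest.approx(expected, abs=1e-4)

    def test_dead_leaf(self):
        kin = h.kinetics_at(29.0, 0.0)
        a, ci = h.solve_assimilation(kin, 0.3, 400.0)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert ci == pytest.approx(400.0)

    def test_quadratic_matches_bisection_on_random_parameterisations(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            kin = h.kinetics_at(float(rng.uniform(20, 35)),
                                float(rng.uniform(5, 150)))
            gt = float(rng.uniform(0.02, 2.0))
            ca = float(rng.uniform(280, 420))
            a, ci = h.solve_assimilation(kin, gt, ca)
            a_o, _ = bisection_oracle(kin, gt, ca)
            assert abs(a - a_o) < 1e-6

    def test_flux_consistency(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            kin = h.kinetics_at(29.0, float(rng.uniform(10, 120)))
            gt = float(rng.uniform(0.05, 1.5))
            ca = float(rng.uniform(300, 410))
            a, ci = h.solve_assimilation(kin, gt, ca)
            assert a == pytest.approx(gt * (ca - ci), abs=1e-9)
            demand = (kin.vcmax * (ci - kin.gamma_star)
                      / (ci + kin.km) - kin.rd)
            assert a == pytest.approx(demand, abs=1e-9)

    def test_monotone_in_gt_and_ca(self):
        kin = h.kinetics_at(29.0, 60.0)
        gts = np.linspace(0.05, 1.5, 20)
        a_gt, _ = h.solve_assimilation(kin, gts, 400.0)
        assert np.all(np.diff(a_gt) >= -1e-12)
        cas = np.linspace(300.0, 420.0, 20)
        a_ca, _ = h.solve_assimilation(kin, 0.3, cas)
        assert np.all(np.diff(a_ca) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            h.solve_assimilation(KIN25, -0.1, 400.0)
        with pytest.raises(ValueError):
            h.solve_assimilation(KIN25, 0.3, KIN25.gamma_star)


class TestAjRate:
    def test_compensation_point(self):
        kin = KineticParams(66.8, 404.9, 278.4, 42.75, 210.0, 1.0, 25.0)
        assert h.aj_rate(kin.gamma_star, 100.0, kin) == pytest.approx(-1.0)

    def test_asymptote(self):
        kin = KineticParams(66.8, 404.9, 278.4, 42.75, 210.0, 1.0, 25.0)
        assert h.aj_rate(1e9, 100.0, kin) == pytest.approx(24.0, abs=1e-4)

    def test_hand_value(self):
        # ci = 2*gamma*: (ci - g*)(Jmax/4)/(ci + 2 g*) - Rd
        #   = 42.75 * 25 / 171 - 1 = 5.25
        kin = KineticParams(66.8, 404.9, 278.4, 42.75, 210.0, 1.0, 25.0)
        assert h.aj_rate(2 * 42.75, 100.0, kin) == pytest.approx(5.25)


class TestVcmaxTraitModel:
    def test_noise_free_coefficients_recovered(self):
        train = h.generate_vcmax_training(n_species=6, n_per_species=5,
                                          species_sd=0.0, resid_sd=0.0, seed=3)
        with pytest.warns(UserWarning, match="singular|fixed"):
            model = h.fit_vcmax_model(train)
        a, b, c, d = DEFAULT_VCMAX_COEFS
        assert model.coef_rec_n == pytest.approx(a, abs=1e-6)
        assert model.coef_ln_sla == pytest.approx(b, abs=1e-6)
        assert model.coef_interaction == pytest.approx(c, abs=1e-6)
        assert model.intercept == pytest.approx(d, abs=1e-6)
        # prediction on a training point reproduces its response
        sp, v, sla, n_area = train[0]
        assert h.predict_vcmax25(model, n_area, sla, sp) == pytest.approx(
            v, rel=1e-6)

    def test_random_intercept_variance_recovered(self):
        train = h.generate_vcmax_training(n_species=20, n_per_species=20,
                                          species_sd=0.1, resid_sd=0.05,
                                          seed=0)
        model = h.fit_vcmax_model(train)
        assert model.is_mixed
        assert 0.005 <= model.random_intercept_var <= 0.015  # within 50%

    def test_single_species_falls_back_with_warning(self):
        train = [("only", 50.0 + i, 0.008 + 2e-4 * i, 2.0 + 0.1 * i)
                 for i in range(6)]
        with pytest.warns(UserWarning, match="single species"):
            model = h.fit_vcmax_model(train)
        assert not model.is_mixed

    def test_intercept_only_model_predicts_constant(self):
        model = h.VcmaxTraitModel(0.0, 0.0, 0.0, float(np.log(50.0)))
        assert h.predict_vcmax25(model, 1.7, 0.009) == pytest.approx(50.0)
        assert h.predict_vcmax25(model, 3.0, 0.004, "anything") == pytest.approx(50.0)

    def test_unseen_species_gets_fixed_part_only(self, vcmax_model):
        base = h.predict_vcmax25(vcmax_model, 2.0, 0.008)
        assert h.predict_vcmax25(vcmax_model, 2.0, 0.008, "never-seen") == base
        seen = next(iter(vcmax_model.random_intercepts))
        offset = vcmax_model.random_intercepts[seen]
        assert h.predict_vcmax25(vcmax_model, 2.0, 0.008, seen) == pytest.approx(
            base * np.exp(offset))

    def test_nonpositive_traits_rejected(self, vcmax_model):
        with pytest.raises(ValueError):
            h.predict_vcmax25(vcmax_model, -1.0, 0.008)

    def test_diagnostics_reported(self, vcmax_model):
        assert 0.5 < vcmax_model.pseudo_r2 <= 1.0
        assert 0.0 <= vcmax_model.resid_normality_p <= 1.0


class TestEbSimulate:
    def test_composition_matches_chained_hand_operations(self, tiny_atmosphere,
                                                         vcmax_model):
        rec = h.SpecimenRecord("s", "sp", 2015, stomatal_density=300.0,
                               pore_length=20.0, guard_cell_width=5.0,
                               lma=120.0, n_area=2.0)
        (res,), counts = h.eb_simulate([rec], tiny_atmosphere, vcmax_model)
        assert counts == {"simulated": 1, "skipped_incomplete": 0,
                          "solver_failed": 0}
        gsmax = h.leaf_gsmax(rec).gsmax
        assert res.gs == pytest.approx(0.51 * gsmax)
        gc, gt = h.total_conductance(res.gs)
        assert res.gt == pytest.approx(gt)
        kin = h.kinetics_at(29.0, res.vcmax25)
        a, ci = h.solve_assimilation(kin, gt, 400.0)
        assert res.a_net == pytest.approx(a) and res.ci == pytest.approx(ci)
        assert res.iwue == pytest.approx(res.a_net / res.gs)

    def test_engine_is_deterministic(self, tiny_atmosphere, vcmax_model):
        rec = h.SpecimenRecord("s", "sp", 2015, stomatal_density=400.0,
                               pore_length=10.0, guard_cell_width=4.0,
                               lma=110.0, n_area=1.9)
        out1, _ = h.eb_simulate([rec, rec], tiny_atmosphere, vcmax_model)
        assert out1[0] == out1[1]

    def test_incomplete_records_skipped_and_counted(self, tiny_atmosphere,
                                                    vcmax_model):
        complete = h.SpecimenRecord("c", "sp", 2015, stomatal_density=400.0,
                                    pore_length=10.0, guard_cell_width=4.0,
                                    lma=110.0, n_area=1.9)
        missing_n = h.SpecimenRecord("m", "sp", 2015, stomatal_density=400.0,
                                     pore_length=10.0, guard_cell_width=4.0,
                                     lma=110.0)
        results, counts = h.eb_simulate([complete, missing_n],
                                        tiny_atmosphere, vcmax_model)
        assert len(results) == 1
        assert counts["skipped_incomplete"] == 1

    def test_results_frame_shape(self, community, atmosphere, vcmax_model):
        results, counts = h.eb_simulate(community[:20], atmosphere, vcmax_model)
        df = eb_results_frame(results)
        assert len(df) == counts["simulated"] == 20
        assert np.allclose(df["a_net"] / df["gs"], df["iwue"])
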