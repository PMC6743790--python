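"""Kinetic-parameter and mixing-coefficient estimation."""

import numpy as np
import pytest

from protdeconv import (
    FitOptions,
    KineticParams,
    MissingAssayError,
    ShapeError,
    SimConfig,
    SingleAssay,
    Timecourse,
    estimate_mixing,
    fit_family_kinetics,
    fit_kinetics,
    fit_kinetics_matrix,
    integrate_single,
    predict_single,
    sample_kinetic_matrix,
    simulate_mixture_assay,
    simulate_single_assays,
)

from conftest import random_params

CAL_TIMES = np.array([10.0, 30.0, 60.0, 120.0, 240.0, 400.0])


def _assay(params, times, protease="E1", substrate="S1"):
    tc = integrate_single(params, 1.0, times)
    return SingleAssay(protease=protease, substrate=substrate, timecourse=tc)


class TestPredictSingle:
    def test_time_zero_is_one(self, params):
        assert predict_single(params, 1.0, [0.0, 60.0])[0] == 1.0

    def test_zero_concentration(self, params):
        np.testing.assert_allclose(predict_single(params, 0.0, [60.0, 240.0]), 1.0)

    def test_identity_with_trajectory_form(self, rng):
        # the 1 - cumulative-cleavage form IS the integrated trajectory
        for _ in range(10):
            p = random_params(rng)
            t = np.sort(rng.uniform(1, 400, 4))
            np.testing.assert_allclose(
                predict_single(p, 1.0, t),
                integrate_single(p, 1.0, t).values,
                atol=1e-10,
            )


class TestFitKinetics:
    def test_recovers_generating_curve(self, rng):
        times = np.linspace(10, 400, 20)
        for _ in range(5):
            truth = random_params(rng)
            assay = _assay(truth, times)
            fit = fit_kinetics(assay, FitOptions(seed=0))
            pred = predict_single(fit.estimate, 1.0, times)
            assert np.max(np.abs(pred - assay.timecourse.values)) < 1e-3

    def test_flat_assay_yields_zero_rate(self):
        tc = Timecourse(np.array([30.0, 120.0, 400.0]), np.ones(3))
        fit = fit_kinetics(SingleAssay("E1", "S1", tc), FitOptions(seed=1))
        assert fit.residual < 1e-8
        p = fit.estimate
        eff = p.V * (1 - p.beta) ** p.n / ((1 - p.beta) ** p.n + p.K**p.n)
        assert eff < 1e-4

    def test_two_point_assay_interpolable(self, rng):
        # residual ~ 0 even though parameters are not unique
        truth = random_params(rng)
        assay = _assay(truth, np.array([60.0, 240.0]))
        fit = fit_kinetics(assay, FitOptions(seed=2))
        assert fit.residual < 1e-8

    def test_bounds_respected_and_objective_decreases(self, rng):
        times = np.linspace(10, 400, 8)
        truth = random_params(rng)
        noisy = np.clip(
            integrate_single(truth, 1.0, times).values + rng.normal(0, 0.05, 8),
            0.0,
            1.0,
        )
        assay = SingleAssay("E1", "S1", Timecourse(times, np.sort(noisy)[::-1]))
        fit = fit_kinetics(assay, FitOptions(seed=3))
        p = fit.estimate
        assert p.V > 0 and p.K > 0 and p.n > 0 and 0.0 <= p.beta < 1.0
        # residual cannot exceed that of a flat-line prediction baseline
        assert fit.residual <= np.sum((assay.timecourse.values - 1.0) ** 2) + 1e-12


class TestFitKineticsMatrix:
    def test_grid_recovery_and_shape(self):
        cfg = SimConfig(M=2, N=2, seed=5)
        km = sample_kinetic_matrix(cfg)
        assays = simulate_single_assays(km, CAL_TIMES)
        fitted = fit_kinetics_matrix(assays, FitOptions(seed=0))
        assert fitted.substrates == km.substrates
        assert fitted.proteases == km.proteases
        for i in range(2):
            for j in range(2):
                pred = predict_single(fitted.param(i, j), 1.0, CAL_TIMES)
                truth = predict_single(km.param(i, j), 1.0, CAL_TIMES)
                assert np.max(np.abs(pred - truth)) < 1e-3

    def test_missing_cell_named(self):
        cfg = SimConfig(M=2, N=2, seed=5)
        km = sample_kinetic_matrix(cfg)
        assays = simulate_single_assays(km, CAL_TIMES)
        dropped = [a for a in assays if not (a.substrate == "S2" and a.protease == "E1")]
        with pytest.raises(MissingAssayError, match=r"S2.*E1"):
            fit_kinetics_matrix(dropped, FitOptions(seed=0))


class TestFitFamilyKinetics:
    def test_single_member_matches_fit_kinetics(self, rng):
        truth = random_params(rng)
        assay = _assay(truth, CAL_TIMES)
        a = fit_kinetics(assay, FitOptions(seed=4))
        b = fit_family_kinetics([assay], FitOptions(seed=4))
        assert a.estimate == b.estimate

    def test_duplicate_members_same_optimum(self, rng):
        truth = random_params(rng)
        assay = _assay(truth, CAL_TIMES)
        twin = SingleAssay("E2", "S1", assay.timecourse)
        one = fit_family_kinetics([assay], FitOptions(seed=4))
        two = fit_family_kinetics([assay, twin], FitOptions(seed=4))
        # objective doubles but the optimiser's path is identical
        assert two.estimate.V == pytest.approx(one.estimate.V, rel=1e-6)
        assert two.residual == pytest.approx(2 * one.residual, abs=1e-12)

    def test_pooled_fit_lies_between_members(self):
        p1 = KineticParams(V=0.03, K=0.4, n=1.2, beta=0.2)
        p4 = KineticParams(V=0.033, K=0.44, n=1.3, beta=0.22)
        assays = [_assay(p1, CAL_TIMES, "E1"), _assay(p4, CAL_TIMES, "E2")]
        fit = fit_family_kinetics(assays, FitOptions(seed=6))
        rep = predict_single(fit.estimate, 1.0, CAL_TIMES)
        lo = np.minimum(assays[0].timecourse.values, assays[1].timecourse.values)
        hi = np.maximum(assays[0].timecourse.values, assays[1].timecourse.values)
        assert np.all(rep >= lo - 5e-3) and np.all(rep <= hi + 5e-3)

    def test_rejects_empty_or_mixed_substrates(self, rng):
        with pytest.raises(ShapeError):
            fit_family_kinetics([], FitOptions(seed=0))
        truth = random_params(rng)
        with pytest.raises(ShapeError):
            fit_family_kinetics(
                [_assay(truth, CAL_TIMES, "E1", "S1"), _assay(truth, CAL_TIMES, "E1", "S2")]
            )


class TestEstimateMixing:
    def test_recovery_with_true_kinetics(self, rng):
        cfg = SimConfig(M=7, N=3, seed=11)
        km = sample_kinetic_matrix(cfg)
        truth = rng.uniform(0.2, 2.0, 3)
        mix = simulate_mixture_assay(km, truth, cfg.times)
        fit = estimate_mixing(mix, km, FitOptions(seed=0))
        np.testing.assert_allclose(fit.estimate.alphas, truth, atol=5e-3)

    def test_all_ones_data_gives_zero_alphas(self, small_km):
        mix = simulate_mixture_assay(small_km, np.zeros(2), (0.0, 60.0))
        fit = estimate_mixing(mix, small_km, FitOptions(seed=0))
        assert np.all(fit.estimate.alphas >= 0.0)
        assert np.max(fit.estimate.alphas) < 1e-3

    def test_one_protease_recovery(self, rng):
        cfg = SimConfig(M=3, N=1, seed=13)
        km = sample_kinetic_matrix(cfg)
        truth = np.array([1.3])
        mix = simulate_mixture_assay(km, truth, cfg.times)
        fit = estimate_mixing(mix, km, FitOptions(seed=0))
        assert fit.estimate.alphas[0] == pytest.approx(1.3, rel=0.01)

    def test_substrate_mismatch_raises(self, small_km):
        mix = simulate_mixture_assay(small_km, np.ones(2), (0.0, 60.0))
        km_wrong = small_km.select_substrates(small_km.substrates[:2])
        with pytest.raises(ShapeError):
            estimate_mixing(mix, km_wrong, FitOptions(seed=0))

    def test_nonnegativity_is_exact(self, small_km, rng):
        mix = simulate_mixture_assay(small_km, rng.uniform(0.2, 2, 2), (0.0, 60.0))
        fit = estimate_mixing(mix, small_km, FitOptions(seed=0))
        assert np.all(fit.estimate.alphas >= 0.0)
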