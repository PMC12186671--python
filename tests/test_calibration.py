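import numpy as np
import pytest

import narsense as ns
from narsense.calibration import (
    ExperimentTimeCourse,
    bagging_ensemble,
    bootstrap_resample,
    calibrate,
    estimate_weights,
    fit_growth,
    make_fit_problem,
    weighted_cost,
)
from narsense.model_core import GrowthParams, KineticParameterSet, double_logistic

CTX = ns.ContextKey("M0", "S0", "P1", "R1")


def _exp(times, od, gfp, ctx=CTX):
    return ExperimentTimeCourse(
        context=ctx, times=np.asarray(times, float),
        od_replicates=np.asarray(od, float), gfp_replicates=np.asarray(gfp, float),
    )


# ---------------------------------------------------------------------------
# weights


class TestWeights:
    def test_identical_replicates_hit_the_floor(self):
        t = np.linspace(0, 16, 20)
        base = np.linspace(0.05, 1.0, 20)
        exp = _exp(t, np.tile(base, (3, 1)), np.tile(base, (3, 1)))
        w = estimate_weights(exp)
        floor = (1e-3 * (base.max() - base.min())) ** 2
        assert np.allclose(w.od, 1.0 / floor)

    def test_doubling_the_sd_quarters_the_weight(self):
        t = np.arange(5.0)
        od = np.vstack([np.full(5, 1.0), np.full(5, 1.2), np.full(5, 0.8)])  # sd 0.2
        od2 = od.copy()
        od2[:, 2] = [1.0, 1.4, 0.6]  # sd doubled at t=2
        w1 = estimate_weights(_exp(t, od, od)).od
        w2 = estimate_weights(_exp(t, od2, od2)).od
        assert w2[2] == pytest.approx(w1[0] / 4)

    def test_single_replicate_warns_and_returns_uniform(self):
        t = np.arange(4.0)
        with pytest.warns(UserWarning, match="single replicate"):
            w = estimate_weights(_exp(t, [np.linspace(0.1, 1, 4)], [np.linspace(0.1, 1, 4)]))
        assert np.allclose(w.od, 1.0)

    def test_weights_track_a_proportional_noise_law(self):
        """Pooled over 200 simulated replicate sets, estimated variances
        recover sigma_t = 0.05 * y_t within 30% for at least 80% of points."""
        rand = np.random.default_rng(7)
        t = np.linspace(0, 16, 25)
        y = 0.1 + np.linspace(0.2, 2.0, 25)
        sigma = 0.05 * y
        s2 = np.empty((200, 25))
        for i in range(200):
            reps = y + rand.normal(0, sigma, size=(3, 25))
            exp = _exp(t, np.clip(reps, 0, None), np.clip(reps, 0, None))
            w = estimate_weights(exp)
            s2[i] = 1.0 / w.od
        pooled_w = 1.0 / s2.mean(axis=0)
        ok = np.abs(pooled_w - 1.0 / sigma**2) <= 0.3 / sigma**2
        assert ok.mean() >= 0.8


# ---------------------------------------------------------------------------
# cost function


class TestWeightedCost:
    def _problem(self, exp, names=("vmax_NAR",)):
        return make_fit_problem(
            [exp], list(names), {exp.context: GrowthParams(1.0, 1.0, 6.0, 0.05, 1.5)},
            KineticParameterSet(), outputs=("od",),
        )

    def test_zero_at_exact_agreement(self, ground_truth, reference_context):
        exp = ns.generate_experiment(
            reference_context, ground_truth, ns.NoiseSpec(0.0, 0.0, 3), seed=1
        )
        problem = make_fit_problem(
            [exp], ["L1[M0-S0-P1-R1]"],
            {reference_context: ground_truth.growth[reference_context]},
            ground_truth.kinetics, outputs=("od",),
        )
        truth = np.array([ground_truth.growth[reference_context].L1])
        # od model is the exact generating curve: residuals vanish identically
        assert weighted_cost(truth, problem) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_residual_two_weight_one(self):
        gp = GrowthParams(1.0, 1.0, 6.0, 0.0, 1.0)
        t = np.array([6.0])
        od_model = double_logistic(t, gp)  # 0.5
        exp = _exp(t, np.tile(od_model + 2.0, (2, 1)), np.tile(od_model, (2, 1)))
        problem = make_fit_problem(
            [exp], ["L1[M0-S0-P1-R1]"], {CTX: gp}, KineticParameterSet(), outputs=("od",),
        )
        problem.weights[0].od[:] = 1.0
        assert weighted_cost(np.array([1.0]), problem) == pytest.approx(4.0)

    def test_matches_hand_computed_weighted_sum(self):
        gp = GrowthParams(1.0, 1.0, 6.0, 0.0, 1.0)
        t = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        model = double_logistic(t, gp)
        offsets = np.array([0.3, 0.05, 0.1, 0.4, 0.2])
        weights = np.array([1.0, 2.0, 0.5, 4.0, 1.5])
        exp = _exp(t, np.tile(model + offsets, (2, 1)), np.tile(model, (2, 1)))
        problem = make_fit_problem(
            [exp], ["L1[M0-S0-P1-R1]"], {CTX: gp}, KineticParameterSet(), outputs=("od",),
        )
        problem.weights[0].od[:] = weights
        expected = float(np.sum(weights * offsets**2))  # independent arithmetic
        assert weighted_cost(np.array([1.0]), problem) == pytest.approx(expected, rel=1e-12)

    def test_out_of_bounds_rejected(self):
        gp = GrowthParams(1.0, 1.0, 6.0, 0.0, 1.0)
        exp = _exp(np.array([1.0]), [[0.5], [0.5]], [[0.1], [0.1]])
        problem = self._problem(exp)
        with pytest.raises(ValueError, match="bounds"):
            weighted_cost(np.array([1e9]), problem)


# ---------------------------------------------------------------------------
# growth fitting


class TestFitGrowth:
    def test_noise_free_recovery_within_one_percent(self, ground_truth, noiseless_experiment):
        gp_true = ground_truth.growth[ns.ContextKey("M0", "S0", "P1", "R1")]
        gp_hat, result = fit_growth(noiseless_experiment, seed=0)
        for name in ("L1", "a1", "t1"):
            assert getattr(gp_hat, name) == pytest.approx(getattr(gp_true, name), rel=0.01)
        assert result.cost >= 0

    def test_single_logistic_truth_yields_negligible_second_wave(self):
        gp_true = GrowthParams(L1=0.9, a1=1.2, t1=6.0, k1=0.0, k2=1.0)
        t = np.linspace(0, 16, 97)
        od = double_logistic(t, gp_true)
        exp = _exp(t, np.tile(od, (3, 1)), np.tile(od, (3, 1)))
        gp_hat, _ = fit_growth(exp, seed=1)
        assert gp_hat.k1 <= 1e-3 * gp_hat.L1

    def test_flat_od_rejected(self):
        t = np.linspace(0, 16, 10)
        flat = np.full((3, 10), 0.4)
        with pytest.raises(ValueError, match="degenerate"):
            fit_growth(_exp(t, flat, flat))


# ---------------------------------------------------------------------------
# global calibration


def _small_problem(gt, ctx, exp):
    names = [f"K_mRNAp[{ctx.medium}]", f"RBS_strength[{ctx.context_id}]", "vmax_NAR"]
    return names, make_fit_problem(
        [exp], names, {ctx: gt.growth[ctx]}, gt.kinetics,
        lower=1e-3, upper=1e2,
    )


class TestCalibrate:
    def test_reaches_known_truth_cost_on_noise_free_data(self, ground_truth, reference_context,
                                                         noiseless_experiment):
        names, problem = _small_problem(ground_truth, reference_context, noiseless_experiment)
        rk = ground_truth.kinetics.resolve(reference_context)
        truth = np.array([rk.K_mRNAp, rk.RBS_strength, rk.vmax_NAR])
        fit = calibrate(problem, seed=3, budget=1200)
        assert fit.cost <= weighted_cost(truth, problem) + 1e-6
        assert np.all(fit.k_hat >= problem.k_lower) and np.all(fit.k_hat <= problem.k_upper)

    def test_collapsed_bounds_return_the_point(self, ground_truth, reference_context,
                                               noiseless_experiment):
        names, problem = _small_problem(ground_truth, reference_context, noiseless_experiment)
        point = np.array([1.0, 2.0, 3.0])
        problem.k_lower = point.copy()
        problem.k_upper = point.copy()
        fit = calibrate(problem, seed=0)
        assert np.array_equal(fit.k_hat, point)
        assert fit.cost == pytest.approx(weighted_cost(point, problem))

    def test_same_seed_is_bitwise_reproducible(self, ground_truth, reference_context,
                                               noisy_experiment):
        names, problem = _small_problem(ground_truth, reference_context, noisy_experiment)
        a = calibrate(problem, seed=5, budget=400)
        b = calibrate(problem, seed=5, budget=400)
        assert np.array_equal(a.k_hat, b.k_hat)
        assert a.cost == b.cost


# ---------------------------------------------------------------------------
# bootstrap and bagging


class TestBootstrap:
    def test_identical_replicates_resample_to_the_original(self):
        t = np.linspace(0, 16, 12)
        base = np.tile(np.linspace(0.05, 1.0, 12), (3, 1))
        exp = _exp(t, base, base)
        boot = bootstrap_resample(exp, seed=0)
        assert np.array_equal(boot.od_replicates, exp.od_replicates)
        assert np.array_equal(boot.gfp_replicates, exp.gfp_replicates)

    def test_shape_and_grid_preserved(self, noisy_experiment):
        boot = bootstrap_resample(noisy_experiment, seed=1)
        assert boot.od_replicates.shape == noisy_experiment.od_replicates.shape
        assert np.array_equal(boot.times, noisy_experiment.times)

    def test_each_replicate_drawn_uniformly(self):
        t = np.array([0.0, 1.0])
        od = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        exp = _exp(t, od, od)
        counts = {1.0: 0, 2.0: 0, 3.0: 0}
        draws = 0
        for seed in range(3500):
            boot = bootstrap_resample(exp, seed=seed)
            for v in boot.od_replicates[:, 0]:
                counts[float(v)] += 1
                draws += 1
        for v, c in counts.items():
            assert c / draws == pytest.approx(1 / 3, abs=0.02)


class TestBagging:
    def test_single_iteration_no_noise_equals_direct_calibration(
        self, ground_truth, reference_context, noiseless_experiment
    ):
        names, problem = _small_problem(ground_truth, reference_context, noiseless_experiment)
        direct = calibrate(problem, seed=9, budget=400)
        ensemble = bagging_ensemble(problem, n_iterations=1, seed=9, budget=400)
        assert ensemble.mean() == pytest.approx(direct.k_hat, rel=1e-6)

    def test_replicate_noise_produces_member_spread(
        self, ground_truth, reference_context, noisy_experiment
    ):
        names, problem = _small_problem(ground_truth, reference_context, noisy_experiment)
        ensemble = bagging_ensemble(problem, n_iterations=8, seed=2, budget=400,
                                    member_budget=200)
        matrix = ensemble.parameter_matrix()
        assert matrix.shape == (8, 3)
        assert np.all(matrix.std(axis=0) > 0)

    def test_full_ensemble_reproducible_from_seed(
        self, ground_truth, reference_context, noisy_experiment
    ):
        names, problem = _small_problem(ground_truth, reference_context, noisy_experiment)
        a = bagging_ensemble(problem, n_iterations=4, seed=3, budget=300, member_budget=150)
        b = bagging_ensemble(problem, n_iterations=4, seed=3, budget=300, member_budget=150)
        assert np.array_equal(a.parameter_matrix(), b.parameter_matrix())
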