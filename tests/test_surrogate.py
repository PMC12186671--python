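import numpy as np
import pandas as pd
import pytest

import narsense as ns
from narsense.context import ContextKey
from narsense.model_core import KineticParameterSet
from narsense.nnet import MLPConfig, MLPRegressor
from narsense.surrogate import (
    ContextEncoder,
    CVReport,
    GrowthPredictor,
    PromoterEncoding,
    cv_report,
    default_promoter_encoding,
    optimize_promoter_encoding,
    predict_response,
    train_growth_surrogate,
    train_reporter_surrogate,
)
from narsense.synthetic_data import synthetic_ensemble_matrix


# ---------------------------------------------------------------------------
# encoding


class TestEncoding:
    def test_feature_dimension_is_eleven(self, space):
        enc = ContextEncoder()
        assert enc.n_features == 11
        assert enc.raw(ContextKey("M0", "S0", "P1", "R1")).shape == (11,)

    def test_injective_over_the_full_space(self, space):
        enc = ContextEncoder()
        rows = {tuple(enc.raw(c)) for c in space.all_contexts()}
        assert len(rows) == 320

    def test_reference_context_is_promoter_value_only(self):
        enc = ContextEncoder()
        row = enc.raw(ContextKey("M0", "S0", "P1", "R1"))
        assert row[0] == enc.pe["P1"]
        assert np.all(row[1:] == 0.0)

    def test_standardization_contract(self, space):
        enc = ContextEncoder()
        x = enc.fit_transform(space.all_contexts()[:50])
        assert np.all(np.abs(x.mean(axis=0)) < 1e-10)
        sd = x.std(axis=0)
        assert np.all((np.abs(sd - 1.0) < 1e-10) | (sd < 1e-10))  # constant cols stay 0

    def test_decode_roundtrip(self, space):
        enc = ContextEncoder()
        contexts = space.all_contexts()[::13]
        enc.fit(contexts)
        for ctx in contexts:
            assert enc.decode(enc.transform([ctx])[0]) == ctx

    def test_unknown_level_rejected(self):
        enc = ContextEncoder()
        bad = ContextKey("M0", "S0", "P1", "R1")
        object.__setattr__(bad, "medium", "MX")
        with pytest.raises(ValueError, match="MX"):
            enc.raw(bad)


# ---------------------------------------------------------------------------
# cross-validation report


class TestCVReport:
    def test_perfect_predictions(self):
        y = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0], [4.0, 8.0]])
        rep = cv_report(y, y, ["a", "b"])
        assert rep.q2 == pytest.approx(1.0)
        assert rep.rmse_relative == pytest.approx(0.0)
        assert all(v == pytest.approx(1.0) for v in rep.r2_per_target.values())

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = cv_report(np.full(4, y.mean()), y, ["a"])
        assert rep.r2_per_target["a"] == pytest.approx(0.0)
        assert rep.q2 == pytest.approx(0.0)

    def test_matches_hand_computed_four_point_example(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        pred = np.array([1.5, 1.5, 3.5, 5.0])
        press = np.sum((obs - pred) ** 2)          # 0.25+0.25+0.25+1 = 1.75
        tss = np.sum((obs - obs.mean()) ** 2)      # 14
        rep = cv_report(pred, obs, ["y"])
        assert rep.q2 == pytest.approx(1 - press / tss)
        assert rep.rmse_relative == pytest.approx(np.sqrt(1.75 / 4) / 5.0 * 100)

    def test_zero_observed_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            cv_report(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))


# ---------------------------------------------------------------------------
# growth surrogate


def _encoded_training_set(space, n, seed):
    rand = np.random.default_rng(seed)
    contexts = [space.all_contexts()[i] for i in rand.choice(320, n, replace=False)]
    enc = ContextEncoder()
    return contexts, enc, enc.fit_transform(contexts)


class TestGrowthSurrogate:
    def test_realizable_linear_function_is_learned(self, space):
        contexts, enc, x = _encoded_training_set(space, 40, 0)
        beta = np.linspace(-1, 1, x.shape[1])
        targets = pd.DataFrame({"a1": x @ beta + 3.0, "t1": x @ beta[::-1] + 6.0})
        models, report = train_growth_surrogate(x, targets, seed=0)
        assert report.r2_per_target["a1"] >= 0.99
        assert report.r2_per_target["t1"] >= 0.99

    def test_loo_produces_one_heldout_prediction_per_row(self, space):
        from narsense.surrogate import _loo_predictions

        contexts, enc, x = _encoded_training_set(space, 20, 1)
        y = np.linspace(0.5, 2.0, 20)
        assert _loo_predictions(x, y, "linear", 1.0).shape == (20,)

    def test_constant_target_rejected(self, space):
        contexts, enc, x = _encoded_training_set(space, 20, 2)
        with pytest.raises(ValueError, match="degenerate"):
            train_growth_surrogate(x, pd.DataFrame({"a1": np.ones(20)}), seed=0)

    def test_pure_noise_targets_score_near_zero_and_no_leakage(self, space):
        """Null-signal contract: LOO R^2 <= 0.2 in >= 90% of 50 seeded
        trials, and the mean LOO Q^2 stays <= 0.1 (no leakage)."""
        contexts, enc, x = _encoded_training_set(space, 20, 3)
        low = 0
        q2s = []
        for seed in range(50):
            rand = np.random.default_rng(seed)
            targets = pd.DataFrame({"a1": rand.normal(0, 1, 20)})
            models, report = train_growth_surrogate(
                x, targets, seed=seed, kernels=("rbf",), c_grid=(1.0, 10.0)
            )
            low += report.r2_per_target["a1"] <= 0.2
            q2s.append(report.q2)
        assert low >= 45
        assert np.mean(q2s) <= 0.1


class TestPromoterEncodingOptimization:
    def test_budget_below_ten_rejected(self, space):
        with pytest.raises(ValueError, match="budget"):
            optimize_promoter_encoding([], pd.DataFrame(), budget=5)

    def test_single_promoter_training_set_rejected(self, space):
        contexts = [ContextKey("M0", "S0", "P1", "R1"), ContextKey("M1", "S0", "P1", "R2")]
        with pytest.raises(ValueError, match="two promoters"):
            optimize_promoter_encoding(contexts, pd.DataFrame({"a1": [1.0, 2.0]}), budget=12)

    def test_planted_promoter_ordering_is_recovered(self, space):
        """A strong planted promoter effect (P3 > P1 > P2 > P4) must be
        reflected monotonically in the learned scalars (the LOO objective is
        invariant to orientation, so the reverse ordering also counts) in at
        least 80% of 20 seeded runs."""
        effect = {"P1": 0.6, "P2": 0.3, "P3": 1.0, "P4": 0.0}
        planted = np.array([effect[p] for p in ("P1", "P2", "P3", "P4")])
        contexts = [c for c in space.all_contexts() if c.supplement == "S0"][::2][:32]
        hits = 0
        for seed in range(20):
            rand = np.random.default_rng(200 + seed)
            y = np.array([effect[c.promoter] for c in contexts]) + rand.normal(0, 0.05, len(contexts))
            pe = optimize_promoter_encoding(
                contexts, pd.DataFrame({"a1": y}), seed=seed, budget=30
            )
            learned = np.array([pe[p] for p in ("P1", "P2", "P3", "P4")])
            from scipy.stats import kendalltau

            tau = kendalltau(learned, planted).statistic
            hits += abs(tau) == 1.0
        assert hits >= 16


# ---------------------------------------------------------------------------
# reporter surrogate


@pytest.fixture(scope="module")
def reporter_setup(space, ground_truth):
    contexts = space.all_contexts()[::11][:24]
    matrix = synthetic_ensemble_matrix(contexts, ground_truth, n_members=10,
                                       member_sd=0.0, seed=0)
    return contexts, matrix


class TestReporterSurrogate:
    def test_interpolates_noise_free_ensemble_means(self, reporter_setup, ground_truth):
        contexts, matrix = reporter_setup
        sur = train_reporter_surrogate(
            matrix, ContextEncoder(), KineticParameterSet(), seed=0,
            config=MLPConfig(epochs=600, dropout=0.05, lr=3e-3),
        )
        consensus = matrix.groupby("context_id").mean()
        worse = 0.0
        for ctx in contexts:
            pred = sur.predict_params(ctx)
            for name in ("K_mRNAp", "K_P", "RBS_strength"):
                true = consensus.loc[ctx.context_id, name]
                worse = max(worse, abs(pred[name] - true) / true)
        assert worse <= 0.10

    def test_single_context_rejected(self, ground_truth):
        matrix = synthetic_ensemble_matrix(
            [ContextKey("M0", "S0", "P1", "R1")], ground_truth, n_members=5, seed=0
        )
        with pytest.raises(ValueError, match="two contexts"):
            train_reporter_surrogate(matrix, ContextEncoder(), KineticParameterSet())

    def test_training_reduces_loss_without_dropout(self, reporter_setup):
        contexts, matrix = reporter_setup
        enc = ContextEncoder().fit(contexts)
        x = enc.transform([ContextKey.from_id(i) for i in matrix["context_id"]])
        y = np.log(matrix[["K_mRNAp", "RBS_strength"]].to_numpy())
        y = (y - y.mean(axis=0)) / y.std(axis=0)
        net = MLPRegressor(x.shape[1], 2, MLPConfig(dropout=0.0, epochs=1), seed=0)
        initial = net.loss(x, y)
        net.fit(x, y)
        assert net.loss(x, y) < initial

    def test_same_seed_gives_identical_validation_loss(self, reporter_setup):
        contexts, matrix = reporter_setup
        other = next(
            c for c in contexts[1:]
            if c.promoter != contexts[0].promoter and c.medium != contexts[0].medium
        )
        val = [contexts[0].context_id, other.context_id]
        cfg = MLPConfig(epochs=50)
        losses = []
        for _ in range(2):
            sur = train_reporter_surrogate(
                matrix, ContextEncoder(), KineticParameterSet(), seed=7,
                config=cfg, validation_contexts=val,
            )
            losses.append(sur.report.q2)
        assert losses[0] == losses[1]


class TestPredictResponse:
    def test_total_over_the_entire_factor_space(self, space, reporter_setup, ground_truth):
        contexts, matrix = reporter_setup
        sur = train_reporter_surrogate(
            matrix, ContextEncoder(), KineticParameterSet(), seed=0,
            config=MLPConfig(epochs=60),
        )
        growth_targets = pd.DataFrame({
            "a1": [ground_truth.growth[c].a1 for c in contexts],
            "t1": [ground_truth.growth[c].t1 for c in contexts],
        })
        enc = ContextEncoder().fit(contexts)
        models, _ = train_growth_surrogate(
            enc.transform(contexts), growth_targets, seed=0,
            kernels=("rbf",), c_grid=(1.0, 10.0),
        )
        predictor = GrowthPredictor(encoder=enc, models=models,
                                    defaults={"L1": 1.0, "k1": 0.05, "k2": 1.5})
        grid = np.linspace(0.0, 16.0, 17)
        for ctx in space.all_contexts()[::29]:
            traj = predict_response(ctx, predictor, sur, grid=grid)
            assert np.all(traj.gfp_per_od >= 0)
            assert len(traj) == 17
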