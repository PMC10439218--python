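"""MaxEnt and MLP classifiers: basis expansion, fitting, prediction, search."""

import numpy as np
import pandas as pd
import pytest

from aquamap.models import (
    FeatureBasis, HyperSearchSpace, MLPModel, expand_features, fit_maxent,
    fit_mlp, hyperparameter_search, maxent_objective,
    permutation_importance, predict_maxent,
)

IDENTITY_SCALING = (np.array([0.0]), np.array([1.0]))


class TestExpandFeatures:
    def test_quadratic_of_scaled_value(self):
        scaling = (np.array([0.0]), np.array([4.0]))  # 2 scales to 0.5
        H, names = expand_features([[2.0]], FeatureBasis(("quadratic",)), scaling)
        assert H.tolist() == [[0.25]]
        assert names == ["quad(z0)"]

    def test_product_of_two_features(self):
        scaling = (np.zeros(2), np.ones(2))
        H, _ = expand_features([[0.3, 0.5]], FeatureBasis(("product",)), scaling)
        assert H.tolist() == [[pytest.approx(0.15)]]

    def test_hinge_value_at_knot(self):
        H, _ = expand_features([[0.7]], FeatureBasis(("hinge",), hinge_knots=1),
                               IDENTITY_SCALING)
        assert H[0, 0] == pytest.approx((0.7 - 0.5) / (1 - 0.5))

    def test_threshold_indicator(self):
        H, _ = expand_features([[0.7], [0.3]],
                               FeatureBasis(("threshold",), threshold_knots=1),
                               IDENTITY_SCALING)
        assert H.ravel().tolist() == [1.0, 0.0]

    def test_far_out_of_range_input_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            H, _ = expand_features([[5.0]], FeatureBasis(("linear",)),
                                   IDENTITY_SCALING)
        assert H[0, 0] == 1.0

    def test_empty_basis_requires_a_class(self):
        with pytest.raises(ValueError):
            FeatureBasis(())


class TestMaxEnt:
    def test_identical_distributions_shrink_beta_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 3))
        m = fit_maxent(X[:1000], X[1000:],
                       FeatureBasis(("linear", "quadratic", "hinge")),
                       lambda_scale=1.0)
        assert np.abs(m.beta).max() < 0.1

    def test_one_feature_beta_matches_bruteforce_grid(self):
        # all-or-nothing binary feature: the penalized optimum is found by a
        # dense 1-D scan of the same objective the fitter maximizes
        pres = np.array([[1.0]] * 80 + [[0.0]] * 20)
        bg = np.array([[1.0]] * 100 + [[0.0]] * 100)
        for lam_scale in (0.0, 0.5):
            m = fit_maxent(pres, bg, FeatureBasis(("linear",)),
                           lambda_scale=lam_scale)
            H_p, _ = expand_features(pres, m.basis, m.scaling)
            H_b, _ = expand_features(bg, m.basis, m.scaling)
            grid = np.linspace(-4, 4, 16001)
            vals = [maxent_objective(np.array([b]), H_p, H_b, m.lam) for b in grid]
            assert abs(m.beta[0] - grid[np.argmax(vals)]) < 1e-3

    def test_unpenalized_stationarity_condition(self):
        # with lambda 0 the optimum satisfies: background-weighted mean of the
        # feature equals the presence mean (logit(0.8) for an 80/20 presence
        # split against a balanced background)
        pres = np.array([[1.0]] * 80 + [[0.0]] * 20)
        bg = np.array([[1.0]] * 100 + [[0.0]] * 100)
        m = fit_maxent(pres, bg, FeatureBasis(("linear",)), lambda_scale=0.0)
        assert m.beta[0] == pytest.approx(np.log(0.8 / 0.2), abs=1e-4)

    def test_perfect_separation_stops_with_warning(self):
        # every presence sits at the feature value only half the background
        # attains: the unpenalized objective increases without bound in beta
        pres = np.full((50, 1), 1.0)
        bg = np.array([[0.0]] * 25 + [[1.0]] * 25)
        with pytest.warns(UserWarning, match="convergence"):
            m = fit_maxent(pres, bg, FeatureBasis(("linear",)), lambda_scale=0.0,
                           max_iter=50)
        assert not m.converged

    def test_zero_variance_basis_column_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        P = np.column_stack([rng.normal(size=50), np.ones(50)])
        B = np.column_stack([rng.normal(size=100), np.ones(100)])
        with pytest.warns(UserWarning, match="zero-variance"):
            m = fit_maxent(P, B, FeatureBasis(("linear",)))
        assert len(m.column_names) == 1

    def test_beta_zero_predicts_constant_half(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 2))
        m = fit_maxent(X[:100], X[100:], FeatureBasis(("linear",)),
                       lambda_scale=10.0)  # heavy penalty forces beta to 0
        assert np.abs(m.beta).max() == 0.0
        assert m.predict_pstar(X[:5]) == pytest.approx(np.full(5, 0.5))

    def test_monotone_beta_gives_monotone_pstar(self):
        rng = np.random.default_rng(3)
        P = rng.normal(1.0, 1.0, size=(300, 1))
        B = rng.normal(0.0, 1.0, size=(300, 1))
        m = fit_maxent(P, B, FeatureBasis(("linear",)), lambda_scale=0.0)
        xs = np.linspace(B.min(), B.max(), 50)[:, None]
        ps = m.predict_pstar(xs)
        assert m.beta[0] > 0
        assert np.all(np.diff(ps) >= -1e-12)

    def test_background_mean_calibrated_to_prevalence(self):
        rng = np.random.default_rng(4)
        P = rng.normal(0.8, 1.0, size=(400, 2))
        B = rng.normal(0.0, 1.0, size=(400, 2))
        m = fit_maxent(P, B, FeatureBasis(("linear", "quadratic")))
        assert m.predict_pstar(B).mean() == pytest.approx(0.5, abs=1e-6)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        P, B = rng.normal(0.5, 1, (100, 2)), rng.normal(0, 1, (200, 2))
        m = fit_maxent(P, B, FeatureBasis(("linear", "hinge")))
        m.to_json(tmp_path / "m.json")
        from aquamap.models import MaxEntModel
        m2 = MaxEntModel.from_json(tmp_path / "m.json")
        X = rng.normal(size=(20, 2))
        assert np.allclose(m.predict_pstar(X), m2.predict_pstar(X))


class TestMLP:
    def test_separable_classes_beat_chance_log_loss(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(150, 2)) + 3.0
        B = rng.normal(size=(150, 2))
        m = fit_mlp(P, B, (10,), "relu", seed=0, max_iter=400)
        X = np.vstack([P, B])
        y = np.r_[np.ones(150), np.zeros(150)]
        from sklearn.metrics import log_loss
        assert log_loss(y, m.predict_pstar(X)) < np.log(2)

    def test_constant_features_predict_the_class_prior(self):
        P = np.full((60, 2), 1.0)
        B = np.full((240, 2), 1.0)
        m = fit_mlp(P, B, (5,), "logistic", seed=0, max_iter=600)
        prior = 60 / 300
        assert m.predict_pstar(P[:5]) == pytest.approx(np.full(5, prior), abs=0.05)

    def test_same_seed_gives_identical_weights(self):
        rng = np.random.default_rng(1)
        P, B = rng.normal(1, 1, (80, 3)), rng.normal(0, 1, (80, 3))
        a = fit_mlp(P, B, (8,), "tanh", seed=7, max_iter=150)
        b = fit_mlp(P, B, (8,), "tanh", seed=7, max_iter=150)
        assert all(np.array_equal(x, y) for x, y in zip(a.coefs, b.coefs))

    def test_forward_pass_matches_sklearn_and_round_trips(self, tmp_path):
        rng = np.random.default_rng(2)
        P, B = rng.normal(1, 1, (60, 2)), rng.normal(0, 1, (60, 2))
        m = fit_mlp(P, B, (6,), "relu", seed=0, max_iter=200)
        m.to_json(tmp_path / "mlp.json")
        m2 = MLPModel.from_json(tmp_path / "mlp.json")
        X = rng.normal(size=(10, 2))
        assert np.allclose(m.predict_pstar(X), m2.predict_pstar(X))


class TestHyperparameterSearch:
    def _data(self):
        rng = np.random.default_rng(3)
        P = rng.normal(1.2, 1, (60, 2))
        B = rng.normal(0, 1, (120, 2))
        return P[:40], B[:80], P[40:], B[80:]

    def test_single_configuration_space(self):
        Xp, Xb, Ep, Eb = self._data()
        space = HyperSearchSpace(hidden_layer_sizes=((5,),), activations=("relu",),
                                 learning_rate_schedules=("constant",),
                                 l1_ratios=(0.0,), max_iters=(100,),
                                 n_trials=1, k_folds=3)
        model, report = hyperparameter_search(space, Xp, Xb, Ep, Eb, seed=0)
        assert len(report) == 3  # 1 trial x 3 folds
        assert model.layer_sizes == (5,)

    def test_winner_has_minimal_mean_cv_loss(self):
        Xp, Xb, Ep, Eb = self._data()
        space = HyperSearchSpace(hidden_layer_sizes=((3,), (6,)),
                                 activations=("relu", "logistic"),
                                 learning_rate_schedules=("constant",),
                                 l1_ratios=(0.0,), max_iters=(100,),
                                 n_trials=5, k_folds=3)
        model, report = hyperparameter_search(space, Xp, Xb, Ep, Eb, seed=1)
        means = report.groupby("trial")["val_log_loss"].mean()
        assert model.training_meta["cv_mean_loss"] == pytest.approx(means.min())
        assert means.min() <= means.median()

    def test_same_seed_reproduces_trials_and_winner(self):
        Xp, Xb, Ep, Eb = self._data()
        space = HyperSearchSpace(hidden_layer_sizes=((3,), (6,)),
                                 activations=("relu",),
                                 learning_rate_schedules=("constant",),
                                 l1_ratios=(0.0,), max_iters=(100,),
                                 n_trials=4, k_folds=3)
        m1, r1 = hyperparameter_search(space, Xp, Xb, Ep, Eb, seed=9)
        m2, r2 = hyperparameter_search(space, Xp, Xb, Ep, Eb, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        assert all(np.array_equal(a, b) for a, b in zip(m1.coefs, m2.coefs))


class TestPermutationImportance:
    @staticmethod
    def _linear_score(weights):
        from scipy.special import expit
        return lambda X: expit(X @ np.asarray(weights))

    def test_unused_feature_has_zero_contribution(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 2))
        y = (X[:, 0] > 0).astype(float)
        contrib = permutation_importance(self._linear_score([4.0, 0.0]), X, y,
                                         n_repeats=3, seed=0)
        assert abs(contrib["z1"]) < 1e-6
        assert contrib["z0"] > 0.5

    def test_single_feature_matches_two_pass_oracle(self):
        from sklearn.metrics import log_loss
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 1))
        y = (X[:, 0] + 0.3 * rng.normal(size=200) > 0).astype(float)
        score = self._linear_score([2.5])
        contrib = permutation_importance(score, X, y, n_repeats=1, seed=42)
        base = log_loss(y, score(X), labels=[0, 1])
        Xp = X.copy()
        Xp[:, 0] = X[np.random.default_rng(42).permutation(200), 0]
        oracle = (log_loss(y, score(Xp), labels=[0, 1]) - base) / base
        assert contrib["z0"] == pytest.approx(oracle)

    def test_contributions_invariant_to_column_order(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 2))
        y = (X[:, 0] + 2 * X[:, 1] > 0).astype(float)
        w = [1.0, 2.0]
        c1 = permutation_importance(self._linear_score(w), X, y,
                                    n_repeats=10, seed=3)
        c2 = permutation_importance(self._linear_score(w[::-1]), X[:, ::-1], y,
                                    groups={"z0": [1], "z1": [0]},
                                    n_repeats=10, seed=3)
        assert c1["z0"] == pytest.approx(c2["z0"], rel=0.2)
        assert c1["z1"] == pytest.approx(c2["z1"], rel=0.2)

    def test_one_hot_group_shuffled_jointly(self):
        rng = np.random.default_rng(4)
        onehot = np.eye(3)[rng.integers(0, 3, 300)]
        X = np.column_stack([rng.normal(size=300), onehot])
        y = onehot[:, 0]
        score = self._linear_score([0.0, 6.0, -3.0, -3.0])
        contrib = permutation_importance(
            score, X, y, groups={"num": [0], "cat": [1, 2, 3]},
            n_repeats=3, seed=0)
        assert contrib["cat"] > 0.5
        assert abs(contrib["num"]) < 1e-6


def test_predict_maxent_over_cell_table(default_world, default_table):
    from aquamap.background import sample_uniform_background, split_presences
    train, _ = split_presences(default_world.presences["borehole"], 0.7, seed=0)
    bg = sample_uniform_background(default_table, default_world.presences,
                                   train.n, 2.0, seed=0)
    df = default_table.df.set_index("cell_id")
    num = default_table.numeric_cols
    cat = [c for c in default_table.feature_cols if c not in num]
    m = fit_maxent(df.loc[train.cells, num].to_numpy(),
                   df.loc[bg.cells, num].to_numpy(),
                   FeatureBasis(("linear", "hinge", "categorical")),
                   presence_categorical=df.loc[train.cells, cat].to_numpy(),
                   background_categorical=df.loc[bg.cells, cat].to_numpy(),
                   categorical_names=cat, numeric_names=num)
    smap = predict_maxent(m, default_table, "borehole")
    assert len(smap.p_star) == len(default_table.df)
    assert smap.p_star.between(0, 1).all()
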