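"""Learner contracts: exactness of federated OLS, sufficient-statistic
additivity, forest training/pooling, and DP protection of shared trees."""

import numpy as np
import pytest

from fedsurvey.fedcore import DPConfig
from fedsurvey.fed_models import (
    ForestHyperparams,
    ForestModel,
    LinearModel,
    SufficientStats,
    aggregate_forests,
    centralized_ols,
    dp_protect_forest,
    fed_forest,
    fed_ols,
    local_sufficient_stats,
    predict,
    train_local_forest,
)
from fedsurvey.synthetic_survey import SurveyTable

from conftest import make_schema, random_table, split_table


class TestSufficientStats:
    def test_hand_computed_example(self):
        table = SurveyTable("s", np.array([[1.0], [2.0]]), np.array([1.0, 2.0]), make_schema(1))
        stats = local_sufficient_stats(table)
        np.testing.assert_allclose(stats.xtx, [[2.0, 3.0], [3.0, 5.0]])
        np.testing.assert_allclose(stats.xty, [3.0, 5.0])
        assert stats.n == 2

    def test_zero_target_gives_zero_xty(self, rng):
        table = SurveyTable("s", rng.normal(size=(10, 3)), np.zeros(10), make_schema(3))
        np.testing.assert_array_equal(local_sufficient_stats(table).xty, np.zeros(4))

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_under_concatenation(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 40, 4)
        a = SurveyTable("a", t.X[:17], t.y[:17], t.schema)
        b = SurveyTable("b", t.X[17:], t.y[17:], t.schema)
        combined = local_sufficient_stats(a) + local_sufficient_stats(b)
        direct = local_sufficient_stats(t)
        np.testing.assert_allclose(combined.xtx, direct.xtx, rtol=1e-12)
        np.testing.assert_allclose(combined.xty, direct.xty, rtol=1e-12)
        assert combined.n == direct.n

    def test_classification_target_rejected(self, tiny_classification_sites):
        with pytest.raises(ValueError, match="regression"):
            local_sufficient_stats(tiny_classification_sites[0])


class TestFedOLS:
    def test_single_site_equals_centralized(self, rng):
        t = random_table(rng, 60, 3)
        np.testing.assert_allclose(
            fed_ols([t]).coefficients, centralized_ols([t]).coefficients, rtol=1e-10
        )

    def test_noiseless_exact_recovery(self, rng):
        sites = []
        for i in range(3):
            X = rng.standard_normal((30, 1))
            sites.append(SurveyTable(str(i), X, 2.0 * X[:, 0], make_schema(1)))
        model = fed_ols(sites)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)
        assert model.slopes[0] == pytest.approx(2.0, abs=1e-8)

    @pytest.mark.parametrize("n_sites", [1, 2, 5, 10])
    def test_partition_invariance(self, n_sites, rng):
        t = random_table(rng, 200, 6)
        sites = split_table(t, rng, n_sites)
        fed = fed_ols(sites).coefficients
        cen = centralized_ols([t]).coefficients
        np.testing.assert_allclose(fed, cen, rtol=1e-8, atol=1e-10)

    def test_smpc_matches_to_fixed_point(self, rng):
        t = random_table(rng, 300, 5)
        sites = split_table(t, rng, 5)
        fed = fed_ols(sites, use_smpc=True, seed=9).coefficients
        cen = centralized_ols([t]).coefficients
        np.testing.assert_allclose(fed, cen, rtol=1e-5, atol=1e-5)

    def test_client_order_invariance(self, rng):
        t = random_table(rng, 120, 4)
        sites = split_table(t, rng, 4)
        a = fed_ols(sites).coefficients
        b = fed_ols(sites[::-1]).coefficients
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_singular_design_raises_named_error(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.column_stack([X, X[:, 0]])  # exact collinearity
        t = SurveyTable("s", X, np.clip(X[:, 0], -100, 100), make_schema(3))
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fed_ols([t])
        # ridge jitter resolves it
        model = fed_ols([t], ridge=True)
        assert np.isfinite(model.coefficients).all()

    def test_parameter_recovery_within_sampling_error(self):
        beta = np.array([2.0, -1.0, 0.5, 0.0, 1.5])
        hits = total = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            t = random_table(rng, 10_000, 5, beta=beta, noise=1.0)
            est = fed_ols(split_table(t, rng, 4)).slopes
            se = 1.0 / np.sqrt(t.n)  # unit-variance regressors, sigma=1
            hits += int(np.sum(np.abs(est - beta) < 3 * se))
            total += 5
        assert hits / total >= 0.95


class TestForests:
    def test_tree_count_and_origins(self, tiny_regression_sites):
        hp = ForestHyperparams(n_estimators=20, max_depth=4)
        f = train_local_forest(tiny_regression_sites[0], hp, seed=0)
        assert len(f.trees) == 20
        assert set(f.origins) == {"a"}

    def test_overfit_regime_zero_training_error(self, rng):
        t = random_table(rng, 30, 2)
        hp = ForestHyperparams(n_estimators=1, max_depth=None, min_samples_leaf=1)
        f = train_local_forest(t, hp, seed=0)
        # a single unrestricted tree memorizes unique rows (no bootstrap in our
        # wrapper? sklearn bootstraps, so check the forest interpolates when
        # many trees vote)
        hp_many = ForestHyperparams(n_estimators=200, max_depth=None, min_samples_leaf=1)
        f = train_local_forest(t, hp_many, seed=0)
        rmse = np.sqrt(np.mean((f.predict(t.X) - t.y) ** 2))
        assert rmse < 0.5 * t.y.std()

    def test_deterministic_given_seed(self, tiny_regression_sites, rng):
        hp = ForestHyperparams(n_estimators=10, max_depth=5)
        probe = rng.normal(size=(20, 4))
        a = train_local_forest(tiny_regression_sites[0], hp, seed=3).predict(probe)
        b = train_local_forest(tiny_regression_sites[0], hp, seed=3).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_site_rejected(self):
        t = SurveyTable("s", np.random.default_rng(0).normal(size=(20, 2)), np.zeros(20), make_schema(2), task="classification")
        with pytest.raises(ValueError, match="single class"):
            train_local_forest(t)

    def test_pooling_counts_and_identity(self, tiny_regression_sites, rng):
        hp = ForestHyperparams(n_estimators=20, max_depth=4)
        forests = [train_local_forest(t, hp, seed=i) for i, t in enumerate(tiny_regression_sites)]
        pooled = aggregate_forests(forests)
        assert len(pooled.trees) == 60
        assert pooled.origins.count("a") == 20
        solo = aggregate_forests([forests[0]])
        probe = rng.normal(size=(15, 4))
        np.testing.assert_array_equal(solo.predict(probe), forests[0].predict(probe))

    def test_pooling_order_invariance(self, tiny_regression_sites, rng):
        hp = ForestHyperparams(n_estimators=5, max_depth=3)
        forests = [train_local_forest(t, hp, seed=i) for i, t in enumerate(tiny_regression_sites)]
        probe = rng.normal(size=(10, 4))
        a = aggregate_forests(forests).predict(probe)
        b = aggregate_forests(forests[::-1]).predict(probe)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_task_mismatch_rejected(self, tiny_regression_sites, tiny_classification_sites):
        fr = train_local_forest(tiny_regression_sites[0], ForestHyperparams(n_estimators=3), seed=0)
        fc = train_local_forest(tiny_classification_sites[0], ForestHyperparams(n_estimators=3), seed=0)
        with pytest.raises(ValueError, match="task"):
            aggregate_forests([fr, fc])


class TestDPForest:
    def test_bypass_leaves_predictions_identical(self, tiny_regression_sites, rng):
        f = train_local_forest(tiny_regression_sites[0], ForestHyperparams(n_estimators=10, max_depth=4), seed=0)
        cfg = DPConfig(epsilon=float("inf"))
        protected = dp_protect_forest(f, cfg, seed=1)
        probe = rng.normal(size=(25, 4))
        np.testing.assert_array_equal(protected.predict(probe), f.predict(probe))

    def test_input_forest_unmodified(self, tiny_regression_sites, rng):
        f = train_local_forest(tiny_regression_sites[0], ForestHyperparams(n_estimators=5, max_depth=4), seed=0)
        probe = rng.normal(size=(10, 4))
        before = f.predict(probe)
        dp_protect_forest(f, DPConfig(epsilon=0.5), seed=1)
        np.testing.assert_array_equal(f.predict(probe), before)

    def test_leaf_values_clipped_before_noise(self, rng):
        t = random_table(rng, 200, 2, beta=np.array([30.0, 0.0]), noise=1.0)
        f = train_local_forest(t, ForestHyperparams(n_estimators=3, max_depth=6), seed=0)
        # near-infinite epsilon: noise negligible, clipping visible
        protected = dp_protect_forest(f, DPConfig(epsilon=1e12), y_range=(-5.0, 5.0), seed=1)
        for tree in protected.trees:
            leaves = tree.tree_.children_left < 0
            vals = tree.tree_.value[leaves, 0, 0]
            assert vals.min() > -5.1 and vals.max() < 5.1

    def test_noise_scale_matches_gaussian_mechanism(self, rng):
        from fedsurvey.fedcore import gaussian_sigma

        t = random_table(rng, 4000, 3, noise=5.0)
        hp = ForestHyperparams(n_estimators=30, max_depth=None, min_samples_leaf=1)
        f = train_local_forest(t, hp, seed=0)
        cfg = DPConfig(epsilon=1.0, delta=1e-5)
        protected = dp_protect_forest(f, cfg, y_range=(-100.0, 100.0), seed=2)
        diffs = []
        for clean, noised in zip(f.trees, protected.trees):
            leaves = clean.tree_.children_left < 0
            min_leaf = clean.tree_.n_node_samples[leaves].min()
            clipped = np.clip(clean.tree_.value[leaves, 0, 0], -100, 100)
            delta = noised.tree_.value[leaves, 0, 0] - clipped
            sigma = gaussian_sigma(DPConfig(epsilon=1.0, delta=1e-5, sensitivity=200.0 / min_leaf))
            diffs.append(delta / sigma)
        z = np.concatenate(diffs)
        assert len(z) > 50_000
        assert abs(z.std() - 1.0) < 0.02

    def test_error_non_increasing_in_epsilon(self):
        rng = np.random.default_rng(0)
        errors = {eps: [] for eps in (0.1, 1.0, 10.0, float("inf"))}
        hp = ForestHyperparams(n_estimators=20, max_depth=6, min_samples_leaf=10)
        for seed in range(10):
            srng = np.random.default_rng(seed)
            t = random_table(srng, 1500, 4, beta=np.array([5.0, 3.0, 1.0, 0.0]), noise=3.0)
            train = SurveyTable("tr", t.X[:1000], t.y[:1000], t.schema)
            X_hold, y_hold = t.X[1000:], t.y[1000:]
            f = train_local_forest(train, hp, seed=seed)
            for eps in errors:
                cfg = DPConfig(epsilon=eps) if np.isfinite(eps) else DPConfig(epsilon=float("inf"))
                protected = dp_protect_forest(f, cfg, seed=seed)
                rmse = np.sqrt(np.mean((protected.predict(X_hold) - y_hold) ** 2))
                errors[eps].append(rmse)
        means = [np.mean(errors[e]) for e in (0.1, 1.0, 10.0, float("inf"))]
        assert means[0] >= means[1] - 1e-3
        assert means[1] >= means[2] - 1e-3
        assert means[2] >= means[3] - 1e-3

    def test_classification_counts_renormalized(self, tiny_classification_sites, rng):
        f = train_local_forest(tiny_classification_sites[0], ForestHyperparams(n_estimators=5, max_depth=5), seed=0)
        protected = dp_protect_forest(f, DPConfig(epsilon=1.0, sensitivity=1.0), seed=3)
        probe = rng.normal(size=(30, 5))
        scores = protected.predict_scores(probe)
        assert np.all((scores >= 0) & (scores <= 1))


class TestPredict:
    def test_linear_hand_example(self):
        model = LinearModel(np.array([0.0, 2.0]))
        np.testing.assert_allclose(model.predict(np.array([[3.0]])), [6.0])

    def test_identical_stumps_vote_their_output(self, rng):
        t = random_table(rng, 50, 2)
        f1 = train_local_forest(t, ForestHyperparams(n_estimators=1, max_depth=1), seed=5)
        stacked = aggregate_forests([f1, f1, f1])
        probe = rng.normal(size=(10, 2))
        np.testing.assert_allclose(stacked.predict(probe), f1.predict(probe), rtol=1e-12)

    def test_classification_scores_consistent_with_labels(self, tiny_classification_sites):
        f = train_local_forest(tiny_classification_sites[0], ForestHyperparams(n_estimators=15, max_depth=5), seed=0)
        labels, scores = predict(f, tiny_classification_sites[1].X)
        assert np.all((scores >= 0) & (scores <= 1))
        np.testing.assert_array_equal(labels, (scores >= 0.5).astype(float))

    def test_dimension_mismatch_rejected(self, tiny_regression_sites):
        model = fed_ols(tiny_regression_sites)
        with pytest.raises(ValueError, match="dimension"):
            model.predict(np.zeros((3, 7)))
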