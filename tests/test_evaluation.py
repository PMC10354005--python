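import numpy as np
import pytest

from mevax.evaluation import (CVPlan, auc_score, classification_metrics,
                              evaluate_solution, feature_complexity,
                              make_cv_plan, make_objective_vector,
                              overall_scores, split_complexity, train_fold, wgm)
from mevax.genome import DecodedModelSpec, HyperparamBounds
from mevax.prescreen import build_prescreen_index
from mevax.fixtures import FixtureSpec, generate
from tests.test_genome import _chrom, _index


class TestCVPlan:
    def test_stratification_on_imbalanced_classes(self):
        y = np.array([1] * 35 + [0] * 54)
        plan = make_cv_plan(y, k=10, base_seed=0, generation=0)
        for fold in plan.folds:
            assert int(y[fold].sum()) in (3, 4)
        all_idx = np.sort(np.concatenate(plan.folds))
        assert np.array_equal(all_idx, np.arange(89))

    def test_same_generation_same_plan(self):
        y = np.repeat([0, 1], 30)
        a = make_cv_plan(y, 10, base_seed=5, generation=3)
        b = make_cv_plan(y, 10, base_seed=5, generation=3)
        for fa, fb in zip(a.folds, b.folds):
            assert np.array_equal(fa, fb)

    def test_generations_differ(self):
        y = np.repeat([0, 1], 30)
        a = make_cv_plan(y, 10, base_seed=5, generation=0)
        b = make_cv_plan(y, 10, base_seed=5, generation=1)
        assert any(not np.array_equal(fa, fb) for fa, fb in zip(a.folds, b.folds))

    def test_small_class_raises(self):
        y = np.array([1] * 5 + [0] * 50)
        with pytest.raises(ValueError, match="smaller k"):
            make_cv_plan(y, 10, 0, 0)


class TestMetrics:
    def test_worked_confusion_matrix(self):
        # TP=3, FN=1, TN=4, FP=2
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        m = classification_metrics(y_true, y_pred, wgm_weight=0.5)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(0.6)
        assert m["recall"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["balanced_accuracy"] == pytest.approx(0.7083, abs=1e-4)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-4)
        assert m["f2"] == pytest.approx(0.7143, abs=1e-4)
        assert m["wgm"] == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1])
        m = classification_metrics(y, y, y.astype(float))
        for key in ("accuracy", "precision", "recall", "f1", "f2",
                    "balanced_accuracy", "auc", "wgm"):
            assert m[key] == 1.0

    def test_all_positive_predictions(self):
        y_true = np.array([1, 0, 0, 1, 0])
        m = classification_metrics(y_true, np.ones(5, int))
        assert m["precision"] == pytest.approx(0.4)  # prevalence
        assert m["recall"] == 1.0
        assert m["specificity"] == 0.0

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn import metrics as sk
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(10, 60)
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            if len(np.unique(y_true)) < 2:
                continue
            m = classification_metrics(y_true, y_pred)
            assert m["accuracy"] == pytest.approx(sk.accuracy_score(y_true, y_pred))
            assert m["precision"] == pytest.approx(
                sk.precision_score(y_true, y_pred, zero_division=0))
            assert m["recall"] == pytest.approx(
                sk.recall_score(y_true, y_pred, zero_division=0))
            assert m["f1"] == pytest.approx(
                sk.f1_score(y_true, y_pred, zero_division=0))
            assert m["f2"] == pytest.approx(
                sk.fbeta_score(y_true, y_pred, beta=2, zero_division=0))
            assert m["balanced_accuracy"] == pytest.approx(
                sk.balanced_accuracy_score(y_true, y_pred))


class TestAUC:
    def test_brute_force_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(10, 100))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # rounded -> ties occur
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = conc / (len(pos) * len(neg))
            assert auc_score(y, s) == pytest.approx(expected, abs=1e-12)

    def test_single_class_returns_zero(self):
        assert auc_score(np.ones(4), np.arange(4.0)) == 0.0


class TestWGM:
    def test_balanced_closed_form(self):
        assert wgm(0.75, 2 / 3, 0.5) == pytest.approx(np.sqrt(0.5))

    def test_zero_law(self):
        assert wgm(0.0, 0.9, 0.3) == 0.0
        assert wgm(0.9, 0.0, 0.3) == 0.0

    def test_exponent_identity(self):
        assert wgm(0.42, 0.9, 1.0) == 0.42
        assert wgm(0.42, 0.9, 0.0) == 0.9


class TestComplexity:
    @pytest.mark.parametrize("n_active,p,expected",
                             [(0, 10, 1.0), (10, 10, 0.0),
                              (9, 13239, 1 - 9 / 13239)])
    def test_feature_complexity(self, n_active, p, expected):
        assert feature_complexity(n_active, p) == pytest.approx(expected)

    @pytest.mark.parametrize("splits,expected",
                             [(0, 1.0), (256, 0.0), (128, 0.5), (999, 0.0)])
    def test_split_complexity(self, splits, expected):
        assert split_complexity(splits, 256) == pytest.approx(expected)


class TestOverall:
    def test_constant_components(self):
        o, w = overall_scores(np.full(10, 0.3))
        assert o == pytest.approx(0.3) and w == pytest.approx(0.3)

    def test_one_hot_weight(self):
        comps = np.linspace(0.1, 1.0, 10)
        weights = np.zeros(10)
        weights[7] = 1.0
        _, w = overall_scores(comps, weights)
        assert w == pytest.approx(comps[7])

    def test_mean_oracle(self):
        comps = np.zeros(10)
        comps[0] = 1.0
        o, _ = overall_scores(comps, np.ones(10))
        assert o == pytest.approx(0.1)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            overall_scores(np.ones(10), np.zeros(10))


def _separable_fold(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)  # interleaved: both classes in every split
    X = (y + rng.normal(0, 0.05, n)).reshape(-1, 1)
    return X[: n - 12], y[: n - 12], X[n - 12:], y[n - 12:]


class TestTrainFold:
    def test_early_stopping_within_patience(self):
        X_tr, y_tr, X_val, y_val = _separable_fold()
        spec = DecodedModelSpec(active_features=[0],
                                classifier_config={"eta": 0.3, "max_depth": 2})
        booster, fr = train_fold(X_tr, y_tr, X_val, y_val, spec)
        assert booster.num_boosted_rounds() <= fr.best_iteration + 1 + 50
        assert auc_score(y_val, fr.y_prob) == 1.0

    def test_depth_one_single_round_has_one_split(self):
        X_tr, y_tr, X_val, y_val = _separable_fold(seed=1)
        spec = DecodedModelSpec(active_features=[0],
                                classifier_config={"eta": 0.3, "max_depth": 1},
                                max_boosting_rounds=1,
                                early_stopping_patience=1)
        _, fr = train_fold(X_tr, y_tr, X_val, y_val, spec)
        assert fr.total_splits == 1

    def test_single_class_training_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="single-class"):
            train_fold(X, np.zeros(10), X, np.zeros(10),
                       DecodedModelSpec([0], {"max_depth": 2}))


class TestEvaluateSolution:
    def test_degenerate_empty_mask(self, planted_dataset, bounds):
        ds, _ = planted_dataset
        idx = build_prescreen_index(ds, 10)
        c = _chrom(p=ds.n_features, bits=())
        plan = make_cv_plan(ds.y, 10, 0, 0)
        sol = evaluate_solution(c, ds, idx, plan, bounds)
        assert sol.degenerate
        arr = sol.objectives.as_array()
        np.testing.assert_allclose(arr[:8], 0.0)
        np.testing.assert_allclose(arr[8:], 1.0)
        assert sol.objectives.overall == pytest.approx(0.2)

    def test_repeat_evaluation_is_identical(self, planted_dataset, bounds):
        ds, informative = planted_dataset
        idx = build_prescreen_index(ds, 10)
        c = _chrom(p=ds.n_features, bits=tuple(informative))
        plan = make_cv_plan(ds.y, 10, 3, 0)
        a = evaluate_solution(c, ds, idx, plan, bounds)
        b = evaluate_solution(c, ds, idx, plan, bounds)
        np.testing.assert_array_equal(a.objectives.as_array(),
                                      b.objectives.as_array())
        np.testing.assert_array_equal(a.oof_probs, b.oof_probs)

    def test_components_in_unit_interval(self, planted_dataset, bounds):
        from mevax.genome import init_population
        ds, _ = planted_dataset
        idx = build_prescreen_index(ds, 10)
        plan = make_cv_plan(ds.y, 10, 1, 0)
        for c in init_population(ds.n_features, 8, bounds, rng=5):
            sol = evaluate_solution(c, ds, idx, plan, bounds)
            sol.objectives.validate()
            assert sol.degenerate == (len(np.unique(sol.oof_labels)) < 2)

    def test_planted_mask_reaches_high_auc(self, bounds):
        """A chromosome holding exactly the informative features separates well."""
        hits, seeds = 0, 15
        for seed in range(seeds):
            fx = generate(FixtureSpec(n_samples=100, n_features=50,
                                      n_informative=5, effect_size=1.2,
                                      class_balance=0.4, seed=100 + seed))
            ds = fx.to_dataset()
            idx = build_prescreen_index(ds, 10)
            c = _chrom(p=50, bits=tuple(fx.informative))
            plan = make_cv_plan(ds.y, 10, seed, 0)
            sol = evaluate_solution(c, ds, idx, plan, bounds)
            if sol.objectives.auc > 0.8:
                hits += 1
        assert hits >= 0.9 * seeds
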