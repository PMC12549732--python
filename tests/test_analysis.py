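import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from gaittwin.analysis import (class_weights, confusion_from_metrics, embed_2d,
                               evaluate_classifier, feature_attribution, impute,
                               kmeans_repeated, minmax_invert, minmax_scale,
                               smote_oversample, train_and_evaluate)
from gaittwin.errors import (AmbiguousSolution, NoSolution, ValidationError)


class TestImpute:
    def test_mean_substitution(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        out, mask = impute(df, "mean")
        assert out["a"].tolist() == [1.0, 2.0, 3.0]
        assert mask["a"].tolist() == [False, True, False]

    def test_median_robust_to_outlier(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0, 100.0]})
        out, _ = impute(df, "median")
        assert out.loc[1, "a"] == 3.0

    def test_complete_table_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out, mask = impute(df, "mean")
        assert out.equals(df) and not mask.any().any()

    def test_all_missing_column_names_offender(self):
        with pytest.raises(ValidationError, match="bad"):
            impute(pd.DataFrame({"bad": [np.nan, np.nan]}), "mean")


class TestMinMax:
    def test_scaling_and_inverse(self):
        df = pd.DataFrame({"a": [0.0, 5.0, 10.0], "b": [2.0, 3.0, 4.0]})
        scaled, params = minmax_scale(df)
        assert scaled["a"].tolist() == [0.0, 0.5, 1.0]
        assert np.allclose(minmax_invert(scaled, params), df, atol=1e-12)

    def test_constant_column_warns_and_zeroes(self):
        df = pd.DataFrame({"c": [7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning):
            scaled, _ = minmax_scale(df)
        assert (scaled["c"] == 0).all()


class TestClassWeights:
    def test_cohort_imbalance_worked_example(self):
        labels = ["low"] * 38 + ["high"] * 8
        w = class_weights(labels)
        assert w["low"] == pytest.approx(46 / 76, abs=1e-12)
        assert w["high"] == pytest.approx(46 / 16, abs=1e-12)

    def test_balanced_gives_unit_weights(self):
        w = class_weights(["a"] * 5 + ["b"] * 5)
        assert w == {"a": 1.0, "b": 1.0}

    def test_weighted_total_identity(self):
        labels = ["x"] * 13 + ["y"] * 4
        w = class_weights(labels)
        assert 13 * w["x"] + 4 * w["y"] == pytest.approx(17.0, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            class_weights(["only"] * 4)


class TestSmote:
    def test_counts_balance_38_8(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(46, 3)))
        y = np.array(["low"] * 38 + ["high"] * 8)
        X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=1)
        assert (y2 == "high").sum() == 38 and (y2 == "low").sum() == 38

    def test_synthetic_points_on_segment(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 5.0, 6.0, 7.0],
                          "y": [0.0, 1.0, 5.0, 6.0, 7.0]})
        y = np.array(["m", "m", "M", "M", "M"])
        X2, y2 = smote_oversample(X, y, k_neighbors=1, seed=0)
        new = X2.iloc[5:]
        assert np.allclose(new["x"], new["y"])        # on the diagonal segment
        assert ((new["x"] >= 0) & (new["x"] <= 1)).all()

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        y = np.array(["a"] * 22 + ["b"] * 8)
        a = smote_oversample(X, y, seed=9)
        b = smote_oversample(X, y, seed=9)
        assert a[0].equals(b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_minority_rejected_with_guidance(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 2)))
        y = np.array(["a"] * 7 + ["b"] * 3)
        with pytest.raises(ValidationError, match="k_neighbors"):
            smote_oversample(X, y, k_neighbors=5)


class TestEmbed:
    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, size=(40, 6)),
                       rng.normal(8, 0.3, size=(40, 6))])
        labels = np.array([0] * 40 + [1] * 40)
        coords, score = embed_2d(X, seed=0, perplexity=10)
        assert silhouette_score(coords, labels) > 0.5
        assert score > 0.2

    def test_duplicated_rows_embeddable(self):
        X = np.tile(np.random.default_rng(5).normal(size=(20, 3)), (2, 1))
        coords, _ = embed_2d(X, seed=0, perplexity=10)
        assert coords.shape == (40, 2)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(6).normal(size=(40, 5))
        a, _ = embed_2d(X, seed=3)
        b, _ = embed_2d(X, seed=3)
        assert np.array_equal(a, b)

    def test_too_small_raises(self):
        with pytest.raises(ValidationError):
            embed_2d(np.zeros((5, 2)), seed=0, perplexity=10)


class TestKmeans:
    def _blobs(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.uniform(0, 1, size=(60, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X.loc[30:, "f3"] += 2.0      # separation only on feature 3
        truth = np.array([0] * 30 + [1] * 30)
        return X, truth

    def test_blob_recovery_and_importance_ranking(self):
        from sklearn.metrics import adjusted_rand_score
        X, truth = self._blobs()
        res = kmeans_repeated(X, seed=0)
        assert adjusted_rand_score(truth, res.consensus) == 1.0
        assert res.importance_mean.index[0] == "f3"

    def test_stable_clustering_has_zero_importance_sd(self):
        X, _ = self._blobs()
        res = kmeans_repeated(X, seed=0)
        assert res.importance_sd.max() == pytest.approx(0.0, abs=1e-9)

    def test_kde_returned_for_top_features(self):
        X, _ = self._blobs()
        res = kmeans_repeated(X, seed=0)
        assert "f3" in res.kde
        grid, dens = res.kde["f3"][0]
        assert len(grid) == len(dens) == 100

    def test_fewer_samples_than_clusters(self):
        with pytest.raises(ValidationError):
            kmeans_repeated(pd.DataFrame({"a": [1.0]}), seed=0)


class TestEvaluate:
    @pytest.mark.parametrize("matrix, expect", [
        # counts -> (Acc, BA, precision, recall, F1, MCC) at 2 d.p.
        ((2, 2, 0, 8), (0.83, 0.90, 0.50, 1.00, 0.67, 0.63)),
        ((0, 0, 2, 10), (0.83, 0.50, 0.00, 0.00, 0.00, 0.00)),
        ((1, 2, 1, 8), (0.75, 0.65, 0.33, 0.50, 0.40, 0.26)),
        ((2, 1, 0, 9), (0.92, 0.95, 0.67, 1.00, 0.80, 0.77)),
    ])
    def test_metric_closed_forms(self, matrix, expect):
        rep = evaluate_classifier(*matrix)
        r = rep.rounded()
        assert (r["Acc"], r["BA"], r["precision"], r["recall"], r["F1"],
                r["MCC"]) == expect

    def test_auc_rank_statistic(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        rep = evaluate_classifier(2, 0, 0, 2, scores=scores,
                                  y_true=np.array([1, 1, 0, 0]))
        assert rep.AUC == 1.0
        tied = evaluate_classifier(1, 1, 1, 1, scores=np.array([0.5] * 4),
                                   y_true=np.array([1, 1, 0, 0]))
        assert tied.AUC == 0.5

    def test_score_length_mismatch(self):
        with pytest.raises(ValidationError):
            evaluate_classifier(1, 1, 1, 1, scores=np.array([0.5]),
                                y_true=np.array([1, 0]))

    def test_mcc_bounded(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(0, 20, size=4)
            if tp + fp + fn + tn == 0:
                continue
            rep = evaluate_classifier(int(tp), int(fp), int(fn), int(tn))
            assert -1.0 <= rep.MCC <= 1.0


class TestConfusionFromMetrics:
    @pytest.mark.parametrize("metrics, expect", [
        ((12, 2, 0.83, 0.50, 1.00), (2, 2, 0, 8)),
        ((12, 2, 0.92, 0.67, 1.00), (2, 1, 0, 9)),
        ((12, 2, 0.75, 0.33, 0.50), (1, 2, 1, 8)),
    ])
    def test_unique_reconstruction(self, metrics, expect):
        assert confusion_from_metrics(*metrics) == expect

    def test_no_solution(self):
        with pytest.raises(NoSolution):
            confusion_from_metrics(12, 2, 0.99, 0.10, 0.10)

    def test_ambiguous_solution(self):
        # with large denominators several integer matrices round to the same
        # printed metrics, so the reconstruction must refuse to guess
        with pytest.raises(AmbiguousSolution):
            confusion_from_metrics(600, 300, 0.9, 0.9, 0.9)


def _separable_data(n=60, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
    y = np.array(["low"] * (n - n // 4) + ["high"] * (n // 4))
    if informative:
        X.loc[y == "high", "f0"] += 4.0
    return X, y


class TestTrainAndEvaluate:
    def test_separable_features_give_perfect_recall(self):
        X, y = _separable_data()
        res = train_and_evaluate(X, y, model_spec="logreg", seed=1, n_iter=5)
        assert res.report.recall == 1.0

    def test_shuffled_labels_stay_near_chance(self):
        """Permutation null: with labels shuffled there is nothing to learn,
        so test balanced accuracy must hover around 0.5 (no leakage)."""
        X, y = _separable_data(n=48, seed=2)
        rng = np.random.default_rng(0)
        bas = []
        for s in range(20):
            ys = rng.permutation(y)
            if pd.Series(ys).value_counts().min() < 2:
                continue
            res = train_and_evaluate(X, ys, model_spec="logreg", seed=s, n_iter=3)
            bas.append(res.report.BA)
        assert 0.2 <= np.mean(bas) <= 0.8

    def test_smote_confined_to_training_partition(self):
        X, y = _separable_data(n=64, seed=3)
        res = train_and_evaluate(X, y, model_spec="logreg", seed=4,
                                 use_smote=True, n_iter=3)
        assert len(res.y_test) == len(res.test_index)     # no synthetic in test
        assert len(res.X_test) == len(res.test_index)

    def test_preprocessing_fit_on_training_only(self):
        """Corrupting test-partition rows must not change anything fit on the
        training side (CV score, selected hyper-parameters)."""
        X, y = _separable_data(n=60, seed=5)
        res = train_and_evaluate(X, y, model_spec="logreg", seed=6, n_iter=5)
        X_bad = X.copy()
        X_bad.iloc[res.test_index] = 1e6
        res_bad = train_and_evaluate(X_bad, y, model_spec="logreg", seed=6, n_iter=5)
        assert res_bad.report.search_meta["cv_score"] == res.report.search_meta["cv_score"]
        assert res_bad.report.search_meta["best_params"] == res.report.search_meta["best_params"]
        # and the corrupted test rows land far outside the unit interval
        assert res_bad.X_test.to_numpy().max() > 10

    def test_each_model_family_trains(self):
        X, y = _separable_data(n=40, seed=7)
        for name in ("svm", "dtree", "rf", "xgboost"):
            res = train_and_evaluate(X, y, model_spec=name, seed=8, n_iter=3)
            assert res.report.TP + res.report.FN == (np.asarray(y)[res.test_index] == "high").sum()


class TestAttribution:
    def test_informative_feature_ranks_first_and_noise_near_zero(self):
        X, y = _separable_data(n=80, seed=9)
        res = train_and_evaluate(X, y, model_spec="logreg", seed=10, n_iter=5)
        attr = feature_attribution(res.estimator, res.X_test, res.y_test,
                                   repeats=30, seed=0)
        assert attr.feature.iloc[0] == "f0"
        noise_imp = attr[attr.feature != "f0"].importance.abs().max()
        assert noise_imp <= 0.25

    def test_deterministic_given_seed(self):
        X, y = _separable_data(n=60, seed=11)
        res = train_and_evaluate(X, y, model_spec="rf", seed=12, n_iter=3)
        a = feature_attribution(res.estimator, res.X_test, res.y_test, seed=5)
        b = feature_attribution(res.estimator, res.X_test, res.y_test, seed=5)
        assert a.equals(b)

    def test_exact_adapter_for_xgboost(self):
        X, y = _separable_data(n=60, seed=13)
        res = train_and_evaluate(X, y, model_spec="xgboost", seed=14, n_iter=3)
        attr = feature_attribution(res.estimator, res.X_test, res.y_test,
                                   exact=True, seed=0)
        assert attr.feature.iloc[0] == "f0"
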