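import numpy as np
import pandas as pd
import pytest

from thetanav.classify import (
    CLASSIFIER_NAMES, ClassifierSpec, FeatureTable, assemble_feature_table,
    auroc, build_classifier, loocv_evaluate,
)
from thetanav.errors import (
    ConfigError, UndefinedMetricError, ValidationError,
)


def pair_counting_auroc(scores, labels):
    """O(n^2) oracle: P(score_pos > score_neg) with ties counting 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def make_table(X, y, dataset="eeg", trial=12):
    idx = [f"s{i}" for i in range(len(y))]
    return FeatureTable(
        X=pd.DataFrame(X, index=pd.Index(idx, name="subject_id"),
                       columns=[f"f{j}" for j in range(X.shape[1])]),
        y=pd.Series(y, index=pd.Index(idx, name="subject_id"), name="label"),
        dataset=dataset, trial=trial,
    )


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 30))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            assert auroc(scores, labels) == pytest.approx(
                pair_counting_auroc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.normal(size=40)
        base = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(base)
        assert auroc(3 * scores - 7, labels) == pytest.approx(base)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.9], [1, 1])


class TestFeatureTable:
    def test_missing_cells_rejected(self):
        X = np.ones((4, 2))
        X[1, 1] = np.nan
        with pytest.raises(ValidationError):
            make_table(X, [0, 1, 0, 1])

    def test_assemble_coordinates_has_four_columns(self, rng):
        idx = pd.Index(["a", "b", "c", "d"], name="subject_id")
        traj = pd.DataFrame(rng.normal(size=(4, 4)), index=idx, columns=[
            "total_idle_time", "total_path_length", "total_angle_shift",
            "average_speed"])
        labels = pd.Series([1, 1, 0, 0], index=idx)
        table = assemble_feature_table(traj_feats=traj, labels=labels,
                                       dataset="coordinates", trial=1)
        assert table.X.shape[1] == 4

    def test_assemble_combined_is_column_union(self, rng):
        idx = pd.Index(["a", "b", "c", "d"], name="subject_id")
        hmm = pd.DataFrame(rng.normal(size=(4, 3)), index=idx,
                           columns=["hmm_mean_1", "hmm_var_1", "duration"])
        lmm = pd.DataFrame(rng.normal(size=(4, 2)), index=idx,
                           columns=["lmm_intercept", "lmm_slope"])
        traj = pd.DataFrame(rng.normal(size=(4, 1)), index=idx,
                            columns=["total_path_length"])
        labels = pd.Series([1, 0, 1, 0], index=idx)
        table = assemble_feature_table(hmm, lmm, traj, labels,
                                       dataset="combined", trial=12)
        assert list(table.X.columns) == [
            "hmm_mean_1", "hmm_var_1", "duration", "lmm_intercept",
            "lmm_slope", "total_path_length"]

    def test_assemble_reports_missing_subjects(self, rng):
        idx = pd.Index(["a", "b", "c"], name="subject_id")
        hmm = pd.DataFrame(rng.normal(size=(3, 2)), index=idx)
        lmm = pd.DataFrame(rng.normal(size=(2, 2)), index=idx[:2],
                           columns=["lmm_intercept", "lmm_slope"])
        labels = pd.Series([1, 0, 1], index=idx)
        with pytest.raises(ValidationError, match="c"):
            assemble_feature_table(hmm, lmm, None, labels, dataset="eeg",
                                   trial=1)


class TestClassifierSpecs:
    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierSpec("gradient_boosting")

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_all_six_configurations_build_and_score(self, name, rng):
        X = rng.normal(size=(20, 5))
        y = (X[:, 0] > 0).astype(int)
        clf = build_classifier(ClassifierSpec(name, seed=0))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        from thetanav.classify import continuous_score
        s = continuous_score(clf, X)
        assert s.shape == (20,)
        assert np.all(np.isfinite(s))

    def test_dnn_layer_widths_as_configured(self):
        clf = build_classifier(ClassifierSpec("dnn", seed=0))
        assert clf.hidden_layer_sizes == (100, 150, 200, 150, 46, 20, 10)

    def test_elastic_net_l2_dominant_mixing(self):
        clf = build_classifier(ClassifierSpec("elastic_net_logistic", seed=0))
        # alpha = 0.98 multiplies the L2 term -> l1_ratio = 0.02
        assert clf.l1_ratio == pytest.approx(0.02)


class TestLoocv:
    def test_one_score_per_subject(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.r_[np.ones(6), np.zeros(6)]
        res = loocv_evaluate(make_table(X, y), "knn")
        assert len(res.scores) == 12
        assert 0.0 <= res.auroc <= 1.0

    def test_perfectly_separable_knn_gets_auroc_one(self, rng):
        X = np.vstack([rng.normal(5, 0.1, size=(8, 2)),
                       rng.normal(-5, 0.1, size=(8, 2))])
        y = np.r_[np.ones(8), np.zeros(8)]
        res = loocv_evaluate(make_table(X, y), "knn")
        assert res.auroc == 1.0

    def test_permuted_labels_give_chance_auroc(self, rng):
        X = rng.normal(size=(20, 4))
        vals = []
        for _ in range(50):
            y = rng.permutation(np.r_[np.ones(10), np.zeros(10)])
            res = loocv_evaluate(make_table(X, y),
                                 ClassifierSpec("knn", seed=0))
            vals.append(res.auroc)
        assert 0.4 <= np.mean(vals) <= 0.6

    def test_too_few_subjects_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValidationError):
            loocv_evaluate(make_table(X, [1, 0, 1]), "knn")

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.r_[np.ones(5), np.zeros(5)]
        spec = ClassifierSpec("random_forest", {"n_estimators": 20}, seed=7)
        r1 = loocv_evaluate(make_table(X, y), spec)
        r2 = loocv_evaluate(make_table(X, y), spec)
        pd.testing.assert_series_equal(r1.scores, r2.scores)


class TestLmmModes:
    def test_modes_identical_without_lmm_columns(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.r_[np.ones(5), np.zeros(5)]
        table = make_table(X, y)
        a = loocv_evaluate(table, ClassifierSpec("knn", seed=0),
                           lmm_mode="per_fold")
        b = loocv_evaluate(table, ClassifierSpec("knn", seed=0),
                           lmm_mode="fit_once")
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_modes_differ_only_through_lmm_features(self, rng):
        """Refitting the peak mixed model per fold perturbs only the two
        BLUP columns; with those columns removed the two modes coincide."""
        from thetanav.lmm import PeakSet, PeakLMM, lmm_features

        n = 12
        peaksets = {}
        for i in range(n):
            x = rng.normal(-1, 1, size=12)
            yv = 1.0 + (0.5 + 0.3 * rng.normal()) * x \
                + rng.normal(0, 0.3, size=12)
            peaksets[f"s{i}"] = PeakSet(
                subject_id=f"s{i}", trial=12, indices=np.arange(12),
                heights=yv, curvatures=x)
        fit = PeakLMM(list(peaksets.values())).fit()
        blups = lmm_features(fit)
        other = pd.DataFrame(rng.normal(size=(n, 2)), index=blups.index,
                             columns=["a", "b"])
        X = pd.concat([other, blups], axis=1)
        y = pd.Series(np.r_[np.ones(n // 2), np.zeros(n // 2)],
                      index=blups.index)
        table = FeatureTable(X=X, y=y, dataset="eeg", trial=12)
        res_fold = loocv_evaluate(table, ClassifierSpec("knn", seed=0),
                                  peaksets=peaksets, lmm_mode="per_fold")
        res_once = loocv_evaluate(table, ClassifierSpec("knn", seed=0),
                                  peaksets=peaksets, lmm_mode="fit_once")
        # scores generally differ through the refitted BLUP columns...
        table_nolmm = FeatureTable(X=other, y=y, dataset="eeg", trial=12)
        a = loocv_evaluate(table_nolmm, ClassifierSpec("knn", seed=0),
                           peaksets=peaksets, lmm_mode="per_fold")
        b = loocv_evaluate(table_nolmm, ClassifierSpec("knn", seed=0),
                           peaksets=peaksets, lmm_mode="fit_once")
        # ...but with the LMM columns absent the modes are identical
        pd.testing.assert_series_equal(a.scores, b.scores)
        assert len(res_fold.scores) == len(res_once.scores) == n
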