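import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from plasmaftir.classify import PLSDAClassifier, RandomForestOOBClassifier
from plasmaftir.evaluate import (
    ConfusionMatrix,
    confusion_from_predictions,
    confusion_metrics,
    evaluate_subgroups,
    importance_pls,
    importance_rf,
    importance_rocfilter,
    permutation_test_accuracy,
    roc_auc,
    smooth_roc,
)


def pairwise_concordance_auc(scores, labels):
    """Exhaustive oracle: P(MS score > HC score), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == "MS"]
    neg = scores[np.asarray(labels) == "HC"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_study_granularity_example(self):
        sens, spec, acc = confusion_metrics(ConfusionMatrix(7, 2, 10, 2))
        assert sens == pytest.approx(7 / 9)
        assert spec == pytest.approx(10 / 12)
        assert acc == pytest.approx(17 / 21)

    def test_perfect_prediction(self):
        assert confusion_metrics(ConfusionMatrix(9, 0, 12, 0)) == (1.0, 1.0, 1.0)

    def test_all_predicted_ms(self):
        sens, spec, _ = confusion_metrics(ConfusionMatrix(9, 0, 0, 12))
        assert (sens, spec) == (1.0, 0.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            confusion_metrics(ConfusionMatrix(0, 0, 5, 5))

    def test_from_predictions(self):
        y = np.array(["MS", "MS", "HC", "HC"])
        pred = np.array(["MS", "HC", "HC", "MS"])
        cm = confusion_from_predictions(y, pred)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)


class TestROC:
    def test_four_point_example(self):
        curve = roc_auc([0.9, 0.8, 0.3, 0.1], ["MS", "HC", "MS", "HC"])
        assert curve.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        curve = roc_auc([1, 2, 8, 9], ["HC", "HC", "MS", "MS"])
        assert curve.auc == 1.0

    def test_label_inversion_symmetry(self):
        scores = np.random.default_rng(0).normal(size=30)
        labels = np.array(["MS"] * 15 + ["HC"] * 15)
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, labels[::-1]).auc  # swap classes
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_endpoints(self):
        curve = roc_auc([0.2, 0.5, 0.7], ["HC", "MS", "MS"])
        assert curve.sensitivity[0] == 0.0 and curve.specificity[0] == 1.0
        assert curve.sensitivity[-1] == 1.0 and curve.specificity[-1] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_concordance_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        labels = np.array(["MS", "HC"] * n)[:n]
        if len(set(labels)) < 2:
            labels[0] = "MS"
        # coarse scores force ties
        scores = rng.integers(0, 5, size=n).astype(float)
        auc = roc_auc(scores, labels).auc
        assert auc == pytest.approx(pairwise_concordance_auc(scores, labels),
                                    abs=1e-12)
        assert auc == pytest.approx(
            roc_auc_score((labels == "MS").astype(int), scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["MS", "MS"])


class TestSmoothROC:
    def test_null_scores_give_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=400)
        labels = np.array(["MS", "HC"] * 200)
        assert smooth_roc(scores, labels).auc == pytest.approx(0.5, abs=0.08)

    def test_unit_effect_matches_binormal_closed_form(self):
        rng = np.random.default_rng(1)
        n = 10_000
        scores = np.r_[rng.normal(0, 1, n), rng.normal(np.sqrt(2), 1, n)]
        labels = np.array(["HC"] * n + ["MS"] * n)
        assert smooth_roc(scores, labels).auc == pytest.approx(
            norm.cdf(1.0), abs=0.01
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_empirical_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.r_[rng.normal(0, 1, 100), rng.normal(1.2, 1.3, 100)]
        labels = np.array(["HC"] * 100 + ["MS"] * 100)
        emp = roc_auc(scores, labels).auc
        smo = smooth_roc(scores, labels).auc
        assert abs(smo - emp) <= 0.05

    def test_zero_variance_falls_back_to_empirical(self):
        scores = np.array([1.0, 1.0, 0.0, 0.2])
        labels = np.array(["MS", "MS", "HC", "HC"])
        curve = smooth_roc(scores, labels)
        assert curve.smoothed == {"ok": False,
                                  "reason": "zero within-class score variance"}
        assert curve.auc == roc_auc(scores, labels).auc


class TestPermutationTest:
    def test_unbeatable_observed_gives_floor_p(self):
        y = np.array(["MS"] * 10 + ["HC"] * 10)

        def pipeline(X, labels):
            # degenerate protocol: accuracy 1 only for the true labelling
            return 1.0 if (labels == y).all() else 0.0

        p, observed, permuted = permutation_test_accuracy(
            pipeline, np.zeros((20, 2)), y, n_permutations=1000, seed=0
        )
        assert observed == 1.0
        assert p == pytest.approx(1 / 1001, abs=1e-9)

    def test_p_strictly_positive_even_when_null_wins(self):
        def pipeline(X, labels):
            return 0.5

        p, _, _ = permutation_test_accuracy(
            pipeline, np.zeros((6, 1)), np.array(["MS", "HC"] * 3),
            n_permutations=50, seed=1,
        )
        assert 0 < p <= 1.0
        assert p == 1.0  # every permutation ties the observed accuracy


class TestImportancePLS:
    def test_single_informative_column_dominates(self):
        rng = np.random.default_rng(0)
        y = np.array(["HC"] * 25 + ["MS"] * 25)
        X = rng.normal(size=(50, 50))
        X[:, 17] = (y == "MS") + rng.normal(scale=0.05, size=50)
        model = PLSDAClassifier(n_components=1).fit(X, y)
        prof = importance_pls(model, np.arange(50))
        assert prof.importance.argmax() == 17
        assert (prof.importance >= 0).all()

    def test_duplicated_noise_column_stays_irrelevant(self):
        rng = np.random.default_rng(1)
        y = np.array(["HC"] * 20 + ["MS"] * 20)
        X = rng.normal(size=(40, 10))
        X[:, 0] = (y == "MS") + rng.normal(scale=0.05, size=40)
        X[:, 9] = X[:, 8]  # duplicate an uninformative column
        prof = importance_pls(PLSDAClassifier(n_components=2).fit(X, y),
                              np.arange(10))
        assert prof.importance[8] < 0.2 * prof.importance[0]
        assert prof.importance[9] < 0.2 * prof.importance[0]


class TestImportanceRF:
    def test_informative_column_ranks_first(self):
        rng = np.random.default_rng(2)
        y = np.array(["HC"] * 30 + ["MS"] * 30)
        X = rng.normal(size=(60, 20))
        X[:, 7] = (y == "MS") * 2 + rng.normal(scale=0.2, size=60)
        model = RandomForestOOBClassifier(n_trees=200, random_state=0).fit(X, y)
        prof = importance_rf(model, np.arange(20))
        assert prof.importance.argmax() == 7

    def test_pure_noise_centers_on_zero(self):
        rng = np.random.default_rng(3)
        y = np.array(["HC", "MS"] * 20)
        X = rng.normal(size=(40, 15))
        model = RandomForestOOBClassifier(n_trees=200, random_state=1).fit(X, y)
        prof = importance_rf(model, np.arange(15))
        assert abs(np.mean(prof.importance)) < 1.0  # t-scale values near 0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        y = np.array(["HC", "MS"] * 15)
        X = rng.normal(size=(30, 8))
        m1 = RandomForestOOBClassifier(n_trees=80, random_state=5).fit(X, y)
        m2 = RandomForestOOBClassifier(n_trees=80, random_state=5).fit(X, y)
        np.testing.assert_array_equal(
            importance_rf(m1, np.arange(8)).importance,
            importance_rf(m2, np.arange(8)).importance,
        )


class TestImportanceROCFilter:
    def test_class_code_column_scores_one(self):
        y = np.array(["HC"] * 10 + ["MS"] * 10)
        X = np.random.default_rng(0).normal(size=(20, 3))
        X[:, 1] = (y == "MS").astype(float)
        prof = importance_rocfilter(X, y)
        assert prof.importance[1] == pytest.approx(1.0)

    def test_folding_is_direction_agnostic(self):
        y = np.array(["HC"] * 10 + ["MS"] * 10)
        X = np.zeros((20, 2))
        X[:, 0] = (y == "MS").astype(float)
        X[:, 1] = -X[:, 0]  # AUC 0 before folding
        prof = importance_rocfilter(X, y)
        np.testing.assert_allclose(prof.importance, 1.0)

    def test_independent_variable_near_half(self):
        rng = np.random.default_rng(1)
        y = np.array(["HC", "MS"] * 500)
        X = rng.normal(size=(1000, 2))
        prof = importance_rocfilter(X, y)
        np.testing.assert_allclose(prof.importance, 0.5, atol=0.06)
        assert (prof.importance >= 0.5).all()  # folded lower bound


class TestSubgroups:
    def _meta(self):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(7)],
                "class_label": ["MS", "MS", "MS", "MS", "HC", "HC", "HC"],
                "edss": [1.0, 2.0, 5.0, 6.0, np.nan, np.nan, np.nan],
                "onset_years": [3.0, 12.0, 4.0, 20.0, np.nan, np.nan, np.nan],
            }
        )

    def test_mild_hit_severe_missed(self):
        pred = np.array(["MS", "MS", "HC", "HC", "HC", "HC", "MS"])
        table = evaluate_subgroups(pred, self._meta()).set_index("subgroup")
        assert table.loc["edss_mild", "sensitivity"] == 1.0
        assert table.loc["edss_moderate_severe", "sensitivity"] == 0.0

    def test_subgroup_true_positives_partition_overall(self):
        pred = np.array(["MS", "HC", "MS", "MS", "HC", "MS", "HC"])
        table = evaluate_subgroups(pred, self._meta()).set_index("subgroup")
        tp = {g: table.loc[g, "sensitivity"] * table.loc[g, "n_MS"]
              for g in table.index}
        assert tp["edss_mild"] + tp["edss_moderate_severe"] == tp["overall"]
        assert tp["onset_short"] + tp["onset_long"] == tp["overall"]

    def test_specificity_constant_across_rows(self):
        pred = np.array(["MS", "HC", "MS", "MS", "HC", "MS", "HC"])
        table = evaluate_subgroups(pred, self._meta())
        assert table["specificity"].nunique() == 1
        assert table["specificity"].iloc[0] == pytest.approx(2 / 3)

    def test_empty_subgroup_reports_nan(self):
        meta = self._meta()
        meta["edss"] = [1.0, 2.0, 2.5, 3.0, np.nan, np.nan, np.nan]
        pred = np.array(["MS"] * 7)
        table = evaluate_subgroups(pred, meta).set_index("subgroup")
        assert np.isnan(table.loc["edss_moderate_severe", "sensitivity"])
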