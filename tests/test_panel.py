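import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import capomics as c
from capomics.panel import CLASSIFIERS, SensSpec

from conftest import make_metadata, make_table


class TestRocAuc:
    def test_perfect_separation(self):
        rc = c.roc_auc([0.9, 0.8, 0.2, 0.1], ["p", "p", "n", "n"], positive="p")
        assert rc.auc == 1.0

    def test_interleaved_scores_count_concordant_pairs(self):
        # pos {0.9, 0.2}, neg {0.8, 0.1}: 3 of 4 pairs concordant
        rc = c.roc_auc([0.9, 0.2, 0.8, 0.1], ["p", "p", "n", "n"], positive="p")
        assert rc.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        rc = c.roc_auc([1.0, 1.0, 1.0, 1.0], ["p", "p", "n", "n"], positive="p")
        assert rc.auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle_with_ties(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(3, 20, size=2)
            # integer scores force ties
            pos = rng.integers(0, 8, n1).astype(float)
            neg = rng.integers(0, 8, n2).astype(float)
            scores = np.concatenate([pos, neg])
            labels = ["p"] * n1 + ["n"] * n2
            rc = c.roc_auc(scores, labels, positive="p", orientation="higher_is_positive")
            u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert rc.auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_monotone_transform_leaves_auc_unchanged(self, rng):
        scores = rng.normal(size=30)
        labels = rng.choice(["p", "n"], size=30)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "p", "n"
        a1 = c.roc_auc(scores, labels, positive="p").auc
        a2 = c.roc_auc(np.exp(3 * scores), labels, positive="p").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_auto_orientation_flips_decreasing_marker(self):
        rc = c.roc_auc([0.1, 0.2, 0.8, 0.9], ["p", "p", "n", "n"], positive="p")
        assert rc.orientation == "lower_is_positive"
        assert rc.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            c.roc_auc([1.0, 2.0], ["p", "p"], positive="p")

    def test_curve_is_monotone(self, rng):
        scores = rng.normal(size=50)
        labels = ["p"] * 25 + ["n"] * 25
        rc = c.roc_auc(scores, labels, positive="p")
        assert (np.diff(rc.tpr) >= 0).all()
        assert (np.diff(rc.fpr) >= 0).all()


class TestFilterCandidates:
    def _inputs(self):
        records = pd.DataFrame(
            {"log2fc": [2.0, 1.5, 0.3, -2.0]},
            index=pd.Index(["A", "B", "C", "D"], name="feature_id"),
        )
        aucs = pd.DataFrame(
            {"max_auc": [0.95, 0.95, 0.99, 0.85]},
            index=pd.Index(["A", "B", "C", "D"], name="feature_id"),
        )
        return records, aucs

    def test_floors_and_ranking(self):
        records, aucs = self._inputs()
        cand = c.filter_candidates(records, aucs, min_auc=0.9, min_fc=1.5)
        # C fails the FC floor, D fails the AUC floor
        assert list(cand.index) == ["A", "B"]

    def test_equal_auc_and_fc_break_ties_by_feature_id(self):
        records = pd.DataFrame(
            {"log2fc": [1.0, 1.0]}, index=pd.Index(["Z", "K"], name="feature_id")
        )
        aucs = pd.DataFrame(
            {"max_auc": [0.9, 0.9]}, index=pd.Index(["Z", "K"], name="feature_id")
        )
        cand = c.filter_candidates(records, aucs, min_auc=0.5, min_fc=1.2)
        assert list(cand.index) == ["K", "Z"]

    def test_required_annotation_excludes_unflagged(self):
        records, aucs = self._inputs()
        ann = pd.DataFrame({
            "feature_id": ["A", "B"],
            "display_name": ["a", "b"],
            "flags": [frozenset({"immunity"}), frozenset()],
        })
        cand = c.filter_candidates(records, aucs, annotations=ann,
                                   min_auc=0.9, min_fc=1.5, require_annotation=True)
        assert list(cand.index) == ["A"]

    def test_empty_result_warns_not_raises(self):
        records, aucs = self._inputs()
        with pytest.warns(UserWarning, match="no candidates"):
            cand = c.filter_candidates(records, aucs, min_auc=1.1, min_fc=1.5)
        assert cand.empty


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "pred,actual,sens,spec",
        [
            (["p"] * 5 + ["n"] * 5, ["p"] * 5 + ["n"] * 5, 1.0, 1.0),
            (["n"] * 10, ["p"] * 5 + ["n"] * 5, 0.0, 1.0),
        ],
    )
    def test_confusion_table_examples(self, pred, actual, sens, spec):
        ss = c.sensitivity_specificity(pred, actual, positive="p")
        assert ss.sensitivity == pytest.approx(sens)
        assert ss.specificity == pytest.approx(spec)

    def test_matches_brute_force_tally(self, rng):
        for _ in range(50):
            pred = rng.choice(["p", "n", "x"], size=20)
            actual = rng.choice(["p", "n"], size=20)
            ss = c.sensitivity_specificity(pred, actual, positive="p")
            tp = sum(1 for a, b in zip(pred, actual) if a == "p" and b == "p")
            fn = sum(1 for a, b in zip(pred, actual) if a != "p" and b == "p")
            tn = sum(1 for a, b in zip(pred, actual) if a != "p" and b != "p")
            fp = sum(1 for a, b in zip(pred, actual) if a == "p" and b != "p")
            if tp + fn:
                assert ss.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert ss.specificity == pytest.approx(tn / (tn + fp))

    def test_undefined_rate_flagged_not_nan(self):
        ss = c.sensitivity_specificity(["n", "n"], ["n", "n"], positive="p")
        assert ss.sensitivity is None
        assert "sensitivity" in ss.undefined
        assert ss.specificity == 1.0


class TestSelectPanel:
    def test_recovers_planted_markers_on_small_cohort(self, small_cohort):
        tables, meta, truth = small_cohort
        panel_truth = truth[truth.is_panel_marker]
        prot = list(panel_truth.loc[panel_truth.layer == "protein", "feature_id"])
        metab = list(panel_truth.loc[panel_truth.layer == "metabolite", "feature_id"])
        # hand the true markers plus decoys as candidates
        decoy_p = list(truth[(truth.layer == "protein") & (truth.pattern == "flat")]
                       .feature_id[:4])
        decoy_m = list(truth[(truth.layer == "metabolite") & (truth.pattern == "flat")]
                       .feature_id[:2])
        panel = c.select_panel(prot + decoy_p, metab + decoy_m, tables, meta, cohort="train")
        selected = {f for _, f in panel.selected_markers}
        assert len(selected & set(prot + metab)) >= 3
        assert {f for _, f in panel.markers} <= selected

    def test_panel_markers_are_exactly_tree_split_variables(self, small_cohort):
        tables, meta, truth = small_cohort
        panel_truth = truth[truth.is_panel_marker]
        prot = list(panel_truth.loc[panel_truth.layer == "protein", "feature_id"])
        metab = list(panel_truth.loc[panel_truth.layer == "metabolite", "feature_id"])
        panel = c.select_panel(prot, metab, tables, meta, cohort="train")
        split_names = {panel.tree.feature_names_[j] for j in panel.tree.split_features()}
        assert {f for _, f in panel.markers} == split_names

    def test_deterministic_serialization(self, small_cohort):
        tables, meta, truth = small_cohort
        panel_truth = truth[truth.is_panel_marker]
        prot = list(panel_truth.loc[panel_truth.layer == "protein", "feature_id"])
        metab = list(panel_truth.loc[panel_truth.layer == "metabolite", "feature_id"])
        p1 = c.select_panel(prot, metab, tables, meta, cohort="train")
        p2 = c.select_panel(prot, metab, tables, meta, cohort="train")
        assert json.dumps(p1.to_dict(), sort_keys=True) == json.dumps(p2.to_dict(), sort_keys=True)

    def test_empty_candidate_list_rejected(self, small_cohort):
        tables, meta, _ = small_cohort
        with pytest.raises(ValueError, match="no candidates"):
            c.select_panel([], ["M001"], tables, meta)


class TestCompareClassifiers:
    def test_separable_panel_scores_perfectly(self, rng):
        n = 60
        y = np.repeat(["CON", "NS_CAP", "S_CAP"], n // 3)
        X = rng.normal(size=(n, 3)) * 0.1
        X[:, 0] += np.where(y == "S_CAP", 10.0, 0.0)
        X[:, 1] += np.where(y == "NS_CAP", 10.0, 0.0)
        cv = c.compare_classifiers(X, y, folds=5, seed=0)
        assert set(cv.classifier) == set(CLASSIFIERS)
        assert (cv.mean_accuracy == 1.0).all()

    def test_error_rate_is_one_minus_accuracy(self, rng):
        y = np.repeat(["a", "b"], 20)
        X = rng.normal(size=(40, 4)) + np.where(y == "a", 0.8, 0)[:, None]
        cv = c.compare_classifiers(X, y, folds=5, seed=1)
        np.testing.assert_allclose(cv.error_rate, 1.0 - cv.mean_accuracy, atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        y = np.repeat(["a", "b"], 15)
        X = rng.normal(size=(30, 4))
        cv1 = c.compare_classifiers(X, y, folds=5, seed=2)
        cv2 = c.compare_classifiers(X, y, folds=5, seed=2)
        pd.testing.assert_frame_equal(cv1, cv2)


class TestFeatureAucs:
    def test_aucs_and_orientations_per_contrast(self):
        vals = np.array([
            [1.0, 1.1, 2.0, 2.1, 4.0, 4.1],   # increasing marker
            [4.0, 4.1, 2.0, 2.1, 1.0, 1.1],   # decreasing marker
        ])
        table = make_table(vals, features=["UP", "DOWN"],
                           samples=[f"S{i}" for i in range(6)])
        meta = make_metadata(["CON", "CON", "NS_CAP", "NS_CAP", "S_CAP", "S_CAP"])
        out = c.feature_aucs(table, meta)
        assert out.loc["UP", "auc_S_CAP_vs_CON"] == 1.0
        assert out.loc["UP", "orient_S_CAP_vs_CON"] == "higher_is_positive"
        assert out.loc["DOWN", "auc_S_CAP_vs_CON"] == 1.0
        assert out.loc["DOWN", "orient_S_CAP_vs_CON"] == "lower_is_positive"
        assert (out["max_auc"] == 1.0).all()
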