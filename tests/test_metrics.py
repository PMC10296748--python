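"""Metric suite: worked values, brute-force oracles, identities, bins."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

from bfdna import (
    ConfusionCounts,
    accuracy,
    confusion,
    csi,
    f1,
    gmean,
    interpret_auc,
    interpret_kappa,
    kappa,
    mcc,
    metric_report,
    precision,
    recall,
    roc_auc,
    specificity,
)
from bfdna.metrics import MetricError


def tally_oracle(true, pred, pos):
    """Independent one-pass tally."""
    tp = sum(1 for t, p in zip(true, pred) if t == pos and p == pos)
    fp = sum(1 for t, p in zip(true, pred) if t != pos and p == pos)
    fn = sum(1 for t, p in zip(true, pred) if t == pos and p != pos)
    tn = sum(1 for t, p in zip(true, pred) if t != pos and p != pos)
    return tp, fp, tn, fn


def pair_count_auc(y, scores):
    """Concordant pairs + half ties over all positive x negative pairs."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion(["+", "+", "-", "-"], ["+", "+", "-", "-"], "+")
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_total_inversion(self):
        c = confusion(["+", "-"], ["-", "+"], "+")
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 1, 0, 1)

    def test_matches_tally_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        true = rng.choice(["a", "b"], size=200).tolist()
        pred = rng.choice(["a", "b"], size=200).tolist()
        c = confusion(true, pred, "a")
        assert (c.tp, c.fp, c.tn, c.fn) == tally_oracle(true, pred, "a")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ in length"):
            confusion(["a"], ["a", "b"], "a")

    def test_unknown_positive_class_rejected(self):
        with pytest.raises(ValueError, match="absent from label universe"):
            confusion(["a", "b"], ["a", "b"], "z")


class TestScalarMetrics:
    def test_hand_computed_panel(self):
        c = ConfusionCounts(tp=3, tn=4, fp=2, fn=1)
        assert accuracy(c) == pytest.approx(0.7)
        assert mcc(c) == pytest.approx(0.408248290463863)
        assert kappa(c) == pytest.approx(0.4)

    def test_precision_recall_f1_hand_case(self):
        c = ConfusionCounts(tp=3, fp=1, fn=1, tn=5)
        assert precision(c) == recall(c) == f1(c) == pytest.approx(0.75)
        assert csi(c) == pytest.approx(0.5)

    def test_perfect_classifier_all_ones(self):
        c = ConfusionCounts(tp=10, fp=0, fn=0, tn=10)
        for fn_ in (accuracy, precision, recall, specificity, f1, csi, gmean, mcc, kappa):
            assert fn_(c) == pytest.approx(1.0)

    def test_always_wrong_classifier(self):
        c = ConfusionCounts(tp=0, tn=0, fp=5, fn=5)
        assert accuracy(c) == 0.0
        assert csi(c) == pytest.approx(-1.0)
        c2 = ConfusionCounts(tp=0, tn=0, fp=50, fn=50)
        assert mcc(c2) == pytest.approx(-1.0)

    def test_chance_level_kappa(self):
        assert kappa(ConfusionCounts(tp=25, fp=25, tn=25, fn=25)) == 0.0

    def test_gmean_cases(self):
        assert gmean(ConfusionCounts(tp=5, fn=5, tn=5, fp=5)) == pytest.approx(0.5)
        assert gmean(ConfusionCounts(tp=5, fn=0, tn=0, fp=5)) == 0.0

    def test_zero_denominator_warns_and_returns_zero(self):
        c = ConfusionCounts(tp=0, fp=0, fn=2, tn=8)
        with pytest.warns(RuntimeWarning, match="precision"):
            assert precision(c) == 0.0
        with pytest.raises(MetricError):
            precision(c, strict=True)

    def test_mcc_zero_on_empty_marginal(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, fn=2, tn=8)) == 0.0

    def test_metrics_match_bruteforce_scan_on_random_problems(self):
        """Counts-based formulas vs direct label-list computation, 500 cases."""
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(4, 60))
            true = rng.choice([0, 1], size=n)
            pred = rng.choice([0, 1], size=n)
            c = confusion(true.tolist(), pred.tolist(), 1)
            tp, fp, tn, fn_ = tally_oracle(true, pred, 1)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn_)
            assert accuracy(c) == pytest.approx(np.mean(true == pred), abs=1e-10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if tp + fp and tp + fn_:
                    assert precision(c) == pytest.approx(tp / (tp + fp), abs=1e-10)
                    assert csi(c) == pytest.approx(precision(c) + recall(c) - 1, abs=1e-12)
                if len(set(true)) == 2 and len(set(pred)) >= 1:
                    assert mcc(c) == pytest.approx(matthews_corrcoef(true, pred), abs=1e-10)
                    assert kappa(c) == pytest.approx(cohen_kappa_score(true, pred), abs=1e-10)

    def test_mcc_and_kappa_symmetric_under_class_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tp, fp, tn, fn_ = rng.integers(1, 30, size=4)
            c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn_)
            swapped = ConfusionCounts(tp=tn, fp=fn_, tn=tp, fn=fp)
            assert mcc(c) == pytest.approx(mcc(swapped), abs=1e-12)
            assert kappa(c) == pytest.approx(kappa(swapped), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        _, a = roc_auc([1, 1, 0, 0], np.array([0.9, 0.8, 0.2, 0.1]), positive_class=1)
        assert a == 1.0

    def test_uninformative_scores(self):
        _, a = roc_auc([1, 0, 1, 0], np.array([0.5, 0.5, 0.5, 0.5]), positive_class=1)
        assert a == 0.5

    def test_six_sample_hand_case(self):
        _, a = roc_auc(["+"] * 3 + ["-"] * 3, np.array([0.9, 0.8, 0.4, 0.6, 0.3, 0.2]),
                       positive_class="+")
        assert a == pytest.approx(8 / 9)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            n = int(rng.integers(10, 201))
            y = rng.choice([0, 1], size=n)
            if len(set(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            _, a = roc_auc(y.tolist(), scores, positive_class=1)
            assert a == pytest.approx(pair_count_auc(y, scores), abs=1e-10)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        curve, _ = roc_auc(rng.choice([0, 1], 50).tolist(), rng.random(50), positive_class=1)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_micro_pools_and_macro_averages(self):
        rng = np.random.default_rng(2)
        true = rng.choice(list("abc"), 90).tolist()
        scores = rng.random((90, 3))
        scores = scores / scores.sum(axis=1, keepdims=True)
        _, micro = roc_auc(true, scores, mode="micro")
        _, macro = roc_auc(true, scores, mode="macro")
        assert 0 <= micro <= 1 and 0 <= macro <= 1
        # macro equals the mean of per-class one-vs-rest AUCs
        per_class = [roc_auc(true, scores, mode="per-class", positive_class=c)[1]
                     for c in "abc"]
        assert macro == pytest.approx(np.mean(per_class))

    def test_macro_skips_absent_class_with_warning(self):
        true = ["a", "b", "a", "b"]
        scores = np.random.default_rng(0).random((4, 3))
        with pytest.warns(RuntimeWarning, match="absent"):
            _, a = roc_auc(true, scores, mode="macro", classes=["a", "b", "c"])
        assert 0 <= a <= 1


class TestInterpretation:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "No distinction"), (0.49, "No distinction"),
            (0.50, "Poor classification"), (0.69, "Poor classification"),
            (0.70, "Acceptable classification"), (0.79, "Acceptable classification"),
            (0.80, "Great classification"), (0.85, "Great classification"),
            (0.89, "Great classification"),
            (0.90, "Outstanding classification"), (0.92, "Outstanding classification"),
            (1.00, "Outstanding classification"),
        ],
    )
    def test_auc_bins(self, value, label):
        assert interpret_auc(value) == label

    def test_auc_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_auc(1.2)

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.00, "No agreement"), (-0.2, "No agreement"),
            (0.10, "Slight agreement"), (0.20, "Slight agreement"),
            (0.21, "Fair agreement"), (0.40, "Fair agreement"),
            (0.41, "Moderate agreement"), (0.5393, "Moderate agreement"),
            (0.60, "Moderate agreement"),
            (0.61, "Substantial agreement"), (0.80, "Substantial agreement"),
            (0.81, "Almost perfect agreement"), (0.8431, "Almost perfect agreement"),
            (0.99, "Almost perfect agreement"),
            (1.00, "Perfect agreement"),
        ],
    )
    def test_kappa_bins(self, value, label):
        assert interpret_kappa(value) == label


class TestMetricReport:
    def test_perfect_three_class_prediction(self):
        true = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        report = metric_report(true, list(true))
        for name in ("accuracy", "precision", "recall", "specificity", "f1",
                     "csi", "gmean", "mcc", "kappa"):
            assert getattr(report, name) == pytest.approx(1.0)

    def test_binary_report_equals_single_metric_operations(self):
        rng = np.random.default_rng(21)
        true = rng.choice(["n", "p"], 100).tolist()
        pred = rng.choice(["n", "p"], 100).tolist()
        report = metric_report(true, pred, positive_class="p")
        c = confusion(true, pred, "p")
        assert report.accuracy == pytest.approx(accuracy(c))
        assert report.precision == pytest.approx(precision(c))
        assert report.recall == pytest.approx(recall(c))
        assert report.specificity == pytest.approx(specificity(c))
        assert report.f1 == pytest.approx(f1(c))
        assert report.csi == pytest.approx(csi(c))
        assert report.gmean == pytest.approx(gmean(c))
        assert report.mcc == pytest.approx(mcc(c))
        assert report.kappa == pytest.approx(kappa(c))

    def test_shuffled_label_null(self):
        """Labels shuffled against themselves: accuracy near the prior's
        self-match rate upper bound, kappa near 0."""
        rng = np.random.default_rng(8)
        n = 10000
        true = rng.choice(["a", "b"], size=n, p=[0.6, 0.4])
        pred = rng.permutation(true)
        report = metric_report(true.tolist(), pred.tolist())
        assert report.kappa == pytest.approx(0.0, abs=0.05)
        assert report.accuracy == pytest.approx(0.6**2 + 0.4**2, abs=0.05)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            metric_report(["a", "a"], ["a", "b"])

    def test_auc_fields_filled_with_scores(self):
        rng = np.random.default_rng(4)
        true = rng.choice(["n", "p"], 60).tolist()
        scores = rng.random(60)
        report = metric_report(true, true, scores=scores, positive_class="p")
        assert report.auc_micro is not None and report.auc_macro is not None
        assert report.interpretations()["kappa"] == "Perfect agreement"
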