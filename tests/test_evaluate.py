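"""Confusion metrics, cross-validated evaluation and the gated comparison."""

import math
from fractions import Fraction

import numpy as np
import pytest

from eegauth import compare_protocols, confusion, kfold_evaluate, metrics
from eegauth.evaluate import ConfusionCounts, make_folds
from eegauth.exceptions import InsufficientDataError


class TestConfusion:
    def test_perfect_three_class_prediction(self):
        y = np.repeat(["A", "B", "C"], 3)
        c = confusion(y, y, "A")
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 0, 0, 6)
        assert c.total == 9

    def test_everything_predicted_positive(self):
        y = np.repeat(["A", "B", "C"], 3)
        c = confusion(y, np.repeat("A", 9), "A")
        assert c.tp == 3 and c.fp == 6 and c.tn == 0 and c.fn == 0

    def test_random_labels_match_tally_loop(self, rng):
        y_true = rng.choice(["A", "B", "C"], size=50)
        y_pred = rng.choice(["A", "B", "C"], size=50)
        c = confusion(y_true, y_pred, "B")
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == "B" and p == "B":
                tp += 1
            elif t != "B" and p == "B":
                fp += 1
            elif t == "B" and p != "B":
                fn += 1
            else:
                tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_row_order_invariance(self, rng):
        y_true = rng.choice(["A", "B"], size=30)
        y_pred = rng.choice(["A", "B"], size=30)
        perm = rng.permutation(30)
        assert confusion(y_true, y_pred, "A") == confusion(
            y_true[perm], y_pred[perm], "A"
        )

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            confusion(["A", "B"], ["A", "B"], "Z")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


def exact_metrics(tp, fp, tn, fn, f1_factor):
    """Independent oracle: exact rational arithmetic, 0/0 -> 0."""

    def ratio(a, b):
        return Fraction(a, b) if b else Fraction(0)

    p = ratio(tp, tp + fp)
    s = ratio(tp, tp + fn)
    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": p,
        "sensitivity": s,
        "specificity": ratio(tn, tn + fp),
        "f1": f1_factor * (p * s / (p + s) if p + s else Fraction(0)),
    }


class TestMetrics:
    def test_perfect_classifier_under_both_f1_modes(self):
        c = ConfusionCounts(tp=5, fp=0, tn=5, fn=0)
        standard = metrics(c, "standard")
        assert all(standard[m] == 1.0 for m in standard)
        literal = metrics(c, "paper_literal")
        assert literal["f1"] == 0.5  # the factor-2-free variant halves F1
        assert literal["accuracy"] == 1.0

    def test_degenerate_zero_division_convention(self):
        c = ConfusionCounts(tp=0, fp=0, tn=0, fn=5)
        m = metrics(c)
        assert m["precision"] == 0.0 and m["sensitivity"] == 0.0 and m["f1"] == 0.0

    def test_hand_computed_case(self):
        m = metrics(ConfusionCounts(tp=8, fp=2, tn=85, fn=5))
        assert m["accuracy"] == pytest.approx(93 / 100)
        assert m["precision"] == pytest.approx(8 / 10)
        assert m["sensitivity"] == pytest.approx(8 / 13)
        assert m["specificity"] == pytest.approx(85 / 87)
        assert m["f1"] == pytest.approx(2 * 0.8 * (8 / 13) / (0.8 + 8 / 13))

    @pytest.mark.parametrize("f1_mode, factor", [("standard", 2), ("paper_literal", 1)])
    def test_random_tuples_match_rational_oracle(self, rng, f1_mode, factor):
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 40, size=4))
            ours = metrics(ConfusionCounts(tp, fp, tn, fn), f1_mode)
            oracle = exact_metrics(tp, fp, tn, fn, factor)
            for name, value in oracle.items():
                assert ours[name] == pytest.approx(float(value), abs=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(1, 1, 1, 1), "f2")


class TestKfold:
    @staticmethod
    def _data(rng, per_class=10, n_classes=4):
        centers = rng.normal(size=(n_classes, 5)) * 5
        X = np.vstack([
            centers[c] + rng.normal(size=(per_class, 5)) for c in range(n_classes)
        ])
        y = np.repeat([f"S{c}" for c in range(n_classes)], per_class)
        return X, y

    @pytest.mark.parametrize("stratify", [False, True])
    def test_folds_partition_all_rows(self, rng, stratify):
        labels = np.repeat(list("abcd"), 10)
        folds = make_folds(40, 5, rng, labels=labels, stratify=stratify)
        combined = np.sort(np.concatenate(folds))
        assert np.array_equal(combined, np.arange(40))

    def test_fixed_seed_reproduces_report(self, rng):
        X, y = self._data(rng)
        a = kfold_evaluate(X, y, "OVO", k=5, seed=42)
        b = kfold_evaluate(X, y, "OVO", k=5, seed=42)
        assert a.per_fold == b.per_fold
        assert a.top1_accuracy_mean == b.top1_accuracy_mean

    def test_separable_data_score_highly(self, rng):
        X, y = self._data(rng)
        report = kfold_evaluate(X, y, "OVA", k=5, seed=0)
        assert report.mean["accuracy"] >= 95.0
        assert all(0.0 <= v <= 100.0 for f in report.per_fold for v in f.values())

    def test_k_default_is_five(self, rng):
        X, y = self._data(rng)
        report = kfold_evaluate(X, y, "OVO", seed=0)
        assert report.k == 5 and len(report.per_fold) == 5

    def test_class_smaller_than_k_rejected(self, rng):
        X, y = self._data(rng, per_class=4)
        with pytest.raises(InsufficientDataError):
            kfold_evaluate(X, y, "OVO", k=5, seed=0)

    def test_per_class_tp_sums_to_correct_predictions(self, rng):
        y_true = rng.choice(["A", "B", "C"], size=60)
        y_pred = rng.choice(["A", "B", "C"], size=60)
        total_tp = sum(
            confusion(y_true, y_pred, c).tp for c in ("A", "B", "C")
        )
        assert total_tp == int(np.sum(y_true == y_pred))

    def test_micro_averaging_available(self, rng):
        X, y = self._data(rng)
        report = kfold_evaluate(X, y, "OVO", k=5, seed=0, averaging="micro")
        assert set(report.mean) == {
            "accuracy", "precision", "sensitivity", "specificity", "f1"
        }


class TestCompareProtocols:
    def test_identical_samples_not_significant(self):
        a = np.array([90.0, 91.0, 92.0, 93.0, 94.0])
        with pytest.warns(UserWarning, match="identical"):
            report = compare_protocols(a, a.copy())
        assert report.comparison_p["value"] == 1.0
        assert not report.significant["value"]

    def test_large_shift_detected(self, rng):
        a = 90.0 + rng.normal(size=8)
        b = a + 50.0
        report = compare_protocols(a, b)
        assert report.comparison_p["value"] < 0.05
        assert report.significant["value"]

    def test_normal_samples_route_to_paired_t(self, rng):
        a = 90.0 + rng.normal(size=10)
        b = 85.0 + rng.normal(size=10)
        report = compare_protocols(a, b)
        assert report.chosen_test["value"] == "paired_t"
        from scipy import stats

        assert report.comparison_p["value"] == pytest.approx(
            stats.ttest_rel(a, b).pvalue
        )

    def test_non_normal_samples_route_to_rank_sum(self, rng):
        a = np.array([1.0, 1.1, 0.9, 1.0, 1.05, 200.0, 1.02, 0.98])
        b = 3.0 + rng.normal(size=8) * 0.1
        report = compare_protocols(a, b)
        assert report.chosen_test["value"] == "ranksum"
        assert report.shapiro_p_a["value"] <= 0.05

    def test_rank_sum_matches_independent_rank_computation(self, rng):
        """The rank-sum p-value equals the hand-computed normal approximation
        of the Wilcoxon rank-sum statistic (tie-free samples)."""
        a = np.array([1.0, 1.1, 0.9, 1.0, 1.05, 200.0, 1.02, 0.98])
        b = 3.0 + rng.normal(size=8) * 0.1
        report = compare_protocols(a, b)

        pooled = np.concatenate([a, b])
        order = np.argsort(pooled)
        ranks = np.empty_like(order, dtype=float)
        ranks[order] = np.arange(1, pooled.size + 1)
        r1 = ranks[: a.size].sum()
        n1, n2 = a.size, b.size
        z = (r1 - n1 * (n1 + n2 + 1) / 2) / math.sqrt(
            n1 * n2 * (n1 + n2 + 1) / 12
        )
        p_manual = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(abs(z) / math.sqrt(2))))
        assert report.comparison_p["value"] == pytest.approx(p_manual, abs=1e-10)

    def test_signed_rank_variant_selectable(self, rng):
        a = np.array([1.0, 1.1, 0.9, 1.0, 1.05, 200.0, 1.02, 0.98])
        b = a + rng.normal(size=8)
        report = compare_protocols(a, b, nonparametric="signed_rank")
        assert report.chosen_test["value"] == "signed_rank"

    def test_metric_dictionaries_compared_per_metric(self, rng):
        a = {"accuracy": 90 + rng.normal(size=5), "f1": 88 + rng.normal(size=5)}
        b = {"accuracy": 95 + rng.normal(size=5), "f1": 93 + rng.normal(size=5)}
        report = compare_protocols(a, b)
        assert set(report.comparison_p) == {"accuracy", "f1"}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_protocols(np.ones(4), np.ones(5))
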