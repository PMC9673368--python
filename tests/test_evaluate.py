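import math

import numpy as np
import pytest
from scipy import stats

from ovus import augment, backbone, evaluate
from ovus.evaluate import (ConfusionCounts, accuracy, confusion_counts,
                           paired_t_test, repeated_holdout, sensitivity,
                           specificity, std_dev, tradeoff_curve)
from ovus.synthgen import BENIGN, MALIGNANT


class TestConfusionCounts:
    def test_small_examples(self):
        c = confusion_counts([MALIGNANT, BENIGN], [MALIGNANT, BENIGN])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)
        c = confusion_counts([MALIGNANT] * 5, [BENIGN] * 5)
        assert c.FN == 5 and c.TP == 0

    def test_matches_independent_tally_on_random_vectors(self):
        rng = np.random.default_rng(0)
        truth = rng.choice([BENIGN, MALIGNANT], size=200)
        pred = rng.choice([BENIGN, MALIGNANT], size=200)
        c = confusion_counts(truth, pred)
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for t, p in zip(truth, pred):
            key = (("TP" if p == MALIGNANT else "FN") if t == MALIGNANT
                   else ("TN" if p == BENIGN else "FP"))
            tally[key] += 1
        assert (c.TP, c.TN, c.FP, c.FN) == (tally["TP"], tally["TN"],
                                            tally["FP"], tally["FN"])
        assert c.total == 200

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            confusion_counts([BENIGN], [BENIGN, MALIGNANT])


class TestMetrics:
    def test_accuracy_from_error_counts(self):
        # 446 correct / 10 wrong and 523 correct of 568
        c = ConfusionCounts(TP=223, TN=223, FP=5, FN=5)
        assert accuracy(c) == pytest.approx(100 * 446 / 456)
        assert accuracy(c) == pytest.approx(97.78, abs=0.05)
        c = ConfusionCounts(TP=262, TN=261, FP=23, FN=22)
        assert round(accuracy(c), 1) == 92.1

    def test_perfect_counts(self):
        assert accuracy(ConfusionCounts(TP=7, TN=3, FP=0, FN=0)) == 100.0

    def test_se_sp_modes(self):
        assert sensitivity(ConfusionCounts(9, 0, 1, 0), "as_printed") == 90.0
        assert sensitivity(ConfusionCounts(9, 0, 0, 1), "conventional") == 90.0
        c = ConfusionCounts(TP=8, TN=6, FP=2, FN=4)
        assert sensitivity(c, "as_printed") == pytest.approx(100 * 8 / 10)
        assert sensitivity(c, "conventional") == pytest.approx(100 * 8 / 12)
        assert specificity(c, "as_printed") == pytest.approx(100 * 6 / 10)
        assert specificity(c, "conventional") == pytest.approx(100 * 6 / 8)

    def test_zero_denominator_flagged_not_silent(self):
        with pytest.raises(ZeroDivisionError):
            sensitivity(ConfusionCounts(0, 5, 0, 5), "as_printed")
        report = evaluate.metrics_report(ConfusionCounts(0, 5, 0, 5))
        assert report.se is None and report.acc == 50.0

    def test_accuracy_plus_error_rate_is_100(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            err = 100.0 * (c.FP + c.FN) / c.total
            assert accuracy(c) + err == pytest.approx(100.0)


class TestStdDev:
    def test_hand_arithmetic(self):
        assert std_dev([2, 4]) == 1.0           # divisor N = 2
        assert std_dev([5, 5, 5]) == 0.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random(100) * 10
        mu = sum(x) / len(x)
        oracle = math.sqrt(sum((v - mu) ** 2 for v in x) / len(x))
        assert std_dev(x) == pytest.approx(oracle, abs=1e-12)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            std_dev([])


class TestPairedT:
    def test_identical_samples_degenerate(self):
        t, p = paired_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        t, p = paired_t_test([1, 2, 3], [2, 3, 5])
        assert t == pytest.approx(-4.0)
        assert p == pytest.approx(0.0572, abs=5e-4)

    def test_matches_scipy_on_random_input(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(10), rng.random(10)
        t, p = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2], [1, 2, 3])


class TestTradeoffCurve:
    def test_two_models_hit_the_endpoints(self):
        curve = tradeoff_curve({"a": (85.0, 0.2), "b": (90.0, 0.5)})
        assert curve.accuracy_ratio == (0.0, 1.0)
        assert curve.time_ratio == (0.0, 1.0)

    def test_flat_accuracy_is_flagged(self):
        curve = tradeoff_curve({"a": (90.0, 0.2), "b": (90.0, 0.5)})
        assert "accuracy" in curve.degenerate_axes
        assert curve.accuracy_ratio == (0.0, 0.0)

    def test_four_model_hand_scaled_values(self):
        singles = {"m1": (80.0, 1.0), "m2": (84.0, 2.0),
                   "m3": (86.0, 3.0), "m4": (82.0, 4.0)}
        accs = {1: 88.0, 2: 90.0, 3: 94.0, 4: 92.0}
        curve = tradeoff_curve(singles,
                               subset_accuracy=lambda ids: accs[len(ids)])
        # times: 1, 3, 6, 10 -> scaled (0, 2/9, 5/9, 1)
        assert curve.time_ratio == pytest.approx((0, 2 / 9, 5 / 9, 1))
        # accuracies: 88, 90, 94, 92 -> scaled (0, 1/3, 1, 2/3)
        assert curve.accuracy_ratio == pytest.approx((0, 1 / 3, 1, 2 / 3))
        assert all(0 <= r <= 1 for r in curve.accuracy_ratio)

    def test_rejects_fewer_than_two_models(self):
        with pytest.raises(ValueError):
            tradeoff_curve({"a": (90.0, 0.5)})


class TestRepeatedHoldout:
    SPECS = [backbone.PRESETS["tiny-residual-18-like"]]
    TRAIN = backbone.TrainingConfig(epochs=1, learning_rate=1e-3)
    AUG = augment.AugmentationConfig()

    def test_single_repetition_has_zero_sd(self, small_dataset):
        summary = repeated_holdout(small_dataset, self.SPECS, self.TRAIN,
                                   self.AUG, repetitions=1, base_seed=3)
        for name in summary.per_rep:
            mean, sd = summary.mean_sd(name)
            assert sd == 0.0
            assert len(summary.per_rep[name]) == 1

    def test_deterministic_given_base_seed(self, small_dataset):
        a = repeated_holdout(small_dataset, self.SPECS, self.TRAIN, self.AUG,
                             repetitions=2, base_seed=7)
        b = repeated_holdout(small_dataset, self.SPECS, self.TRAIN, self.AUG,
                             repetitions=2, base_seed=7)
        assert a.to_frame().equals(b.to_frame())
        assert a.records.equals(b.records)

    def test_mean_within_min_max(self, small_dataset):
        summary = repeated_holdout(small_dataset, self.SPECS, self.TRAIN,
                                   self.AUG, repetitions=3, base_seed=11)
        for name in summary.per_rep:
            vals = summary.metric_values(name, "acc")
            mean, _ = summary.mean_sd(name)
            assert min(vals) <= mean <= max(vals)

    def test_rejects_zero_repetitions(self, small_dataset):
        with pytest.raises(ValueError):
            repeated_holdout(small_dataset, self.SPECS, repetitions=0)
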