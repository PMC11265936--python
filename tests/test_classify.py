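"""Metric formulas, oversampling baseline, classifier protocol, three-condition report."""

import numpy as np
import pandas as pd
import pytest

from ergsynth import (ClassificationMetrics, ConfusionCounts, CvSpec,
                      compute_metrics, confusion_counts, f1_score,
                      fit_and_evaluate, random_oversample)
from ergsynth.classify import UndefinedMetricError
from ergsynth.simulate import LA3


def brute_counts(y_true, y_pred, positive):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t == positive:
            fn += 1
        elif p == positive:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestConfusionCounts:
    def test_perfect_agreement(self):
        c = confusion_counts(["+", "+", "-", "-"], ["+", "+", "-", "-"], "+")
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        c = confusion_counts(["+", "-"], ["+", "+"], "+")
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 0, 0)

    def test_against_elementwise_tally(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(["m", "f"], 500)
        y_pred = rng.choice(["m", "f"], 500)
        c = confusion_counts(y_true, y_pred, "m")
        assert (c.tp, c.tn, c.fp, c.fn) == brute_counts(y_true, y_pred, "m")
        assert c.total == 500

    def test_unseen_positive_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(["a", "b"], ["a", "b"], "c")


class TestComputeMetrics:
    def test_published_worked_example(self):
        """precision 0.809 and recall 0.850 combine to F1 = 0.829 (3 d.p.)."""
        assert f1_score(0.809, 0.850) == pytest.approx(0.829, abs=5e-4)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=7, fp=0, fn=0))
        assert m == ClassificationMetrics(1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_arithmetic(self):
        m = compute_metrics(ConfusionCounts(tp=3, fn=1, tn=2, fp=2))
        assert m.recall == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.5)
        assert m.balanced_accuracy == pytest.approx(0.625)
        assert m.precision == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=0))  # no positives
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(tp=3, tn=0, fp=0, fn=0))  # no negatives
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=2))  # no predicted pos

    def test_oracle_equivalence_random_vectors(self):
        """Metrics from confusion counts equal hand formulas from brute-force
        tallies on 1000 random prediction vectors."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            y_true = rng.choice([0, 1], n)
            y_pred = rng.choice([0, 1], n)
            tp, tn, fp, fn = brute_counts(y_true, y_pred, 1)
            if tp + fn == 0 or tn + fp == 0 or tp + fp == 0 or tp == 0:
                continue
            m = compute_metrics(confusion_counts(y_true, y_pred, 1))
            assert m.precision == tp / (tp + fp)
            assert m.recall == tp / (tp + fn)
            assert m.specificity == tn / (tn + fp)
            assert m.balanced_accuracy == (m.recall + m.specificity) / 2
            assert m.f1 == 2 * m.precision * m.recall / (m.precision + m.recall)

    def test_label_swap_symmetry(self):
        """Swapping the positive class swaps sensitivity/specificity; BA invariant."""
        rng = np.random.default_rng(3)
        y_true = rng.choice(["m", "f"], 200)
        y_pred = rng.choice(["m", "f"], 200)
        m1 = compute_metrics(confusion_counts(y_true, y_pred, "m"))
        m2 = compute_metrics(confusion_counts(y_true, y_pred, "f"))
        assert m1.recall == pytest.approx(m2.specificity)
        assert m1.specificity == pytest.approx(m2.recall)
        assert m1.balanced_accuracy == pytest.approx(m2.balanced_accuracy)


def _rows(n_f, n_m, rng=None, sep=0.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    for sex, n, shift in (("female", n_f, 0.0), ("male", n_m, sep)):
        for _ in range(n):
            rows.append({
                "sex": sex, "stimulus": LA3, "provenance": "real",
                "ta_s": rng.normal(0.015 + shift * 0.001, 0.001),
                "la_uv": rng.normal(10 + shift, 1),
                "tb_s": rng.normal(0.032 + shift * 0.001, 0.001),
                "lb_uv": rng.normal(30 + shift, 1),
            })
    return pd.DataFrame(rows)


class TestRandomOversample:
    def test_parity_and_retention(self):
        rows = _rows(10, 4)
        out = random_oversample(rows, "male", seed=0)
        counts = out.sex.value_counts()
        assert counts["male"] == counts["female"] == 10
        originals = rows[rows.sex == "male"].drop_duplicates()
        merged = out.merge(originals, how="inner")
        assert len(merged) >= len(originals)

    def test_balanced_input_unchanged(self):
        rows = _rows(6, 6)
        out = random_oversample(rows, "male", seed=0)
        pd.testing.assert_frame_equal(out, rows)

    def test_determinism(self):
        rows = _rows(12, 5)
        a = random_oversample(rows, "male", seed=4)
        b = random_oversample(rows, "male", seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        rows = _rows(8, 0)
        with pytest.raises(ValueError):
            random_oversample(rows, "male", seed=0)

    def test_minority_sub_multiset_of_output(self):
        rows = _rows(15, 6)
        out = random_oversample(rows, "male", seed=2)
        # every original minority row (by value) appears at least as often
        key = ["ta_s", "la_uv", "tb_s", "lb_uv"]
        orig = rows[rows.sex == "male"].groupby(key).size()
        new = out[out.sex == "male"].groupby(key).size()
        assert all(new.get(k, 0) >= v for k, v in orig.items())


class TestFitAndEvaluate:
    def test_separable_blobs_high_ba(self):
        rng = np.random.default_rng(1)
        train = _rows(60, 60, rng, sep=8.0)
        test = _rows(15, 15, rng, sep=8.0)
        _, m = fit_and_evaluate(train, test, CvSpec(seed=0))
        assert m.balanced_accuracy >= 0.95

    def test_permuted_labels_near_chance(self):
        bas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            train = _rows(100, 100, rng, sep=0.0)
            test = _rows(30, 30, rng, sep=0.0)
            _, m = fit_and_evaluate(train, test, CvSpec(seed=seed))
            bas.append(m.balanced_accuracy)
        assert abs(np.mean(bas) - 0.5) <= 0.1

    def test_determinism(self):
        rng = np.random.default_rng(5)
        train = _rows(40, 20, rng, sep=2.0)
        test = _rows(10, 10, rng, sep=2.0)
        _, m1 = fit_and_evaluate(train, test, CvSpec(seed=3))
        _, m2 = fit_and_evaluate(train, test, CvSpec(seed=3))
        assert m1 == m2

    def test_single_class_test_rejected(self):
        rng = np.random.default_rng(5)
        train = _rows(20, 20, rng)
        test = _rows(10, 0, rng)
        with pytest.raises(UndefinedMetricError):
            fit_and_evaluate(train, test, CvSpec(seed=0))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            CvSpec(n_estimators=())
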