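"""Metric tests: the Sen/Spc/Acc/MCC equations on published-style confusion
counts, the rank-statistic AUROC against a brute-force pair-counting oracle
and sklearn, and the algebraic identities of MCC and accuracy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from neuropep import (
    ConfusionCounts,
    accuracy,
    auroc,
    confusion_at_threshold,
    evaluate_at_threshold,
    mcc,
    sensitivity,
    specificity,
    threshold_sweep,
)


def auroc_pair_oracle(scores, labels):
    """Probability a random positive outscores a random negative, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


counts_strategy = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 200),
    tn=st.integers(0, 200),
    fp=st.integers(0, 200),
    fn=st.integers(0, 200),
)


class TestThresholdMetrics:
    def test_benchmark_comparison_counts(self):
        # the balanced classifier's validation confusion table
        c = ConfusionCounts(tp=144, tn=149, fp=26, fn=31)
        assert sensitivity(c) == pytest.approx(82.29, abs=0.005)
        assert specificity(c) == pytest.approx(85.14, abs=0.005)
        assert accuracy(c) == pytest.approx(83.71, abs=0.005)
        assert mcc(c) == pytest.approx(0.6746, abs=5e-4)

    def test_high_sensitivity_low_specificity_counts(self):
        # an all-but-trivially-positive predictor: Sen 100, Spc collapses
        c = ConfusionCounts(tp=175, tn=9, fp=166, fn=0)
        assert sensitivity(c) == 100.0
        assert specificity(c) == pytest.approx(5.14, abs=0.005)
        assert accuracy(c) == pytest.approx(52.57, abs=0.005)
        assert mcc(c) == pytest.approx(0.16, abs=0.005)

    def test_degenerate_cases(self):
        assert sensitivity(ConfusionCounts(tp=5, tn=0, fp=0, fn=0)) == 100.0
        assert specificity(ConfusionCounts(tp=0, tn=7, fp=0, fn=0)) == 100.0
        with pytest.raises(ZeroDivisionError):
            sensitivity(ConfusionCounts(tp=0, tn=3, fp=1, fn=0))
        assert accuracy(ConfusionCounts(tp=3, tn=3, fp=0, fn=0)) == 100.0

    def test_mcc_zero_denominator_convention(self):
        # never-positive predictor: the (TP+FP) factor vanishes
        assert mcc(ConfusionCounts(tp=0, tn=5, fp=0, fn=5)) == 0.0

    def test_mcc_extremes(self):
        assert mcc(ConfusionCounts(tp=10, tn=10, fp=0, fn=0)) == 1.0
        assert mcc(ConfusionCounts(tp=0, tn=0, fp=10, fn=10)) == -1.0

    @given(c=counts_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_mcc_identities(self, c):
        # class swap leaves MCC unchanged; prediction swap negates it
        swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
        inverted = ConfusionCounts(tp=c.fp, tn=c.fn, fp=c.tp, fn=c.tn)
        assert mcc(swapped) == pytest.approx(mcc(c), abs=1e-12)
        assert mcc(inverted) == pytest.approx(-mcc(c), abs=1e-12)
        assert -1.0 - 1e-12 <= mcc(c) <= 1.0 + 1e-12

    @given(c=counts_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_accuracy_is_prevalence_weighted_sen_spc(self, c):
        P, N = c.n_positives, c.n_negatives
        if P == 0 or N == 0:
            return
        expected = (sensitivity(c) * P + specificity(c) * N) / (P + N)
        assert accuracy(c) == pytest.approx(expected, abs=1e-9)

    def test_mcc_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        c = ConfusionCounts(
            tp=int(np.sum((y == 1) & (pred == 1))),
            tn=int(np.sum((y == 0) & (pred == 0))),
            fp=int(np.sum((y == 0) & (pred == 1))),
            fn=int(np.sum((y == 1) & (pred == 0))),
        )
        assert mcc(c) == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)


class TestConfusionAtThreshold:
    def test_all_above_threshold_all_positive_labels(self):
        c = confusion_at_threshold([1.0, 2.0], [1, 1], 0.5)
        assert (c.fp, c.fn) == (0, 0)

    def test_infinite_threshold(self):
        c = confusion_at_threshold([1.0, -1.0], [1, 0], np.inf)
        assert (c.tp, c.fp) == (0, 0)

    def test_two_point_enumeration(self):
        c = confusion_at_threshold([0.6, 0.4], [1, 0], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([1.0], [1, 0], 0.0)


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])

    def test_single_swapped_pair(self):
        # 3 pos x 3 neg = 9 pairs; one discordant pair -> 8/9
        scores = [6, 5, 3, 4, 2, 1]
        labels = [1, 1, 1, 0, 0, 0]
        assert auroc(scores, labels) == pytest.approx(8 / 9)
        assert auroc(scores, labels) == pytest.approx(
            auroc_pair_oracle(scores, labels)
        )

    def test_matches_pair_oracle_on_all_small_toys(self):
        rng = np.random.default_rng(11)
        for trial in range(200):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, n).astype(float)  # many ties
            assert auroc(scores, labels) == pytest.approx(
                auroc_pair_oracle(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_trapezoid(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 300)
        labels[0], labels[1] = 0, 1
        scores = rng.normal(size=300) + labels
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_permutation_null_near_half(self):
        rng = np.random.default_rng(17)
        labels = np.array([1] * 500 + [0] * 500)
        scores = rng.normal(size=1000)
        assert auroc(scores, labels) == pytest.approx(0.5, abs=0.05)


class TestThresholdSweep:
    def test_best_threshold_maximizes_accuracy(self):
        scores = [0.9, 0.8, 0.3, 0.2]
        labels = [1, 1, 0, 0]
        table, best = threshold_sweep(scores, labels)
        rep = evaluate_at_threshold(scores, labels, best)
        assert rep.acc == 100.0
        assert table["acc"].max() == 100.0

    def test_monotone_predicted_positive_count(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        counts = [
            np.sum(scores >= t) for t in np.sort(np.unique(scores))
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_tie_break_prefers_balanced_operating_point(self):
        # two thresholds reach the same accuracy; the |Sen-Spc|-minimizing wins
        scores = [0.9, 0.7, 0.6, 0.1]
        labels = [1, 0, 1, 0]
        _, best = threshold_sweep(scores, labels)
        rep = evaluate_at_threshold(scores, labels, best)
        assert rep.acc == 75.0
        assert abs(rep.sen - rep.spc) == min(
            abs(evaluate_at_threshold(scores, labels, t).sen
                - evaluate_at_threshold(scores, labels, t).spc)
            for t in set(scores)
            if evaluate_at_threshold(scores, labels, t).acc == 75.0
        )
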