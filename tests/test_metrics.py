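"""Multi-label metrics against from-definition enumeration, an independent
reference implementation (scikit-learn), and the reporting arithmetic."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, f1_score, hamming_loss as sk_hamming,
                             jaccard_score, roc_auc_score)

from modalcoder import (MetricsReport, absolute_drop, evaluate_all,
                        hamming_loss, macro_auc, macro_f1, macro_jaccard,
                        relative_change, subset_accuracy)
from modalcoder.metrics import UndefinedAUCError, labelwise_jaccard


# -- independent from-definition oracles (scalar loops, no vectorization) -----

def oracle_subset_accuracy(Y, Yhat):
    return sum(1 for yi, pi in zip(Y, Yhat) if list(yi) == list(pi)) / len(Y)


def oracle_hamming(Y, Yhat):
    N, L = np.asarray(Y).shape
    return sum(1 for i in range(N) for j in range(L)
               if Y[i][j] != Yhat[i][j]) / (N * L)


def oracle_macro_f1(Y, Yhat):
    Y, Yhat = np.asarray(Y), np.asarray(Yhat)
    f1s = []
    for j in range(Y.shape[1]):
        tp = sum(int(y == 1 and p == 1) for y, p in zip(Y[:, j], Yhat[:, j]))
        fp = sum(int(y == 0 and p == 1) for y, p in zip(Y[:, j], Yhat[:, j]))
        fn = sum(int(y == 1 and p == 0) for y, p in zip(Y[:, j], Yhat[:, j]))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(f1s) / len(f1s)


def oracle_jaccard(Y, Yhat):
    Y, Yhat = np.asarray(Y), np.asarray(Yhat)
    vals = []
    for i in range(Y.shape[0]):
        tp = int(((Y[i] == 1) & (Yhat[i] == 1)).sum())
        union = int(((Y[i] == 1) | (Yhat[i] == 1)).sum())
        vals.append(tp / union if union else 1.0)
    return sum(vals) / len(vals)


def oracle_auc_column(y, s):
    """Probability a random positive outscores a random negative (ties 1/2)."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def all_binary_matrices(n, l):
    for bits in itertools.product((0, 1), repeat=n * l):
        yield np.asarray(bits).reshape(n, l)


def enumerate_pairs(n, l, limit=4096, seed=0):
    """All (Y, Yhat) pairs when feasible, otherwise a seeded subsample."""
    mats = list(all_binary_matrices(n, l))
    total = len(mats) ** 2
    if total <= limit:
        yield from itertools.product(mats, mats)
        return
    rng = np.random.default_rng(seed)
    for _ in range(limit):
        yield (mats[rng.integers(len(mats))], mats[rng.integers(len(mats))])


class TestAgainstEnumeration:
    @pytest.mark.parametrize("n,l", [(1, 1), (2, 1), (1, 3), (2, 2),
                                     (3, 2), (2, 3), (3, 3)])
    def test_all_four_set_metrics_match_definition(self, n, l):
        for Y, Yhat in enumerate_pairs(n, l):
            assert subset_accuracy(Y, Yhat) == pytest.approx(
                oracle_subset_accuracy(Y, Yhat), abs=1e-12)
            assert hamming_loss(Y, Yhat) == pytest.approx(
                oracle_hamming(Y, Yhat), abs=1e-12)
            assert macro_f1(Y, Yhat) == pytest.approx(
                oracle_macro_f1(Y, Yhat), abs=1e-12)
            assert macro_jaccard(Y, Yhat) == pytest.approx(
                oracle_jaccard(Y, Yhat), abs=1e-12)

    def test_auc_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(3, 10))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = rng.choice([-1.0, 0.0, 0.5, 1.0, 2.0], size=n)  # force ties
            got = macro_auc(y[:, None], s[:, None])
            assert got == pytest.approx(oracle_auc_column(y, s), abs=1e-12)


class TestAgainstSklearn:
    def test_thousand_random_instances_match_reference(self):
        """Independent-implementation cross-check at 1e-9."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            l = int(rng.integers(2, 6))
            Y = rng.integers(0, 2, size=(n, l))
            Yhat = rng.integers(0, 2, size=(n, l))
            S = rng.standard_normal((n, l))
            assert subset_accuracy(Y, Yhat) == pytest.approx(
                accuracy_score(Y, Yhat), abs=1e-9)
            assert hamming_loss(Y, Yhat) == pytest.approx(
                sk_hamming(Y, Yhat), abs=1e-9)
            assert macro_f1(Y, Yhat) == pytest.approx(
                f1_score(Y, Yhat, average="macro", zero_division=0), abs=1e-9)
            assert macro_jaccard(Y, Yhat) == pytest.approx(
                jaccard_score(Y, Yhat, average="samples", zero_division=1),
                abs=1e-9)
            both = (Y.sum(axis=0) > 0) & (Y.sum(axis=0) < n)
            if both.any():
                assert macro_auc(Y[:, both], S[:, both]) == pytest.approx(
                    roc_auc_score(Y[:, both], S[:, both], average="macro"),
                    abs=1e-9)


class TestCornerCases:
    def test_perfect_prediction(self):
        Y = np.array([[1, 0], [0, 1]])
        assert subset_accuracy(Y, Y) == 1.0
        assert hamming_loss(Y, Y) == 0.0
        assert macro_f1(Y, Y) == 1.0
        assert macro_jaccard(Y, Y) == 1.0

    def test_one_row_off_by_one_label(self):
        Y = np.array([[1, 0], [0, 1]])
        Yhat = np.array([[1, 0], [1, 1]])
        assert subset_accuracy(Y, Yhat) == 0.5

    def test_single_flip_hamming(self):
        Y = np.zeros((2, 3), dtype=int)
        Yhat = Y.copy()
        Yhat[0, 1] = 1
        assert hamming_loss(Y, Yhat) == pytest.approx(1 / 6)

    def test_complement_prediction_hamming_is_one(self):
        Y = np.array([[1, 0, 1]])
        assert hamming_loss(Y, 1 - Y) == 1.0

    def test_macro_f1_hand_example(self):
        """Class 1: TP=1 FP=1 FN=0; class 2: TP=1 FP=0 FN=1 -> mean 2/3."""
        Y = np.array([[1, 1], [0, 1]])
        Yhat = np.array([[1, 1], [1, 0]])
        assert macro_f1(Y, Yhat) == pytest.approx(2 / 3)

    def test_never_predicted_never_true_class_contributes_zero(self):
        Y = np.array([[1, 0], [1, 0]])
        assert macro_f1(Y, Y) == pytest.approx(0.5)

    def test_jaccard_single_sample_third(self):
        assert macro_jaccard([[1, 1, 0]], [[1, 0, 1]]) == pytest.approx(1 / 3)

    def test_jaccard_disjoint_is_zero(self):
        assert macro_jaccard([[1, 0]], [[0, 1]]) == 0.0

    def test_jaccard_empty_union_counts_as_one(self):
        assert macro_jaccard([[0, 0]], [[0, 0]]) == 1.0

    def test_labelwise_variant_differs_from_samplewise(self):
        Y = np.array([[1, 0], [1, 0]])
        Yhat = np.array([[1, 0], [0, 0]])
        assert macro_jaccard(Y, Yhat) == pytest.approx(0.5)       # (1 + 0)/2
        assert labelwise_jaccard(Y, Yhat) == pytest.approx(0.75)  # (1/2 + 1)/2

    def test_auc_perfect_and_reversed_and_constant(self):
        y = np.array([[1], [1], [0], [0]])
        s = np.array([[4.0], [3.0], [2.0], [1.0]])
        assert macro_auc(y, s) == 1.0
        assert macro_auc(y, -s) == 0.0
        assert macro_auc(y, np.zeros_like(s)) == 0.5

    def test_auc_single_class_everywhere_raises(self):
        with pytest.raises(UndefinedAUCError):
            macro_auc(np.ones((3, 2), dtype=int), np.zeros((3, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subset_accuracy(np.zeros((2, 2), dtype=int),
                            np.zeros((2, 3), dtype=int))


class TestInvariants:
    def test_subset_accuracy_one_iff_hamming_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            Y = rng.integers(0, 2, size=(4, 3))
            Yhat = rng.integers(0, 2, size=(4, 3))
            assert (subset_accuracy(Y, Yhat) == 1.0) == (hamming_loss(Y, Yhat) == 0.0)

    def test_subset_accuracy_lower_bound_from_hamming(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n, l = rng.integers(1, 6), rng.integers(1, 5)
            Y = rng.integers(0, 2, size=(n, l))
            Yhat = rng.integers(0, 2, size=(n, l))
            assert subset_accuracy(Y, Yhat) >= 1 - l * hamming_loss(Y, Yhat) - 1e-12

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(13)
        Y = rng.integers(0, 2, size=(6, 4))
        Yhat = rng.integers(0, 2, size=(6, 4))
        perm = rng.permutation(4)
        assert macro_f1(Y, Yhat) == pytest.approx(macro_f1(Y[:, perm], Yhat[:, perm]))
        assert macro_jaccard(Y, Yhat) == pytest.approx(
            macro_jaccard(Y[:, perm], Yhat[:, perm]))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        Y = rng.integers(0, 2, size=(20, 3))
        Y[0], Y[1] = 0, 1  # both classes present everywhere
        S = rng.standard_normal((20, 3))
        assert macro_auc(Y, S) == pytest.approx(macro_auc(Y, np.exp(2 * S)))


class TestReportingArithmetic:
    @pytest.mark.parametrize("ref,new,expected", [
        (49.0, 55.2, 12.7),
        (0.046, 0.034, 26.1),
        (3.0, 3.0, 0.0),
        (88.0, 91.2, 3.6),
    ])
    def test_relative_change(self, ref, new, expected):
        assert relative_change(ref, new) == expected

    def test_relative_change_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_change(0.0, 1.0)

    @pytest.mark.parametrize("std,pert,expected", [
        (64.8, 63.2, 1.6),
        (65.5, 64.1, 1.4),
        (5.0, 5.0, 0.0),
        (55.2, 53.1, 2.1),
    ])
    def test_absolute_drop(self, std, pert, expected):
        assert absolute_drop(std, pert) == expected

    def test_round_half_up_behaviour(self):
        # 100 * |10.05 - 10| / 10 = 0.5 -> rounds up to 0.5? one-decimal: 0.5
        assert relative_change(10.0, 10.015) == 0.2  # 0.15 -> 0.2 (half-up)
        assert absolute_drop(1.0, 0.75) == 0.3       # 0.25 -> 0.3 (half-up)


class TestReport:
    def test_evaluate_all_consistency(self):
        rng = np.random.default_rng(21)
        Y = rng.integers(0, 2, size=(10, 3))
        Y[0], Y[1] = 0, 1
        Yhat = rng.integers(0, 2, size=(10, 3))
        S = rng.standard_normal((10, 3))
        rep = evaluate_all(Y, S, Yhat)
        assert rep.subset_accuracy == subset_accuracy(Y, Yhat)
        assert rep.macro_f1 == macro_f1(Y, Yhat)
        assert rep.macro_auc == macro_auc(Y, S)
        assert rep.jaccard == macro_jaccard(Y, Yhat)
        assert rep.hamming_loss == hamming_loss(Y, Yhat)
        assert set(rep.per_class) == {"precision", "recall", "f1"}

    def test_percent_row_scaling(self):
        rep = MetricsReport(subset_accuracy=0.552, macro_f1=0.648,
                            macro_auc=0.912, jaccard=0.601, hamming_loss=0.034)
        row = rep.as_percent_row()
        assert row["Subset Accuracy(%)"] == 55.2
        assert row["Hamming Loss(%)"] == 3.4
        assert rep.as_fractions()["hamming_loss"] == 0.034

    def test_out_of_range_metric_rejected(self):
        with pytest.raises(ValueError):
            MetricsReport(1.2, 0.5, 0.5, 0.5, 0.1)
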