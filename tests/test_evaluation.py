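"""ROC/PR machinery, intersection-k confusion, F/MCC, SVD analysis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaloc.core import GoldStandard, MetalocError
from metaloc.evaluation import (
    bootstrap_auroc_diff,
    confusion_at_k,
    evaluate,
    f_score,
    mcc,
    pr,
    roc,
    shared_rank_matrix,
    svd_independence,
)


def _scores_for(labels):
    """Tie-free scores whose descending order matches the label sequence."""
    return np.linspace(1.0, 0.0, len(labels), endpoint=False)


def pairwise_auroc(labels):
    """Brute-force Mann-Whitney statistic on an ordered label sequence."""
    pos_idx = [i for i, y in enumerate(labels) if y == 1]
    neg_idx = [i for i, y in enumerate(labels) if y == 0]
    wins = sum(1 for i in pos_idx for j in neg_idx if i < j)
    return wins / (len(pos_idx) * len(neg_idx))


class TestRoc:
    @pytest.mark.parametrize(
        "labels,expected",
        [((1, 1, 0, 0), 1.0), ((1, 0, 1, 0), 0.75), ((0, 0, 1, 1), 0.0)],
    )
    def test_known_values(self, labels, expected):
        assert roc(_scores_for(labels), np.array(labels)).auroc == pytest.approx(expected)

    def test_single_class_errors(self):
        with pytest.raises(MetalocError, match="negative"):
            roc(np.array([0.9, 0.1]), np.array([1, 1]))

    def test_curve_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 1, 0
        curve = roc(rng.normal(size=50), labels)
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.points[:, 0]) >= 0)
        assert np.all(np.diff(curve.points[:, 1]) >= 0)

    def test_equals_pairwise_statistic_exhaustive_small(self):
        """Trapezoid AUROC == Mann-Whitney count on all length<=8 sequences."""
        for n in range(2, 9):
            for labels in itertools.product((0, 1), repeat=n):
                if 0 < sum(labels) < n:
                    got = roc(_scores_for(labels), np.array(labels)).auroc
                    assert got == pytest.approx(pairwise_auroc(labels))

    def test_matches_sklearn_on_tie_free_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 200)
        labels[:2] = (0, 1)
        scores = rng.permutation(np.linspace(0, 1, 200))
        assert roc(scores, labels).auroc == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_reversal_complements_auroc(self, rng):
        labels = rng.integers(0, 2, 99)
        labels[:2] = (0, 1)
        scores = rng.permutation(np.linspace(0, 1, 99))
        a = roc(scores, labels).auroc
        b = roc(-scores, labels).auroc
        assert a + b == pytest.approx(1.0)

    def test_shuffled_labels_near_half(self, rng):
        """Random ranking scores ~0.5; 3 SE band over repeated shuffles."""
        n_pos, n_neg = 60, 140
        labels = np.array([1] * n_pos + [0] * n_neg)
        aucs = [
            roc(np.arange(200, dtype=float), rng.permutation(labels)).auroc
            for _ in range(200)
        ]
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(np.mean(aucs) - 0.5) < 3 * se / np.sqrt(200)


class TestPr:
    def test_perfect_list_crosses_at_p(self):
        labels = np.array([1, 1, 1, 0, 0])
        curve = pr(_scores_for(labels), labels)
        assert curve.k_star == 3
        tp, tn, fp, fn = confusion_at_k(_scores_for(labels), labels, curve.k_star)
        assert (tp, fp, fn) == (3, 0, 0)

    def test_alternating_crosses_at_two(self):
        labels = np.array([1, 0, 1, 0])
        assert pr(_scores_for(labels), labels).k_star == 2

    def test_all_positive_aupr_one(self):
        labels = np.array([1, 1, 1])
        curve = pr(_scores_for(labels), labels)
        assert curve.aupr == pytest.approx(1.0)
        assert np.all(curve.points[:, 1] == 1.0)

    def test_no_positive_errors(self):
        with pytest.raises(MetalocError):
            pr(np.array([0.5]), np.array([0]))


class TestConfusion:
    def test_alternating_at_two(self):
        labels = np.array([1, 0, 1, 0])
        assert confusion_at_k(_scores_for(labels), labels, 2) == (1, 1, 1, 1)

    def test_full_cutoff_no_negatives_predicted(self):
        labels = np.array([1, 0, 0, 1])
        tp, tn, fp, fn = confusion_at_k(_scores_for(labels), labels, 4)
        assert tn == fn == 0

    def test_sums_conserve_for_all_k(self, rng):
        labels = rng.integers(0, 2, 30)
        scores = rng.normal(size=30)
        for k in range(1, 31):
            assert sum(confusion_at_k(scores, labels, k)) == 30

    def test_out_of_range_errors(self):
        with pytest.raises(MetalocError):
            confusion_at_k(np.array([0.5]), np.array([1]), 2)


class TestFScore:
    def test_perfect(self):
        assert f_score(5, 0, 0) == 1.0

    def test_arithmetic(self):
        assert f_score(3, 1, 2) == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))

    def test_zero_tp(self):
        assert f_score(0, 3, 2) == 0.0

    def test_undefined_denominator_errors(self):
        with pytest.raises(MetalocError):
            f_score(0, 0, 2)


class TestMcc:
    def test_perfect(self):
        assert mcc(5, 5, 0, 0) == 1.0

    def test_arithmetic(self):
        assert mcc(3, 4, 1, 2) == pytest.approx(10 / np.sqrt(600))

    def test_no_association(self):
        assert mcc(2, 2, 2, 2) == 0.0

    def test_degenerate_zero_by_convention(self):
        assert mcc(0, 5, 0, 2) == 0.0  # tp+fp == 0 marginal

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_symmetric_under_class_swap(self, counts):
        tp, tn, fp, fn = counts
        assert mcc(tp, tn, fp, fn) == pytest.approx(mcc(tn, tp, fn, fp))


class TestEvaluate:
    def test_overall_equals_single_location_row(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = (0, 1)
        score_map = {
            (f"prot{i:02d}", "mito"): float(s)
            for i, s in enumerate(rng.normal(labels * 2.0, 1.0))
        }
        gold = GoldStandard(
            positives={
                f"prot{i:02d}": ({"mito"} if labels[i] else {"plast"})
                for i in range(40)
            }
        )
        report = evaluate(score_map, gold)
        assert report.per_location["mito"].auroc == pytest.approx(report.overall.auroc)
        assert report.per_location["vacu"] is None

    def test_location_without_nodes_unavailable(self, tiny_gold):
        score_map = {("prot1", "mito"): 0.9, ("prot2", "mito"): 0.4}
        report = evaluate(score_map, tiny_gold)
        assert report.per_location["Golgi"] is None

    def test_counts_sum_to_list_length(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = (0, 1)
        score_map = {
            (f"p{i:02d}", "nucl"): float(s) for i, s in enumerate(rng.normal(size=50))
        }
        gold = GoldStandard(
            positives={
                f"p{i:02d}": ({"nucl"} if labels[i] else {"cytos"}) for i in range(50)
            }
        )
        row = evaluate(score_map, gold).overall
        assert row.tp + row.tn + row.fp + row.fn == row.n_nodes


class TestBootstrap:
    def test_detects_obvious_difference(self, rng):
        labels = rng.integers(0, 2, 300)
        labels[:2] = (0, 1)
        good = {
            (f"p{i}", "mito"): float(rng.normal(2.5 * labels[i], 1)) for i in range(300)
        }
        bad = {(f"p{i}", "mito"): float(rng.normal(0, 1)) for i in range(300)}
        gold = GoldStandard(
            positives={
                f"p{i}": ({"mito"} if labels[i] else {"plast"}) for i in range(300)
            }
        )
        diff, lo, hi = bootstrap_auroc_diff(good, bad, gold, n_boot=100, seed=1)
        assert diff > 0.2
        assert lo > 0


class TestSvd:
    def test_duplicated_column_fully_dependent(self):
        col = np.arange(1, 21, dtype=float)
        res = svd_independence(np.column_stack([col, col]))
        assert res.singular_values[1] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_design_equal_values(self):
        m = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        res = svd_independence(m)
        assert res.singular_values[0] == pytest.approx(res.singular_values[1])

    def test_independent_rank_vectors_flat_spectrum(self, rng):
        m = np.column_stack([rng.permutation(500) + 1.0 for _ in range(5)])
        res = svd_independence(m)
        assert res.variance_fraction[0] < 0.40

    def test_single_row_errors(self):
        with pytest.raises(MetalocError):
            svd_independence(np.array([[1.0, 2.0]]))

    def test_shared_rank_matrix_alignment(self, tiny_outputs):
        from metaloc.voting import build_ranked_lists

        lists = build_ranked_lists(tiny_outputs)
        ids, matrix = shared_rank_matrix(lists)
        # shared nodes: predB scored mito+plast for prot1..3 only
        assert matrix.shape == (len(ids), 2)
        assert set(ids) == {
            (p, l) for p in ("prot1", "prot2", "prot3") for l in ("mito", "plast")
        }
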