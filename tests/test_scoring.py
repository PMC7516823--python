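import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import normalized_mutual_info_score

from conftest import random_contingency
from wmiclust.scoring import (ContingencyTable, conditional_entropy, contingency,
                              entropy, nmi, nmi_labels, nmi_vs_accuracy_curve)


def table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(counts, np.arange(counts.shape[0]),
                            np.arange(counts.shape[1]))


def mi_double_sum(counts):
    """Independent MI oracle: sum_ij p_ij log2(p_ij / (p_i p_j))."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    p = counts / n
    pj = p.sum(axis=1, keepdims=True)
    pi = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pj * pi))
    return float(np.nansum(terms))


class TestContingency:
    def test_diagonal_for_identical_partitions(self):
        t = contingency([1, 1, 2, 2], [1, 1, 2, 2])
        np.testing.assert_array_equal(t.counts, [[2, 0], [0, 2]])

    def test_single_cluster_two_classes(self):
        t = contingency([1, 2], [1, 1])
        np.testing.assert_array_equal(t.counts, [[1, 1]])

    def test_grand_total_conserved(self, rng):
        truth = rng.integers(0, 3, size=20)
        clust = rng.integers(0, 4, size=20)
        assert contingency(truth, clust).n == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            contingency([1, 2], [1, 2, 3])

    def test_arbitrary_label_values_mapped_densely(self):
        t = contingency([10, 10, -5], ["a", "b", "a"])
        assert t.counts.shape == (2, 2)
        assert t.n == 3


class TestEntropy:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 5), 1.0),          # uniform binary: 1 bit
        ((10,), 0.0),           # degenerate
        ((1, 1, 1, 1), 2.0),    # uniform over 4: 2 bits
        ((3, 0, 3), 1.0),       # zero counts contribute nothing
    ])
    def test_closed_forms(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            entropy((0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            entropy((3, -1))


class TestConditionalEntropy:
    def test_pure_clusters_zero(self):
        assert conditional_entropy(table([[2, 0], [0, 2]])) == pytest.approx(0.0)

    def test_uninformative_clusters_full_entropy(self):
        assert conditional_entropy(table([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_mixed_table_matches_double_sum(self):
        # each cluster is (4,1): h(0.2) = -0.2 log2 0.2 - 0.8 log2 0.8
        h = -(0.2 * np.log2(0.2) + 0.8 * np.log2(0.8))
        assert conditional_entropy(table([[4, 1], [1, 4]])) == pytest.approx(h)
        assert conditional_entropy(table([[4, 1], [1, 4]])) == pytest.approx(
            0.7219, abs=5e-5)

    def test_bounded_by_class_entropy(self, rng):
        for _ in range(200):
            counts = random_contingency(rng)
            t = table(counts)
            assert -1e-12 <= conditional_entropy(t) <= entropy(t.class_sizes) + 1e-9


class TestNmi:
    def test_perfect_clustering_scores_one(self):
        assert nmi(table([[5, 0], [0, 5]])).value == pytest.approx(1.0)

    def test_half_correct_balanced_scores_zero(self):
        assert nmi(table([[5, 5], [5, 5]])).value == pytest.approx(0.0, abs=1e-12)

    def test_mixed_table_value(self):
        # H(T)=H(C)=1 bit, H(T|C)=h(0.2) -> NMI = 1 - h(0.2) = 0.2781...
        h = -(0.2 * np.log2(0.2) + 0.8 * np.log2(0.8))
        assert nmi(table([[4, 1], [1, 4]])).value == pytest.approx(1 - h, rel=1e-10)
        assert nmi(table([[4, 1], [1, 4]])).value == pytest.approx(0.2781, abs=5e-5)

    def test_degenerate_single_class_single_cluster_is_one(self):
        assert nmi(table([[7]])).value == 1.0

    def test_mi_consistent_with_entropy_decomposition(self, rng):
        for _ in range(100):
            s = nmi(table(random_contingency(rng)))
            assert s.mi == pytest.approx(max(s.h_t - s.h_t_given_c, 0.0), abs=1e-10)
            assert 0.0 <= s.value <= 1.0

    def test_mi_matches_double_sum_oracle(self, rng):
        for _ in range(1000):
            counts = random_contingency(rng)
            s = nmi(table(counts))
            ref = mi_double_sum(counts)
            assert s.mi == pytest.approx(max(ref, 0.0), abs=1e-10)
            assert s.mi <= min(s.h_t, s.h_c) + 1e-9

    def test_invariant_to_row_and_column_permutations(self, rng):
        counts = random_contingency(rng, max_rows=4, max_cols=4)
        base = nmi(table(counts)).value
        for _ in range(10):
            p = rng.permutation(counts.shape[0])
            q = rng.permutation(counts.shape[1])
            assert nmi(table(counts[p][:, q])).value == pytest.approx(base, abs=1e-12)

    def test_invariant_to_log_base(self, rng):
        counts = random_contingency(rng)
        assert nmi(table(counts), base=2.0).value == pytest.approx(
            nmi(table(counts), base=np.e).value, abs=1e-12)

    def test_matches_reference_library_on_random_labels(self, rng):
        # independent implementation check: scikit-learn's NMI with
        # arithmetic-mean normalisation is the same statistic
        for _ in range(100):
            n = int(rng.integers(5, 60))
            truth = rng.integers(0, 4, size=n)
            clust = rng.integers(0, 4, size=n)
            ours = nmi_labels(truth, clust)
            if np.unique(truth).size == 1 and np.unique(clust).size == 1:
                continue  # sklearn defines this degenerate case as 0, we as 1
            ref = normalized_mutual_info_score(truth, clust,
                                               average_method="arithmetic")
            assert ours == pytest.approx(ref, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=30))
    def test_nmi_bounded_for_arbitrary_label_pairs(self, pairs):
        truth = [a for a, _ in pairs]
        clust = [b for _, b in pairs]
        assert 0.0 <= nmi_labels(truth, clust) <= 1.0


class TestAccuracyCurve:
    def test_endpoints(self):
        curve = dict(nmi_vs_accuracy_curve([0.0, 0.5]))
        assert curve[1.0] == pytest.approx(1.0)
        assert curve[0.5] == pytest.approx(0.0, abs=1e-12)

    def test_interior_point_closed_form(self):
        ((acc, val),) = nmi_vs_accuracy_curve([0.07])
        h = -(0.07 * np.log2(0.07) + 0.93 * np.log2(0.93))
        assert acc == pytest.approx(0.93)
        assert val == pytest.approx(1 - h, rel=1e-12)
        assert 0.55 < val < 0.7  # steeply nonlinear: ~0.63 at 93% accuracy

    def test_monotone_increasing_in_accuracy(self):
        vals = [v for _, v in nmi_vs_accuracy_curve(np.linspace(0.5, 0.0, 26))]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            nmi_vs_accuracy_curve([0.6])


def test_curve_matches_empirical_confusion_tables():
    # the closed form agrees with NMI computed from an explicit balanced
    # symmetric confusion table at the same accuracy
    for e, n in ((0.1, 1000), (0.25, 1000)):
        wrong = int(e * n)
        t = table([[n - wrong, wrong], [wrong, n - wrong]])
        ((_, closed),) = nmi_vs_accuracy_curve([e])
        assert nmi(t).value == pytest.approx(closed, rel=1e-9)
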