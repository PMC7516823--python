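"""Contingency tables, entropy, mutual information and NMI.

All agreement scores between a clustering C and the true classes T are
functions of the contingency table n_ji (objects in cluster j with true
class i).  With marginals n_j, n_i and total n:

    H(T)    = - sum_i (n_i/n) log2(n_i/n)
    H(C)    = - sum_j (n_j/n) log2(n_j/n)
    H(T|C)  =   sum_j (n_j/n) [ - sum_i (n_ji/n_j) log2(n_ji/n_j) ]
    MI      =   H(T) - H(T|C)
    NMI     =   2 MI / (H(T) + H(C))

NMI is bounded in [0, 1], invariant to relabelling of clusters or classes
and to the logarithm base, and deliberately nonlinear in accuracy: for a
balanced two-class problem it is 0 when half the objects are correctly
grouped and rises steeply only near perfect agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContingencyTable",
    "NmiScore",
    "contingency",
    "entropy",
    "conditional_entropy",
    "nmi",
    "nmi_labels",
    "nmi_vs_accuracy_curve",
]


@dataclass
class ContingencyTable:
    """Counts[j, i] = number of objects in cluster j belonging to class i."""

    counts: np.ndarray
    cluster_values: np.ndarray  # original cluster ids, row order
    class_values: np.ndarray    # original class ids, column order

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("contingency counts must be 2-d")
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be nonnegative")
        if self.counts.sum() < 1:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class NmiScore:
    """NMI with the entropy terms it was assembled from (all in bits)."""

    value: float
    mi: float
    h_t: float
    h_c: float
    h_t_given_c: float


def contingency(true_labels, cluster_labels) -> ContingencyTable:
    """Cross-tabulate cluster assignments (rows) against true classes (columns)."""
    t = np.asarray(true_labels).ravel()
    c = np.asarray(cluster_labels).ravel()
    if t.shape[0] != c.shape[0]:
        raise ValueError(
            f"label sequences have different lengths: {t.shape[0]} vs {c.shape[0]}"
        )
    if t.shape[0] == 0:
        raise ValueError("label sequences are empty")
    cvals, crows = np.unique(c, return_inverse=True)
    tvals, tcols = np.unique(t, return_inverse=True)
    counts = np.zeros((cvals.size, tvals.size), dtype=np.int64)
    np.add.at(counts, (crows, tcols), 1)
    return ContingencyTable(counts, cvals, tvals)


def entropy(marginal_counts, base: float = 2.0) -> float:
    """Shannon entropy of a count vector; zero counts contribute 0 (0 log 0 := 0)."""
    counts = np.asarray(marginal_counts, dtype=float).ravel()
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an all-zero count vector is undefined")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def conditional_entropy(table: ContingencyTable, base: float = 2.0) -> float:
    """H(T|C): class-label entropy remaining within each cluster, size-weighted."""
    counts = table.counts.astype(float)
    n = counts.sum()
    nj = counts.sum(axis=1)
    h = 0.0
    for j in range(counts.shape[0]):
        if nj[j] == 0:
            continue
        p = counts[j][counts[j] > 0] / nj[j]
        h += (nj[j] / n) * float(-(p * (np.log(p) / np.log(base))).sum())
    return h


def nmi(table: ContingencyTable, base: float = 2.0) -> NmiScore:
    """Normalized mutual information 2 MI / (H(T) + H(C)) from a contingency table.

    The degenerate case of a single class in a single cluster has
    H(T) + H(C) = 0 and is scored 1: both partitions are trivial and agree
    perfectly.  The value is clamped to [0, 1] against rounding.
    """
    h_t = entropy(table.class_sizes, base=base)
    h_c = entropy(table.cluster_sizes, base=base)
    h_tc = conditional_entropy(table, base=base)
    mi = h_t - h_tc
    if h_t + h_c <= 0:
        value = 1.0
    else:
        value = 2.0 * mi / (h_t + h_c)
    return NmiScore(float(min(max(value, 0.0), 1.0)), float(max(mi, 0.0)),
                    h_t, h_c, h_tc)


def nmi_labels(true_labels, cluster_labels, base: float = 2.0) -> float:
    """Convenience: NMI value straight from two label sequences."""
    return nmi(contingency(true_labels, cluster_labels), base=base).value


def _binary_entropy(p: float) -> float:
    if p <= 0 or p >= 1:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def nmi_vs_accuracy_curve(error_rate_grid) -> list[tuple[float, float]]:
    """NMI as a function of accuracy for balanced two-class symmetric confusion.

    For error rate e in [0, 0.5] the table is [[1-e, e], [e, 1-e]]/2, both
    marginals are uniform (1 bit), and NMI = 1 - h(e) with h the binary
    entropy — zero at 50% accuracy, one at 100%, and markedly convex in
    between (about 0.63 at 93% accuracy).  Returns (accuracy, nmi) pairs.
    """
    out = []
    for e in np.asarray(error_rate_grid, dtype=float).ravel():
        if not (0.0 <= e <= 0.5):
            raise ValueError(f"error rate must lie in [0, 0.5], got {e}")
        out.append((1.0 - e, 1.0 - _binary_entropy(e)))
    return out
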