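"""WMI weights, cross-kernel label alignment, and consensus voting.

Each kernel r earns a weight proportional to its training-set NMI eta_r:

    w_r = eta_r / sum_k eta_k,   sum_r w_r = 1.

Per object, every kernel casts its weight for the cluster it assigned the
object to; the consensus label is the argmax of the accumulated weight.
Majority voting is the uniform-weight special case.

Votes are only meaningful if "cluster j" names the same group across
kernels, but each kernel K-means run labels its clusters arbitrarily.  The
labelled training subset is the one anchor available, so before voting each
result's cluster ids are permuted to maximise agreement with the true
classes on the training subset (optimal one-to-one assignment on the
training contingency counts, solved by the Hungarian method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .kkmeans import ClusteringResult
from .scoring import contingency

__all__ = ["WeightVector", "AggregationResult", "wmi_weights", "align_clusters",
           "weighted_vote", "majority_vote"]

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """Per-kernel WMI weights (nonnegative, summing to 1) and their source NMIs."""

    weights: np.ndarray
    source_nmis: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.source_nmis = np.asarray(self.source_nmis, dtype=float)
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise ValueError("weights must be a nonempty 1-d sequence")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()!r}")

    @property
    def R(self) -> int:
        return self.weights.size


@dataclass
class AggregationResult:
    """Consensus labels plus the per-object accumulated vote mass per cluster."""

    labels: np.ndarray
    per_object_scores: np.ndarray
    cluster_ids: np.ndarray
    method: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.per_object_scores = np.asarray(self.per_object_scores, dtype=float)


def wmi_weights(nmis: Sequence[float]) -> WeightVector:
    """Normalise per-kernel NMI scores into voting weights w_r = eta_r / sum eta.

    All-zero NMIs make the ratio 0/0; the declared fallback is uniform
    weights (i.e. plain majority voting), logged as a warning.
    """
    eta = np.asarray(nmis, dtype=float).ravel()
    if eta.size < 1:
        raise ValueError("need at least one NMI score")
    if (eta < 0).any():
        raise ValueError(f"NMI scores must be nonnegative, got {eta.tolist()}")
    total = eta.sum()
    if total <= 0:
        logger.warning(
            "all training NMI scores are zero; falling back to uniform weights"
        )
        return WeightVector(np.full(eta.size, 1.0 / eta.size), eta)
    return WeightVector(eta / total, eta)


def align_clusters(result: ClusteringResult, training_truth,
                   training_indices) -> ClusteringResult:
    """Permute a result's cluster ids to best match true classes on the training set.

    Solves the optimal one-to-one assignment between cluster ids and class
    ids that maximises training-subset agreement; the partition itself is
    untouched.  Clusters unmatched on the training subset (absent there, or
    in excess of the class count) keep distinct ids after the matched ones.
    """
    truth = np.asarray(training_truth).ravel()
    idx = np.asarray(list(training_indices), dtype=int)
    if idx.size == 0:
        raise ValueError("training subset is empty; nothing to align on")
    if truth.shape[0] == idx.shape[0]:
        sub_truth = truth
    else:
        sub_truth = truth[idx]
    sub_clusters = result.labels[idx]
    table = contingency(sub_truth, sub_clusters)
    # rows = clusters present on the training subset, columns = classes
    rows, cols = linear_sum_assignment(-table.counts)
    # assignment targets are dense 1-based class ranks
    mapping: dict[int, int] = {}
    for r, c in zip(rows, cols):
        mapping[int(table.cluster_values[r])] = int(c) + 1
    taken = set(mapping.values())
    nxt = 1
    for cid in range(1, result.k + 1):
        if cid not in mapping:
            while nxt in taken:
                nxt += 1
            mapping[cid] = nxt
            taken.add(nxt)
    return result.relabeled(mapping)


def _vote(results: Sequence[ClusteringResult], weights: np.ndarray,
          method: str) -> AggregationResult:
    if len(results) == 0:
        raise ValueError("no clustering results to aggregate")
    n = results[0].n
    for r in results:
        if r.n != n:
            raise ValueError(
                f"results cover different object counts: {r.n} vs {n}"
            )
    if len(results) != weights.size:
        raise ValueError(
            f"{len(results)} results but {weights.size} weights"
        )
    cluster_ids = np.unique(np.concatenate([r.labels for r in results]))
    scores = np.zeros((n, cluster_ids.size))
    col = {int(c): j for j, c in enumerate(cluster_ids)}
    for w, r in zip(weights, results):
        for a, lab in enumerate(r.labels):
            scores[a, col[int(lab)]] += w
    labels = cluster_ids[np.argmax(scores, axis=1)]  # argmax ties -> lowest id
    return AggregationResult(labels, scores, cluster_ids, method)


def weighted_vote(aligned_results: Sequence[ClusteringResult],
                  weights: WeightVector) -> AggregationResult:
    """WMI consensus: each kernel votes its weight; argmax wins, ties to lowest id."""
    return _vote(aligned_results, weights.weights, "wmi")


def majority_vote(aligned_results: Sequence[ClusteringResult]) -> AggregationResult:
    """Uniform-weight consensus baseline (each kernel one equal vote)."""
    R = len(aligned_results)
    if R == 0:
        raise ValueError("no clustering results to aggregate")
    return _vote(aligned_results, np.full(R, 1.0 / R), "majority")
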