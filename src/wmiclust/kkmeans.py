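"""Kernel K-means operating purely on a Gram matrix.

Cluster centres live in the implicit feature space and are never
materialised: the squared distance of point a from the centre of cluster C is

    d^2(a, C) = K[a,a] - (2/|C|) sum_{b in C} K[a,b]
              + (1/|C|^2) sum_{b,c in C} K[b,c]

so one Gram matrix is all the algorithm ever touches.  With the linear
kernel K = X X^T this reduces exactly to Lloyd's K-means in input space.

Assignments are initialised uniformly at random (centres are implicit, so
there is nothing else to initialise), Lloyd-style alternation runs until the
assignment is stable, and the best of ``n_restarts`` random restarts by
final objective is returned.  For PSD kernels the objective is
non-increasing within a restart except at empty-cluster repairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelMatrix

__all__ = ["ClusteringResult", "feature_space_sqdist", "fit"]


def _gram_values(K) -> np.ndarray:
    V = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError(f"Gram matrix must be square, got shape {V.shape}")
    return V


@dataclass
class ClusteringResult:
    """One kernel K-means solution: labels in {1..k} plus convergence metadata."""

    labels: np.ndarray
    k: int
    objective: float
    n_iter: int
    converged: bool
    restart_index: int
    objective_history: np.ndarray = field(default_factory=lambda: np.array([]))
    repaired_iterations: tuple[int, ...] = ()

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def relabeled(self, mapping: dict[int, int]) -> "ClusteringResult":
        """Return a copy with cluster ids permuted (partition unchanged)."""
        new = np.array([mapping[int(l)] for l in self.labels], dtype=int)
        return ClusteringResult(
            new, self.k, self.objective, self.n_iter, self.converged,
            self.restart_index, self.objective_history, self.repaired_iterations,
        )


def feature_space_sqdist(K, a: int, members) -> float:
    """Squared feature-space distance of point ``a`` from the centroid of ``members``.

    ``members`` is the index set of one cluster; it must be nonempty since a
    centroid of nothing is undefined.  Small negative values (numerical noise
    for PSD kernels, genuine pseudo-distances for indefinite ones) are
    clamped to zero.
    """
    V = _gram_values(K)
    idx = np.asarray(list(members), dtype=int)
    if idx.size == 0:
        raise ValueError("cluster member set is empty: centroid undefined")
    m = idx.size
    d2 = V[a, a] - 2.0 * V[a, idx].sum() / m + V[np.ix_(idx, idx)].sum() / m**2
    return float(max(d2, 0.0))


def _all_sqdist(V: np.ndarray, labels0: np.ndarray, k: int) -> np.ndarray:
    """(n, k) matrix of squared distances to every cluster centroid.

    ``labels0`` are 0-based; empty clusters get +inf columns.
    """
    n = V.shape[0]
    Z = np.zeros((n, k))
    Z[np.arange(n), labels0] = 1.0
    sizes = Z.sum(axis=0)
    D = np.full((n, k), np.inf)
    occupied = sizes > 0
    Zn = Z[:, occupied] / sizes[occupied]
    cross = V @ Zn                      # (n, k_occ): mean kernel to each cluster
    within = np.einsum("ij,ij->j", Zn, V @ Zn)  # (k_occ,): centroid self-kernel
    D[:, occupied] = np.diag(V)[:, None] - 2.0 * cross + within[None, :]
    return np.maximum(D, 0.0)


def _single_run(V: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int, tol: float, init_labels=None,
                trace: list | None = None):
    n = V.shape[0]
    if init_labels is not None:
        labels = np.asarray(init_labels, dtype=int).copy()
    else:
        # random-assignment init; guarantee every cluster starts nonempty
        labels = rng.integers(0, k, size=n)
        labels[rng.permutation(n)[:k]] = np.arange(k)
    history, repaired = [], []
    converged = False
    it = 0
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        D = _all_sqdist(V, labels, k)
        new = D.argmin(axis=1)
        # empty-cluster repair: seed each empty cluster with the point
        # currently farthest from its assigned centroid
        for j in range(k):
            if not np.any(new == j):
                D_new = _all_sqdist(V, new, k)
                far = int(np.argmax(D_new[np.arange(n), new]))
                new[far] = j
                repaired.append(it)
        obj = float(_all_sqdist(V, new, k)[np.arange(n), new].sum())
        history.append(obj)
        if trace is not None:
            trace.append(new.copy())
        if np.array_equal(new, labels):
            converged = True
            labels = new
            break
        labels = new
        if prev_obj < np.inf and abs(prev_obj - obj) <= tol * max(abs(prev_obj), 1.0):
            converged = True
            break
        prev_obj = obj
    return labels, history[-1], it, converged, np.asarray(history), tuple(repaired)


def fit(K, k: int, n_restarts: int = 10, max_iter: int = 300,
        tol: float = 1e-8, seed=None, init_labels=None,
        trace: list | None = None) -> ClusteringResult:
    """Cluster the objects behind Gram matrix ``K`` into ``k`` groups.

    Runs ``n_restarts`` random-assignment restarts and keeps the one with the
    lowest final within-cluster sum of squared feature-space distances.
    Returned labels are 1-based ids in {1..k}.

    ``init_labels`` (1-based, length n) fixes the starting assignment — the
    run is then deterministic and ``n_restarts`` is ignored.  ``trace``, if a
    list, collects the 0-based assignment after every iteration.
    """
    V = _gram_values(K)
    n = V.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds number of objects n={n}")
    if k == 1:
        obj = float(_all_sqdist(V, np.zeros(n, dtype=int), 1)[:, 0].sum())
        return ClusteringResult(np.ones(n, dtype=int), 1, obj, 0, True, 0,
                                np.array([obj]))
    rng = np.random.default_rng(seed)
    if init_labels is not None:
        init0 = np.asarray(init_labels, dtype=int) - 1
        if init0.shape[0] != n:
            raise ValueError(f"init_labels length {init0.shape[0]} != n={n}")
        labels, obj, it, conv, hist, rep = _single_run(
            V, k, rng, max_iter, tol, init_labels=init0, trace=trace)
        return ClusteringResult(labels + 1, k, obj, it, conv, 0, hist, rep)
    best = None
    for r in range(n_restarts):
        labels, obj, it, conv, hist, rep = _single_run(
            V, k, rng, max_iter, tol, trace=trace if n_restarts == 1 else None)
        if best is None or obj < best[1]:
            best = (labels, obj, it, conv, r, hist, rep)
    labels, obj, it, conv, r, hist, rep = best
    return ClusteringResult(labels + 1, k, obj, it, conv, r, hist, rep)
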