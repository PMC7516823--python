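"""Kernel functions and Gram-matrix construction.

Kernel K-means never materialises the feature map phi; every quantity it
needs is a dot product phi(x_a) . phi(x_b), i.e. an entry of the n x n Gram
matrix K[a, b] = kappa(x_a, x_b).  This module defines the three kernel
families used throughout the package and builds Gram matrices from data.

Families
--------
gaussian    kappa(x, y) = exp(-||x - y||^2 / (2 sigma^2)),   sigma > 0
polynomial  kappa(x, y) = (x . y + coef0)^degree,            degree >= 1
tangent     kappa(x, y) = tanh(scale * (x . y) + offset),    scale > 0

The Gaussian and (for coef0 >= 0, even degree or nonnegative features)
polynomial kernels are positive semidefinite; the hyperbolic-tangent
("sigmoid") kernel is in general indefinite, which is tolerated here: the
clustering loop works on the Gram matrix regardless, but objective
monotonicity guarantees hold only for PSD kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "KernelSpec",
    "KernelMatrix",
    "kernel_value",
    "gram_matrix",
    "median_heuristic",
    "local_scale_heuristic",
    "default_kernel_specs",
    "resolve_spec",
]

FAMILIES = ("gaussian", "polynomial", "tangent")

_REQUIRED_PARAMS = {
    "gaussian": ("sigma",),
    "polynomial": ("degree", "coef0"),
    "tangent": ("scale", "offset"),
}


def _as_matrix(X) -> np.ndarray:
    """Accept a LabeledDataset, DataFrame or array and return an n x d float array."""
    X = getattr(X, "X", X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError(f"expected a nonempty 2-d feature matrix, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its hyperparameters.

    ``params['sigma']`` may be the string ``"median"`` (resolved against a
    dataset by :func:`resolve_spec` / :func:`gram_matrix`) or a positive float.
    """

    family: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {FAMILIES}"
            )
        object.__setattr__(self, "params", dict(self.params))
        missing = [p for p in _REQUIRED_PARAMS[self.family] if p not in self.params]
        if missing:
            raise ValueError(f"{self.family} kernel missing parameter(s): {missing}")
        p = self.params
        if self.family == "gaussian":
            sigma = p["sigma"]
            if isinstance(sigma, str):
                if sigma not in ("median", "local"):
                    raise ValueError(
                        f"sigma must be a positive number, 'median' or 'local'; got {sigma!r}"
                    )
            elif not (float(sigma) > 0):
                raise ValueError(f"gaussian sigma must be > 0, got {sigma}")
        elif self.family == "polynomial":
            degree = p["degree"]
            if int(degree) != degree or int(degree) < 1:
                raise ValueError(f"polynomial degree must be an integer >= 1, got {degree}")
            float(p["coef0"])
        else:  # tangent
            if not (float(p["scale"]) > 0):
                raise ValueError(f"tangent scale must be > 0, got {p['scale']}")
            float(p["offset"])

    @property
    def label(self) -> str:
        """Short human-readable identifier, e.g. ``gaussian(sigma=0.5)``."""
        inner = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.family}({inner})"

    def to_dict(self) -> dict:
        return {"family": self.family, **self.params}

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "KernelSpec":
        d = dict(d)
        family = d.pop("family")
        return cls(family=family, params=d)


@dataclass
class KernelMatrix:
    """An n x n symmetric Gram matrix together with the spec that produced it."""

    values: np.ndarray
    spec: KernelSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"Gram matrix must be square, got shape {self.values.shape}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, idx):
        return self.values[idx]


def resolve_spec(spec: KernelSpec, X) -> KernelSpec:
    """Replace data-dependent placeholder parameters with numeric values.

    ``sigma='median'`` becomes the median pairwise distance of ``X``;
    ``sigma='local'`` the local-neighbourhood scale (see
    :func:`local_scale_heuristic`).  Numeric specs pass through unchanged.
    """
    if spec.family == "gaussian" and isinstance(spec.params["sigma"], str):
        which = spec.params["sigma"]
        sigma = median_heuristic(X) if which == "median" else local_scale_heuristic(X)
        return KernelSpec("gaussian", {**spec.params, "sigma": float(sigma)})
    return spec


def kernel_value(x: Sequence[float], y: Sequence[float], spec: KernelSpec) -> float:
    """Evaluate kappa(x, y) for a single pair of feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(
            f"feature vectors have mismatched dimensions: {x.shape[0]} vs {y.shape[0]}"
        )
    p = spec.params
    if spec.family == "gaussian":
        sigma = p["sigma"]
        if isinstance(sigma, str):
            raise ValueError(
                "sigma placeholder must be resolved against a dataset first "
                "(see resolve_spec)"
            )
        d2 = float(np.dot(x - y, x - y))
        return float(np.exp(-d2 / (2.0 * float(sigma) ** 2)))
    if spec.family == "polynomial":
        return float((np.dot(x, y) + float(p["coef0"])) ** int(p["degree"]))
    return float(np.tanh(float(p["scale"]) * np.dot(x, y) + float(p["offset"])))


def gram_matrix(X, spec: KernelSpec) -> KernelMatrix:
    """Build the Gram matrix K[a, b] = kappa(x_a, x_b) for all pairs.

    ``X`` may be a LabeledDataset, DataFrame or (n, d) array.  Placeholder
    hyperparameters (``sigma='median'``) are resolved against ``X``.
    The result is symmetrised to machine tolerance.
    """
    arr = _as_matrix(X)
    spec = resolve_spec(spec, arr)
    p = spec.params
    if spec.family == "gaussian":
        sq = squareform(pdist(arr, metric="sqeuclidean")) if arr.shape[0] > 1 else np.zeros((1, 1))
        K = np.exp(-sq / (2.0 * float(p["sigma"]) ** 2))
    elif spec.family == "polynomial":
        K = (arr @ arr.T + float(p["coef0"])) ** int(p["degree"])
    else:
        K = np.tanh(float(p["scale"]) * (arr @ arr.T) + float(p["offset"]))
    K = (K + K.T) / 2.0
    return KernelMatrix(K, spec)


def median_heuristic(X) -> float:
    """Median pairwise Euclidean distance — a scale-free global bandwidth.

    Falls back to 1.0 for degenerate inputs (a single point, or all points
    coincident) where no positive pairwise distance exists.
    """
    arr = _as_matrix(X)
    if arr.shape[0] < 2:
        return 1.0
    d = pdist(arr)
    med = float(np.median(d))
    return med if med > 0 else 1.0


def local_scale_heuristic(X, n_neighbors: int = 7) -> float:
    """Median distance to the ``n_neighbors``-th nearest neighbour.

    Datasets whose classes are thin manifolds (rings, moons) need a bandwidth
    on the order of the within-manifold neighbour spacing, far below the
    global median pairwise distance; this local scale captures connectivity
    along the manifold while keeping distinct manifolds far apart in kernel
    space.  ``n_neighbors=7`` follows the common local-scaling choice.
    """
    arr = _as_matrix(X)
    n = arr.shape[0]
    if n < 2:
        return 1.0
    k = min(n_neighbors, n - 1)
    D = squareform(pdist(arr))
    kth = np.sort(D, axis=1)[:, k]  # column 0 is the self-distance
    med = float(np.median(kth))
    return med if med > 0 else 1.0


def default_kernel_specs(X=None) -> list[KernelSpec]:
    """The package's default three-kernel pool: Gaussian, polynomial, tangent.

    Gaussian bandwidth defaults to the median pairwise distance (resolved
    against ``X`` when given, else left as the ``'median'`` placeholder);
    polynomial is quadratic with coef0=1; tangent uses scale 1/d, offset 0.
    """
    d = _as_matrix(X).shape[1] if X is not None else None
    specs = [
        KernelSpec("gaussian", {"sigma": "median"}),
        KernelSpec("polynomial", {"degree": 2, "coef0": 1.0}),
        KernelSpec("tangent", {"scale": 1.0 / d if d else 1.0, "offset": 0.0}),
    ]
    if X is not None:
        specs = [resolve_spec(s, X) for s in specs]
    return specs
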