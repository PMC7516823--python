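"""Synthetic benchmark generators, the Iris fixture, and training splits.

The two benchmark shapes are the classic cases where plain K-means fails:

* two concentric circles (classes = inner ring radius ``r_inner``, outer
  ring radius ``r_outer``), and
* two interleaving half-moons (unit upper half-circle, plus a lower
  half-circle shifted by (1, -0.5)).

Points are placed at uniformly random angles on each curve and displaced by
isotropic Gaussian noise with standard deviation ``noise_sd``.  Named noise
regimes map to sd = 0 (noiseless), 0.05 (low), 0.10 (moderate) and 0.15
(high) for the default geometry (radii 1 and 2; unit moons) — spanning
visually clean rings through heavily overlapping ones.

A labelled training subset — the only supervised ingredient of the whole
method — is drawn by stratified sampling without replacement.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "TrainTestSplit",
    "NOISE_LEVELS",
    "make_two_circles",
    "make_two_moons",
    "load_iris_fixture",
    "split_training",
]

NOISE_LEVELS = {"noiseless": 0.0, "low": 0.05, "moderate": 0.10, "high": 0.15}

_IRIS_SHA256 = None  # filled in lazily from the packaged file on first load
_IRIS_EXPECTED_SHA256 = "6bcf2ab25d22625844575625401acdc92ba36a6e9db4b4668eeb05502185fe02"


@dataclass
class LabeledDataset:
    """An (n, d) feature matrix with optional integer class labels."""

    X: np.ndarray
    y: Optional[np.ndarray] = None
    name: str = ""
    noise_level: Optional[str] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError(f"feature matrix must be (n>=1, d>=1), got {self.X.shape}")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int).ravel()
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError(
                    f"label length {self.y.shape[0]} != n objects {self.X.shape[0]}"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        if self.y is None:
            raise ValueError(f"dataset {self.name!r} has no labels")
        return int(np.unique(self.y).size)

    def to_csv(self, path) -> None:
        cols = {f"x{i + 1}": self.X[:, i] for i in range(self.d)}
        if self.y is not None:
            cols["label"] = self.y
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "LabeledDataset":
        df = pd.read_csv(path)
        ycol = "label" if "label" in df.columns else None
        y = df[ycol].to_numpy() if ycol else None
        X = df.drop(columns=[ycol]).to_numpy(dtype=float) if ycol else df.to_numpy(dtype=float)
        return cls(X, y, name=name or str(path))


@dataclass
class TrainTestSplit:
    """Indices of the labelled training subset (a proper subset of the data)."""

    training_indices: np.ndarray
    fraction: float

    def __post_init__(self):
        self.training_indices = np.asarray(self.training_indices, dtype=int)
        idx = self.training_indices
        if idx.size == 0:
            raise ValueError("training subset is empty")
        if np.unique(idx).size != idx.size:
            raise ValueError("training indices contain duplicates")


def make_two_circles(n_per_class: int = 150, r_inner: float = 1.0,
                     r_outer: float = 2.0, noise_sd: float = 0.0,
                     seed=None) -> LabeledDataset:
    """Two concentric rings: class 1 at radius ``r_inner``, class 2 at ``r_outer``."""
    if not (0 < r_inner < r_outer):
        raise ValueError(f"need 0 < r_inner < r_outer, got {r_inner}, {r_outer}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for cls, r in ((1, r_inner), (2, r_outer)):
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_per_class)
        ring = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        pts.append(ring + rng.normal(0.0, noise_sd, size=ring.shape))
        labels.append(np.full(n_per_class, cls))
    return LabeledDataset(np.vstack(pts), np.concatenate(labels),
                          name="two_circles", noise_level=_level_name(noise_sd))


def make_two_moons(n_per_class: int = 150, noise_sd: float = 0.0,
                   seed=None) -> LabeledDataset:
    """Two interleaving half-moons: upper unit half-circle, and a lower one
    shifted by (1, -0.5)."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    t1 = rng.uniform(0.0, np.pi, size=n_per_class)
    t2 = rng.uniform(0.0, np.pi, size=n_per_class)
    upper = np.column_stack([np.cos(t1), np.sin(t1)])
    lower = np.column_stack([1.0 - np.cos(t2), -np.sin(t2) - 0.5])
    X = np.vstack([upper, lower]) + rng.normal(0.0, noise_sd, size=(2 * n_per_class, 2))
    y = np.concatenate([np.full(n_per_class, 1), np.full(n_per_class, 2)])
    return LabeledDataset(X, y, name="two_moons", noise_level=_level_name(noise_sd))


def _level_name(sd: float) -> Optional[str]:
    for name, value in NOISE_LEVELS.items():
        if abs(sd - value) < 1e-12:
            return name
    return None


def load_iris_fixture() -> LabeledDataset:
    """Load the bundled 150 x 4, three-class Iris table (public-domain data).

    The packaged CSV is checksummed; a corrupted or missing file raises with
    the expected and observed SHA-256 digests.
    """
    ref = resources.files("wmiclust").joinpath("data/iris.csv")
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"iris fixture missing from package data (expected sha256 "
            f"{_IRIS_EXPECTED_SHA256})"
        ) from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _IRIS_EXPECTED_SHA256:
        raise ValueError(
            f"iris fixture corrupt: sha256 {digest} != expected {_IRIS_EXPECTED_SHA256}"
        )
    import io

    ds = LabeledDataset.from_csv(io.BytesIO(raw), name="iris")
    if ds.X.shape != (150, 4) or ds.n_classes != 3:
        raise ValueError(f"iris fixture has unexpected shape {ds.X.shape}")
    return ds


def split_training(ds: LabeledDataset, fraction: float = 0.3, seed=None,
                   stratified: bool = True) -> TrainTestSplit:
    """Draw a labelled training subset without replacement.

    Stratified by class (default): each class contributes round(fraction *
    class size) points, at least 1 and never the whole class, so the split is
    always a proper subset with every class represented.
    """
    if ds.y is None:
        raise ValueError(f"dataset {ds.name!r} has no labels; cannot form a training set")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    chosen = []
    if stratified:
        for cls in np.unique(ds.y):
            members = np.flatnonzero(ds.y == cls)
            m = int(round(fraction * members.size))
            m = min(max(m, 1), members.size - 1)
            chosen.append(rng.choice(members, size=m, replace=False))
        idx = np.sort(np.concatenate(chosen))
    else:
        m = int(round(fraction * ds.n))
        m = min(max(m, 1), ds.n - 1)
        idx = np.sort(rng.choice(ds.n, size=m, replace=False))
    return TrainTestSplit(idx, fraction)
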