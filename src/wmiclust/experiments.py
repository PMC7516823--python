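"""Monte-Carlo noise-robustness protocol, AWSS cluster-count selection, reporting.

The protocol, per noise level:

1. weight estimation — for each of ``n_instances`` noisy realisations of the
   dataset, draw a stratified labelled training subset, cluster *the
   training subset* with each kernel, and score the result against the known
   training labels with NMI; average the NMI over instances and convert the
   per-kernel means into WMI weights;
2. full-data clustering — on each realisation, cluster the full dataset
   with every kernel, align each result's cluster ids to the true classes on
   the training subset, and aggregate by WMI-weighted voting and by majority
   voting; score every individual kernel and both consensus labelings
   against the (withheld) truth with NMI and average over instances.

Only the training subset's labels ever influence the clustering pipeline;
full-data labels are used solely for evaluation.

Randomness is organised as a seed tree: the master seed spawns independent
streams per (noise level, instance) for data generation, splitting and
restart initialisation, so the whole report is reproducible bit-for-bit
from the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import kkmeans
from .aggregate import align_clusters, majority_vote, weighted_vote, wmi_weights
from .kernels import KernelSpec, default_kernel_specs, gram_matrix, resolve_spec
from .scoring import nmi_labels
from .synthdata import (NOISE_LEVELS, LabeledDataset, load_iris_fixture,
                        make_two_circles, make_two_moons, split_training)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "awss_curve", "suggest_k_elbow"]

_GENERATORS = {"two_circles": make_two_circles, "two_moons": make_two_moons}


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one Monte-Carlo experiment."""

    dataset: str = "two_circles"           # generator name, 'iris', or a CSV path
    dataset_params: dict = field(default_factory=dict)
    kernels: Optional[Sequence[KernelSpec]] = None   # None -> default 3-kernel pool
    k: int = 2
    noise_levels: Sequence[str] = ("noiseless", "low", "moderate", "high")
    n_instances: int = 100
    training_fraction: float = 0.3
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        self.noise_levels = tuple(self.noise_levels)
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.kernels is not None and len(self.kernels) == 0:
            raise ValueError("need at least one kernel")
        unknown = [nl for nl in self.noise_levels if nl not in NOISE_LEVELS]
        if unknown:
            raise ValueError(f"unknown noise level(s) {unknown}; "
                             f"choose from {list(NOISE_LEVELS)}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "kernels" in d and d["kernels"] is not None:
            d["kernels"] = [KernelSpec.from_dict(s) for s in d["kernels"]]
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "dataset_params": dict(self.dataset_params),
            "kernels": None if self.kernels is None
            else [s.to_dict() for s in self.kernels],
            "k": self.k,
            "noise_levels": list(self.noise_levels),
            "n_instances": self.n_instances,
            "training_fraction": self.training_fraction,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }


@dataclass
class ExperimentReport:
    """Tidy result tables mirroring the training-weight / full-data split."""

    training: pd.DataFrame    # noise_level, kernel, mean_train_nmi, wmi_weight
    full_data: pd.DataFrame   # noise_level, method, mean_nmi
    config: dict

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.training.to_csv(out / "training_weights.csv", index=False)
        self.full_data.to_csv(out / "full_data_nmi.csv", index=False)
        (out / "config.json").write_text(json.dumps(self.config, indent=2))

    @classmethod
    def load(cls, outdir) -> "ExperimentReport":
        from pathlib import Path

        out = Path(outdir)
        return cls(pd.read_csv(out / "training_weights.csv"),
                   pd.read_csv(out / "full_data_nmi.csv"),
                   json.loads((out / "config.json").read_text()))


def _make_dataset(cfg: ExperimentConfig, noise_sd: float, seed) -> LabeledDataset:
    if cfg.dataset in _GENERATORS:
        return _GENERATORS[cfg.dataset](noise_sd=noise_sd, seed=seed,
                                        **cfg.dataset_params)
    if cfg.dataset == "iris":
        ds = load_iris_fixture()
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            ds = LabeledDataset(ds.X + rng.normal(0, noise_sd, ds.X.shape),
                                ds.y, name="iris", noise_level=ds.noise_level)
        return ds
    ds = LabeledDataset.from_csv(cfg.dataset)
    return ds


def _kernel_pool(cfg: ExperimentConfig, X) -> list[KernelSpec]:
    if cfg.kernels is None:
        return default_kernel_specs(X)
    return [resolve_spec(s, X) for s in cfg.kernels]


def run_experiment(cfg: ExperimentConfig,
                   progress: Optional[Callable[[str], None]] = None) -> ExperimentReport:
    """Run the full Monte-Carlo protocol described in the module docstring."""
    log = progress or (lambda msg: None)
    train_rows, full_rows = [], []
    for lvl_i, level in enumerate(cfg.noise_levels):
        sd = NOISE_LEVELS[level]
        level_ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(lvl_i,))
        inst_streams = level_ss.spawn(cfg.n_instances)
        kernel_labels = None
        train_nmis = None   # (n_instances, R)
        full_nmis = []      # rows of dicts
        for i, ss in enumerate(inst_streams):
            s_data, s_split, s_fit = ss.spawn(3)
            try:
                ds = _make_dataset(cfg, sd, s_data)
                specs = _kernel_pool(cfg, ds.X)
                if kernel_labels is None:
                    kernel_labels = [s.family for s in specs]
                    train_nmis = np.zeros((cfg.n_instances, len(specs)))
                split = split_training(ds, cfg.training_fraction, seed=s_split)
                idx = split.training_indices
                fit_seeds = np.random.default_rng(s_fit).integers(
                    0, 2**31 - 1, size=2 * len(specs))
                # -- weight estimation on the training subset
                for r, spec in enumerate(specs):
                    Ktr = gram_matrix(ds.X[idx], spec)
                    res = kkmeans.fit(Ktr, cfg.k, n_restarts=cfg.n_restarts,
                                      seed=int(fit_seeds[r]))
                    train_nmis[i, r] = nmi_labels(ds.y[idx], res.labels)
                # -- full-data clustering, aligned on the training subset
                aligned = []
                inst_full = {}
                for r, spec in enumerate(specs):
                    Kfull = gram_matrix(ds.X, spec)
                    res = kkmeans.fit(Kfull, cfg.k, n_restarts=cfg.n_restarts,
                                      seed=int(fit_seeds[len(specs) + r]))
                    res = align_clusters(res, ds.y, idx)
                    aligned.append(res)
                    inst_full[kernel_labels[r]] = nmi_labels(ds.y, res.labels)
                inst_full["_aligned"] = aligned
                inst_full["_truth"] = ds.y
                full_nmis.append(inst_full)
            except Exception as exc:
                raise RuntimeError(
                    f"experiment failed at noise level {level!r}, instance {i}"
                ) from exc
            log(f"{level}: instance {i + 1}/{cfg.n_instances} done")
        # weights from the Monte-Carlo mean training NMI (mean-then-weight)
        mean_train = train_nmis.mean(axis=0)
        wv = wmi_weights(mean_train)
        for r, name in enumerate(kernel_labels):
            train_rows.append({"noise_level": level, "kernel": name,
                               "mean_train_nmi": mean_train[r],
                               "wmi_weight": wv.weights[r]})
        # aggregate each instance with the level's weights
        agg_scores = {name: [] for name in kernel_labels}
        agg_scores["majority"] = []
        agg_scores["wmi"] = []
        for inst in full_nmis:
            aligned = inst.pop("_aligned")
            truth = inst.pop("_truth")
            for name in kernel_labels:
                agg_scores[name].append(inst[name])
            agg_scores["wmi"].append(
                nmi_labels(truth, weighted_vote(aligned, wv).labels))
            agg_scores["majority"].append(
                nmi_labels(truth, majority_vote(aligned).labels))
        for name, vals in agg_scores.items():
            full_rows.append({"noise_level": level, "method": name,
                              "mean_nmi": float(np.mean(vals))})
        log(f"{level}: weights " +
            ", ".join(f"{n}={w:.3f}" for n, w in zip(kernel_labels, wv.weights)))
    return ExperimentReport(pd.DataFrame(train_rows), pd.DataFrame(full_rows),
                            cfg.to_dict())


def awss_curve(ds, kernel_specs: Sequence[KernelSpec], k_max: int,
               seed=None, n_restarts: int = 10) -> list[tuple[int, float]]:
    """Average within-cluster sum of squares across kernels, for k = 1..k_max.

    WSS is each kernel's converged feature-space objective; AWSS averages it
    over the kernel pool.  AWSS is (empirically) non-increasing in k and hits
    0 at k = n, so its literal minimum is degenerate — use
    :func:`suggest_k_elbow` on the returned curve to pick k.
    """
    X = getattr(ds, "X", ds)
    n = np.asarray(X).shape[0]
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds n={n}")
    rng = np.random.default_rng(seed)
    grams = [gram_matrix(X, resolve_spec(s, X)) for s in kernel_specs]
    curve = []
    for k in range(1, k_max + 1):
        wss = [kkmeans.fit(K, k, n_restarts=n_restarts,
                           seed=int(rng.integers(2**31 - 1))).objective
               for K in grams]
        curve.append((k, float(np.mean(wss))))
    return curve


def suggest_k_elbow(curve: Sequence[tuple[int, float]]) -> int:
    """Pick k at the largest relative AWSS drop (the 'elbow').

    The literal AWSS minimiser is always the largest k tried, so the useful
    signal is where adding one more cluster stops paying: the k whose step
    from k-1 removes the largest fraction of the remaining AWSS.
    """
    ks = [k for k, _ in curve]
    vals = [v for _, v in curve]
    if len(ks) < 2:
        return ks[0]
    drops = []
    for i in range(1, len(ks)):
        prev = vals[i - 1]
        drops.append((vals[i - 1] - vals[i]) / prev if prev > 0 else 0.0)
    return ks[1 + int(np.argmax(drops))]
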