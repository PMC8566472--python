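"""Gaussian simulation models and Monte-Carlo experiment runners.

Two benchmark two-group Gaussian models emulate expression-like data:

* **Model 1** — 100 independent unit-variance coordinates; group means
  differ by 0.5 in every coordinate.  A mild, high-dimensional overlap
  scenario mimicking simple expression data.
* **Model 2** — 10 coordinates; group means (0, ..., 0) versus
  (1, 0.8, 0.6, 0.4, 0.2, 0, ..., 0), shared covariance
  ``0.1 I + delta A_6`` where ``A_6`` has a single 1 at diagonal
  position 6.  The last five coordinates are pure noise and ``delta``
  inflates one of them, which is exactly the situation where
  magnitude-sensitive distances break down.

Arbitrary Gaussian mixtures are supported through explicit parameter
sets.  The experiment runners reproduce the classification protocol
(independent train/test pairs per replicate, kNN) and the clustering
protocol (PAM with the true number of groups, scored by clustering
error rate and adjusted Rand index).  One root seed spawns a child seed
stream per replicate, so any single replicate is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .band_counts import ExpressionMatrix
from .binary_indices import (
    SimilarityMatrix,
    band_coefficient_layers,
    cross_band_coefficient_layers,
    to_dissimilarity,
)
from .eval_suite import (
    DistanceSpec,
    LabeledData,
    adjusted_rand_index,
    choose_k,
    classical_dissimilarity,
    clustering_error,
    cross_dissimilarity,
    knn_classify,
    pam_cluster,
)

__all__ = [
    "GaussianModelSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "model1",
    "model2",
    "gaussian_mixture_from_spec",
    "run_classification_experiment",
    "run_clustering_experiment",
]


@dataclass(frozen=True)
class GaussianModelSpec:
    """Explicit parameters of a G-component Gaussian mixture."""

    means: np.ndarray  # (G, d)
    covariances: np.ndarray  # (G, d, d)
    n_per_group: int = 50

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        covs = np.asarray(self.covariances, dtype=float)
        if covs.ndim != 3 or covs.shape[0] != means.shape[0]:
            raise ValueError("need one covariance matrix per group")
        if covs.shape[1:] != (means.shape[1], means.shape[1]):
            raise ValueError("covariance dimensions do not match the means")
        for g, cov in enumerate(covs):
            if not np.allclose(cov, cov.T):
                raise ValueError(f"covariance of group {g} is not symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-8:
                raise ValueError(f"covariance of group {g} is not positive semi-definite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)

    @property
    def G(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]


def _labeled(blocks: list[np.ndarray], group_names: list[str]) -> LabeledData:
    X = np.vstack(blocks)
    labels: list[str] = []
    for name, block in zip(group_names, blocks):
        labels.extend([name] * block.shape[0])
    return LabeledData(X=ExpressionMatrix(X), labels=tuple(labels))


def model1(n_per_group: int = 50, seed=0) -> LabeledData:
    """Two spherical Gaussian groups in 100 dimensions, means 0 and 0.5."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be positive")
    rng = np.random.default_rng(seed)
    d = 100
    g1 = rng.standard_normal((n_per_group, d))
    g2 = rng.standard_normal((n_per_group, d)) + 0.5
    return _labeled([g1, g2], ["g1", "g2"])


def model2(
    delta: float = 0.0,
    n_per_group: int = 50,
    seed=0,
    noise_as: str = "covariance",
) -> LabeledData:
    """Two 10-dimensional Gaussian groups with one inflated noise coordinate.

    ``noise_as="covariance"`` (default) reads ``0.1 I + delta A_6`` as
    the covariance matrix, so coordinate 6 has variance ``0.1 + delta``.
    ``noise_as="sd"`` instead adds ``delta`` to that coordinate's
    standard deviation.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if n_per_group < 1:
        raise ValueError("n_per_group must be positive")
    rng = np.random.default_rng(seed)
    d = 10
    sd = np.full(d, np.sqrt(0.1))
    if noise_as == "covariance":
        sd[5] = np.sqrt(0.1 + delta)
    elif noise_as == "sd":
        sd[5] = np.sqrt(0.1) + delta
    else:
        raise ValueError(f"unknown noise_as mode {noise_as!r}")
    mu2 = np.array([1.0, 0.8, 0.6, 0.4, 0.2, 0, 0, 0, 0, 0])
    g1 = rng.standard_normal((n_per_group, d)) * sd
    g2 = rng.standard_normal((n_per_group, d)) * sd + mu2
    return _labeled([g1, g2], ["g1", "g2"])


def gaussian_mixture_from_spec(spec: GaussianModelSpec, seed=0) -> LabeledData:
    """Sample each group from its own Gaussian; labels attached."""
    rng = np.random.default_rng(seed)
    blocks = [
        rng.multivariate_normal(spec.means[g], spec.covariances[g],
                                size=spec.n_per_group, method="svd")
        for g in range(spec.G)
    ]
    return _labeled(blocks, [f"g{g + 1}" for g in range(spec.G)])


@dataclass(frozen=True)
class ExperimentConfig:
    """A Monte-Carlo experiment: a model, the dissimilarities to race, sizes, seed."""

    task: str  # "classification" | "clustering"
    model: Callable[..., LabeledData]
    specs: tuple[DistanceSpec, ...]
    B: int = 200
    n_train_per_group: int = 100
    n_test_per_group: int = 25
    n_per_cluster: int = 50
    k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "clustering"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.B < 1:
            raise ValueError("need at least one replicate")
        object.__setattr__(self, "specs", tuple(self.specs))


@dataclass
class ExperimentResult:
    """Per-replicate records plus a Table-style mean (sd) summary."""

    task: str
    records: pd.DataFrame  # columns: replicate, method, error[, ari]

    def summary(self) -> pd.DataFrame:
        metrics = [c for c in ("error", "ari") if c in self.records.columns]
        grouped = self.records.groupby("method", sort=False)[metrics]
        out = grouped.agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out

    def mean(self, method: str, metric: str = "error") -> float:
        sub = self.records[self.records["method"] == method]
        if sub.empty:
            raise KeyError(f"no records for method {method!r}")
        return float(sub[metric].mean())


def _square_band_dissims(X, band_specs: Sequence[DistanceSpec]) -> dict[str, np.ndarray]:
    """Square dissimilarities for several band specs, sharing one counting pass."""
    import warnings

    out: dict[str, np.ndarray] = {}
    for agg in {s.aggregation for s in band_specs}:
        group = [s for s in band_specs if s.aggregation == agg]
        Jmax = max(s.J for s in group)
        coeffs = tuple(dict.fromkeys(s.coefficient for s in group))
        layers = band_coefficient_layers(X, Jmax, coeffs, agg)
        for s in group:
            sim = SimilarityMatrix(
                coefficient=s.coefficient,
                J=s.J,
                values=layers[s.coefficient][: s.J - 1].mean(axis=0),
                aggregation=agg,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                out[s.name] = to_dissimilarity(sim).values
    return out


def _cross_band_dissims(
    train, queries, band_specs: Sequence[DistanceSpec]
) -> dict[str, np.ndarray]:
    """Cross dissimilarity blocks for several band specs in one counting pass."""
    out: dict[str, np.ndarray] = {}
    for key in {(s.aggregation, s.reference) for s in band_specs}:
        agg, ref = key
        group = [s for s in band_specs if (s.aggregation, s.reference) == key]
        Jmax = max(s.J for s in group)
        coeffs = tuple(dict.fromkeys(s.coefficient for s in group))
        layers = cross_band_coefficient_layers(train, queries, Jmax, coeffs, agg, ref)
        for s in group:
            S = layers[s.coefficient][: s.J - 1].mean(axis=0)
            if s.coefficient == "F":
                peak = S.max()
                if peak > 0:
                    S = S / peak
            out[s.name] = np.clip(1.0 - S, 0.0, None)
    return out


def run_classification_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Independent train/test pairs per replicate; kNN test error per method."""
    if cfg.task != "classification":
        raise ValueError("config task must be 'classification'")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.B)
    band_specs = [s for s in cfg.specs if s.family == "band"]
    classic_specs = [s for s in cfg.specs if s.family != "band"]
    rows = []
    for r, child in enumerate(children):
        s_train, s_test = child.spawn(2)
        train = cfg.model(cfg.n_train_per_group, s_train)
        test = cfg.model(cfg.n_test_per_group, s_test)
        k = cfg.k if cfg.k is not None else choose_k(train.X.n)
        blocks = _cross_band_dissims(train.X, test.X.values, band_specs)
        for s in classic_specs:
            blocks[s.name] = cross_dissimilarity(train.X, test.X.values, s)
        truth = np.asarray(test.labels)
        for s in cfg.specs:
            pred = knn_classify(blocks[s.name], train.labels, k)
            rows.append(
                {"replicate": r, "method": s.name,
                 "error": float(np.mean(np.asarray(pred) != truth))}
            )
    return ExperimentResult(task="classification", records=pd.DataFrame(rows))


def run_clustering_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """PAM with the true group count per replicate; error rate and ARI per method."""
    if cfg.task != "clustering":
        raise ValueError("config task must be 'clustering'")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.B)
    band_specs = [s for s in cfg.specs if s.family == "band"]
    classic_specs = [s for s in cfg.specs if s.family != "band"]
    rows = []
    for r, child in enumerate(children):
        data = cfg.model(cfg.n_per_cluster, child)
        mats = _square_band_dissims(data.X, band_specs)
        for s in classic_specs:
            mats[s.name] = classical_dissimilarity(data.X, s).values
        for s in cfg.specs:
            part = pam_cluster(mats[s.name], data.G)
            rows.append(
                {
                    "replicate": r,
                    "method": s.name,
                    "error": clustering_error(part.assignment, data.labels),
                    "ari": adjusted_rand_index(part.assignment, data.labels),
                }
            )
    return ExperimentResult(task="clustering", records=pd.DataFrame(rows))
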