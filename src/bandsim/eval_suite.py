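"""Classification and clustering harness for arbitrary dissimilarities.

kNN with a precomputed query-by-train dissimilarity block, PAM
(partitioning around medoids) and complete-linkage trees operating on a
precomputed matrix, the clustering error rate (minimum disagreement over
cluster-label permutations), the adjusted Rand index, classical distance
baselines (Euclidean / Manhattan / Minkowski / Pearson correlation), and
supervised (B/W ratio) and unsupervised (variance) gene filters with
repeated stratified cross-validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import isqrt
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedKFold

from .band_counts import ExpressionMatrix, as_expression_matrix
from .binary_indices import (
    DissimilarityMatrix,
    band_similarity_matrix,
    cross_band_similarity,
    to_dissimilarity,
)

__all__ = [
    "LabeledData",
    "DistanceSpec",
    "PartitionResult",
    "classical_dissimilarity",
    "dissimilarity_matrix",
    "cross_dissimilarity",
    "choose_k",
    "knn_classify",
    "cv_error",
    "bw_select",
    "variance_select",
    "pam_cluster",
    "complete_linkage_tree",
    "tree_to_newick",
    "clustering_error",
    "adjusted_rand_index",
]


@dataclass(frozen=True)
class LabeledData:
    """An expression matrix with one categorical label per sample."""

    X: ExpressionMatrix
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(v) for v in self.labels)
        if len(labels) != self.X.n:
            raise ValueError("one label per sample required")
        if any(not v for v in labels):
            raise ValueError("empty label")
        object.__setattr__(self, "labels", labels)

    @property
    def G(self) -> int:
        return len(set(self.labels))

    def subset(self, rows: np.ndarray) -> "LabeledData":
        rows = np.asarray(rows)
        X = ExpressionMatrix(
            self.X.values[rows],
            tuple(self.X.sample_ids[i] for i in rows),
            self.X.variable_ids,
        )
        return LabeledData(X=X, labels=tuple(self.labels[i] for i in rows))


@dataclass(frozen=True)
class DistanceSpec:
    """A dissimilarity family plus its parameters.

    ``family`` is one of ``euclidean``, ``manhattan``, ``minkowski``
    (requires ``p > 0``; applied as a formula even for p < 1),
    ``pearson`` (1 minus row-wise correlation) or ``band`` (requires
    ``coefficient``, ``J`` and optionally ``aggregation``/``reference``).
    """

    family: str
    p: float | None = None
    coefficient: str | None = None
    J: int | None = None
    aggregation: str = "coordinate-wise-average"
    reference: str = "train"

    def __post_init__(self) -> None:
        if self.family == "minkowski" and (self.p is None or self.p <= 0):
            raise ValueError("minkowski requires p > 0")
        if self.family == "band" and (self.coefficient is None or self.J is None):
            raise ValueError("band spec requires a coefficient and J")
        if self.family not in ("euclidean", "manhattan", "minkowski", "pearson", "band"):
            raise ValueError(f"unknown distance family {self.family!r}")

    @property
    def name(self) -> str:
        if self.family == "minkowski":
            return f"minkowski_p{self.p:g}"
        if self.family == "band":
            return f"{self.coefficient}_{self.J}"
        return self.family

    @classmethod
    def euclidean(cls) -> "DistanceSpec":
        return cls("euclidean")

    @classmethod
    def manhattan(cls) -> "DistanceSpec":
        return cls("manhattan")

    @classmethod
    def minkowski(cls, p: float) -> "DistanceSpec":
        return cls("minkowski", p=p)

    @classmethod
    def pearson(cls) -> "DistanceSpec":
        return cls("pearson")

    @classmethod
    def band(
        cls,
        coefficient: str,
        J: int = 2,
        aggregation: str = "coordinate-wise-average",
        reference: str = "train",
    ) -> "DistanceSpec":
        return cls("band", coefficient=coefficient, J=J, aggregation=aggregation,
                   reference=reference)


@dataclass
class PartitionResult:
    """A flat partition with optional quality measures against a ground truth."""

    assignment: np.ndarray
    medoids: tuple[int, ...] = ()
    cost: float = 0.0
    error_rate: float | None = None
    ari: float | None = None


def _values(X) -> np.ndarray:
    return as_expression_matrix(X).values


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("Pearson distance undefined for a zero-variance profile")
    return 1.0 - (Ac @ Bc.T) / np.outer(na, nb)


def _cross_classical(A: np.ndarray, B: np.ndarray, spec: DistanceSpec) -> np.ndarray:
    if spec.family == "euclidean":
        return cdist(A, B, "euclidean")
    if spec.family == "manhattan":
        return cdist(A, B, "cityblock")
    if spec.family == "minkowski":
        p = float(spec.p)
        if p >= 1:
            return cdist(A, B, "minkowski", p=p)
        # p < 1: same formula, no longer a metric; computed directly
        diff = np.abs(A[:, None, :] - B[None, :, :]) ** p
        return diff.sum(axis=2) ** (1.0 / p)
    if spec.family == "pearson":
        return _pearson_rows(A, B)
    raise ValueError(f"not a classical family: {spec.family}")


def classical_dissimilarity(X, spec: DistanceSpec) -> DissimilarityMatrix:
    """Square matrix of one of the classical distances."""
    Xm = as_expression_matrix(X)
    D = _cross_classical(Xm.values, Xm.values, spec)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(values=D, coefficient=spec.name,
                               sample_ids=Xm.sample_ids)


def dissimilarity_matrix(X, spec: DistanceSpec) -> DissimilarityMatrix:
    """Square dissimilarity under any spec, band-based or classical."""
    if spec.family == "band":
        S = band_similarity_matrix(X, spec.J, spec.coefficient, spec.aggregation)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return to_dissimilarity(S)
    return classical_dissimilarity(X, spec)


def cross_dissimilarity(train, queries, spec: DistanceSpec) -> np.ndarray:
    """|queries| x n_train dissimilarity block under any spec.

    For band specs the Forbes block is rescaled by its own maximum (a
    monotone transform, so neighbour rankings are unaffected).
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if spec.family == "band":
        S = cross_band_similarity(
            train, queries, spec.J, spec.coefficient, spec.aggregation, spec.reference
        )
        if spec.coefficient == "F":
            peak = S.max()
            if peak > 0:
                S = S / peak
        return np.clip(1.0 - S, 0.0, None)
    return _cross_classical(queries, _values(train), spec)


def choose_k(n_train: int) -> int:
    """Largest odd integer not exceeding sqrt(n_train); at least 1."""
    if n_train < 1:
        raise ValueError("need at least one training sample")
    k = isqrt(n_train)
    if k % 2 == 0:
        k -= 1
    return max(k, 1)


def knn_classify(D_block: np.ndarray, train_labels: Sequence[str], k: int) -> list[str]:
    """Majority-vote kNN on a precomputed query-by-train dissimilarity block.

    A vote tie is resolved in favour of the tied group containing the
    closest neighbour (the k = 1 rule); exact distance ties rank the
    lower training index first.
    """
    D_block = np.atleast_2d(np.asarray(D_block, dtype=float))
    train_labels = list(train_labels)
    n_train = D_block.shape[1]
    if len(train_labels) != n_train:
        raise ValueError("label count does not match block width")
    if not 1 <= k <= n_train:
        raise ValueError(f"k={k} out of range 1..{n_train}")
    order = np.argsort(D_block, axis=1, kind="stable")
    out = []
    for row in order:
        nearest = [train_labels[i] for i in row[:k]]
        counts: dict[str, int] = {}
        for lab in nearest:
            counts[lab] = counts.get(lab, 0) + 1
        top = max(counts.values())
        tied = {lab for lab, cnt in counts.items() if cnt == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            out.append(next(lab for lab in nearest if lab in tied))
    return out


def _resolve_feature_rule(feature_rule):
    if feature_rule is None or callable(feature_rule):
        return feature_rule
    kind, m = feature_rule
    if kind == "bw":
        return lambda data: bw_select(data, m)
    if kind == "variance":
        return lambda data: variance_select(data.X, m)
    raise ValueError(f"unknown feature rule {kind!r}")


def cv_error(
    data: LabeledData,
    spec: DistanceSpec,
    folds: int = 10,
    repeats: int = 1,
    feature_rule=None,
    k: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-repeat misclassification proportions of kNN under stratified K-fold CV.

    Any feature rule (e.g. ``("bw", 200)``) is re-fitted inside each
    training fold, so the selection bias of filtering on the full data
    is avoided.  Returns an array of length ``repeats``.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    labels = np.asarray(data.labels)
    _, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples, fewer than "
            f"{folds} folds; reduce the fold count"
        )
    rule = _resolve_feature_rule(feature_rule)
    n = data.X.n
    errors = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        wrong = 0
        for train_idx, test_idx in skf.split(np.zeros(n), labels):
            train = data.subset(train_idx)
            test_X = data.X.values[test_idx]
            if rule is not None:
                cols = np.asarray(rule(train))
                train = LabeledData(
                    X=ExpressionMatrix(
                        train.X.values[:, cols],
                        train.X.sample_ids,
                        tuple(train.X.variable_ids[c] for c in cols),
                    ),
                    labels=train.labels,
                )
                test_X = test_X[:, cols]
            kk = k if k is not None else choose_k(train.X.n)
            block = cross_dissimilarity(train.X, test_X, spec)
            pred = knn_classify(block, train.labels, kk)
            wrong += sum(p != t for p, t in zip(pred, labels[test_idx]))
        errors[r] = wrong / n
    return errors


def bw_select(data: LabeledData, m: int) -> np.ndarray:
    """Top-m variables by the between-to-within sums-of-squares ratio.

    Zero within-group variance with non-zero between ranks first
    (infinite ratio); an entirely constant variable (0/0) ranks last.
    Ties keep the original variable order.
    """
    X = data.X.values
    if data.G < 2:
        raise ValueError("B/W selection requires at least two classes")
    if m > X.shape[1]:
        raise ValueError("cannot select more variables than available")
    labels = np.asarray(data.labels)
    grand = X.mean(axis=0)
    B = np.zeros(X.shape[1])
    W = np.zeros(X.shape[1])
    for cls in np.unique(labels):
        block = X[labels == cls]
        mu = block.mean(axis=0)
        B += block.shape[0] * (mu - grand) ** 2
        W += ((block - mu) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(W > 0, B / np.where(W > 0, W, 1.0),
                         np.where(B > 0, np.inf, -np.inf))
    order = np.argsort(-ratio, kind="stable")
    return np.sort(order[:m])


def variance_select(X, m: int) -> np.ndarray:
    """Top-m most variable variables (unsupervised filter); ties by order."""
    values = _values(X)
    if m > values.shape[1]:
        raise ValueError("cannot select more variables than available")
    var = values.var(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:m])


def pam_cluster(D, G: int) -> PartitionResult:
    """Deterministic PAM (BUILD then SWAP) on a precomputed dissimilarity matrix.

    BUILD greedily seeds medoids by maximal cost reduction; SWAP
    repeatedly applies the single best strictly-improving
    medoid/non-medoid exchange.  All ties break toward the lowest index,
    so repeated runs are identical.
    """
    D = np.asarray(getattr(D, "values", D), dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    n = D.shape[0]
    if not 2 <= G < n:
        raise ValueError(f"number of clusters G={G} must satisfy 2 <= G < n={n}")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < G:
        candidates = np.array([i for i in range(n) if i not in medoids])
        gains = np.clip(nearest[None, :] - D[candidates], 0, None).sum(axis=1)
        best = int(candidates[int(np.argmax(gains))])
        medoids.append(best)
        nearest = np.minimum(nearest, D[best])

    # SWAP
    cost = float(np.min(D[medoids], axis=0).sum())
    while True:
        best_delta = -1e-12
        best_swap = None
        med_sorted = sorted(medoids)
        non_medoids = np.array([i for i in range(n) if i not in medoids])
        for mi in med_sorted:
            others = [m for m in med_sorted if m != mi]
            rest_min = np.min(D[others], axis=0) if others else np.full(n, np.inf)
            new_costs = np.minimum(rest_min[None, :], D[non_medoids]).sum(axis=1)
            deltas = new_costs - cost
            idx = int(np.argmin(deltas))
            if deltas[idx] < best_delta:
                best_delta = float(deltas[idx])
                best_swap = (mi, int(non_medoids[idx]))
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[medoids.index(mi)] = h
        cost = float(np.min(D[medoids], axis=0).sum())
    medoids = tuple(sorted(medoids))
    assignment = np.argmin(D[list(medoids)], axis=0)
    return PartitionResult(assignment=assignment, medoids=medoids, cost=cost)


def complete_linkage_tree(D) -> np.ndarray:
    """Agglomerative complete-linkage merge list in SciPy linkage format.

    Each of the n-1 rows is ``(left_id, right_id, height, size)`` with
    new clusters numbered n, n+1, ...; at every step the minimum-height
    pair with the lexicographically smallest (left, right) ids merges.
    """
    D = np.asarray(getattr(D, "values", D), dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    work = D.astype(float).copy()
    ids = list(range(n))
    sizes = list(np.ones(n, dtype=int))
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                h = work[active[ai], active[aj]]
                if best is None or h < best[0]:
                    best = (h, ai, aj)
        h, ai, aj = best
        i, j = active[ai], active[aj]
        Z[step] = (ids[i], ids[j], h, sizes[i] + sizes[j])
        merged = np.maximum(work[i], work[j])
        work[i] = merged
        work[:, i] = merged
        ids[i] = n + step
        sizes[i] = sizes[i] + sizes[j]
        active.pop(aj)
    return Z


def tree_to_newick(Z: np.ndarray, labels: Sequence[str] | None = None) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    n = Z.shape[0] + 1
    labels = list(labels) if labels is not None else [f"s{i + 1}" for i in range(n)]
    heights = {i: 0.0 for i in range(n)}
    texts = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        node = n + step
        texts[node] = f"({texts[a]}:{la:.10g},{texts[b]}:{lb:.10g})"
        heights[node] = h
    return texts[2 * n - 2] + ";"


def _encode(seq) -> np.ndarray:
    seq = np.asarray(seq)
    _, codes = np.unique(seq, return_inverse=True)
    return codes


def clustering_error(pred, truth) -> float:
    """Minimum disagreement proportion over permutations of cluster labels.

    Exact permutation search for at most 8 distinct labels, Hungarian
    assignment (same optimum) beyond that.
    """
    pred = _encode(pred)
    truth = _encode(truth)
    if pred.shape != truth.shape:
        raise ValueError("partitions have different lengths")
    n = pred.size
    g = max(pred.max(), truth.max()) + 1
    conf = np.zeros((g, g), dtype=int)
    np.add.at(conf, (pred, truth), 1)
    if g <= 8:
        agreement = max(
            sum(conf[i, perm[i]] for i in range(g))
            for perm in itertools.permutations(range(g))
        )
    else:
        rows, cols = linear_sum_assignment(-conf)
        agreement = int(conf[rows, cols].sum())
    return 1.0 - agreement / n


def adjusted_rand_index(pred, truth) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("partitions have different lengths")
    return float(adjusted_rand_score(truth, pred))
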