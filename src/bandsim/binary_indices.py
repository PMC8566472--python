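"""Band-based similarity coefficients for multivariate quantitative data.

For a pair of observations, a fixed coordinate ``k`` and a band size
``j``, the band-inclusion counts define a 2x2 contingency table over the
C(n, j) bands:

====  =============================================
a     bands covering the k-th coordinate of both
b     bands covering only the first
c     bands covering only the second
d     bands covering neither
====  =============================================

Eight classical binary similarity coefficients are computed from these
tables and aggregated into an n x n sample-dependent similarity matrix

    S = sum_{j=2..J} sum_{k=1..d} S_{k,j} / (d (J - 1))

(the coordinate-wise average; a pooled-tables variant that sums the d
tables before applying the coefficient is available as well).  Because
the tables only depend on within-column ranks, every such similarity is
invariant under strictly increasing transforms applied per coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .band_counts import (
    ExpressionMatrix,
    as_expression_matrix,
    binom,
    binom_table,
    column_order_stats,
    _pair_counts,
    _single_counts,
)

__all__ = [
    "COEFFICIENTS",
    "ContingencyTable",
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "contingency_table",
    "coefficient_value",
    "band_similarity_matrix",
    "band_coefficient_layers",
    "cross_band_similarity",
    "cross_band_coefficient_layers",
    "to_dissimilarity",
]

#: The closed enumeration of supported coefficients: Simple Matching,
#: Jaccard, Simpson, Forbes, Dice, Anderberg, Ochiai, Russell-Rao.
COEFFICIENTS = ("SM", "J", "S", "F", "D", "A", "O", "RR")

#: Coefficients whose self-similarity is exactly 1 (F exceeds 1 before
#: rescaling; RR's diagonal is the per-point band-coverage proportion).
UNIT_DIAGONAL = frozenset({"SM", "J", "S", "D", "A", "O"})

_CHUNK_ELEMS = 4_000_000  # soft cap on pair-table array sizes


@dataclass(frozen=True)
class ContingencyTable:
    """Band-inclusion contingency table of one sample pair at one (k, j)."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SimilarityMatrix:
    coefficient: str
    J: int
    values: np.ndarray  # (n, n), symmetric
    aggregation: str
    sample_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class DissimilarityMatrix:
    values: np.ndarray  # (n, n), symmetric, non-negative
    coefficient: str
    #: True when derived from Russell-Rao, whose self-dissimilarity is
    #: generally positive (D_RR is not reflexive).
    nonreflexive: bool = False
    sample_ids: tuple[str, ...] = ()


def _check_coefficient(c: str) -> str:
    if c not in COEFFICIENTS:
        raise ValueError(f"unknown coefficient {c!r}; expected one of {COEFFICIENTS}")
    return c


def _check_aggregation(mode: str) -> str:
    if mode not in ("coordinate-wise-average", "pooled-tables"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return mode


def contingency_table(N1: int, N2: int, Npair: int, n: int, j: int) -> ContingencyTable:
    """Assemble (a, b, c, d) from single and pair band counts.

    ``a = Npair``, ``b = N1 - a``, ``c = N2 - a``,
    ``d = C(n, j) - N1 - N2 + a``; any negative cell signals an
    inconsistent set of counts.
    """
    total = binom(n, j)
    a = int(Npair)
    b = int(N1) - a
    c = int(N2) - a
    d = total - int(N1) - int(N2) + a
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"inconsistent band counts N1={N1}, N2={N2}, Npair={Npair} for "
            f"C({n},{j})={total}: cells ({a},{b},{c},{d})"
        )
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _coefficient_array(a, b, c, d, coefficient: str):
    """Vectorised coefficient on (a, b, c, d) float arrays.

    A denominator of zero (possible only for out-of-sample queries,
    where it forces a = 0) yields 0, the a -> 0 limit of each formula.
    """
    total = a + b + c + d
    if coefficient == "SM":
        return (a + d) / total
    if coefficient == "RR":
        return a / total
    if coefficient == "J":
        den = a + b + c
    elif coefficient == "S":
        den = np.minimum(a + b, a + c)
    elif coefficient == "F":
        den = (a + b) * (a + c)
    elif coefficient == "D":
        den = 2 * a + b + c
        a = 2 * a
    elif coefficient == "A":
        den = a + 2 * (b + c)
    elif coefficient == "O":
        den = np.sqrt((a + b) * (a + c))
    else:  # pragma: no cover
        raise ValueError(coefficient)
    num = a * total if coefficient == "F" else a
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def coefficient_value(t: ContingencyTable, c: str) -> float:
    """One similarity coefficient evaluated on one contingency table."""
    _check_coefficient(c)
    val = _coefficient_array(
        np.float64(t.a), np.float64(t.b), np.float64(t.c), np.float64(t.d), c
    )
    return float(val)


def _validate_cells(b, c, d) -> None:
    if b.size and (b.min() < 0 or c.min() < 0 or d.min() < 0):
        raise ValueError("negative contingency cell: inconsistent band counts upstream")


def band_coefficient_layers(
    Y,
    J: int,
    coefficients=COEFFICIENTS,
    aggregation: str = "coordinate-wise-average",
) -> dict[str, np.ndarray]:
    """Per-band-size similarity layers for several coefficients at once.

    Returns ``{coefficient: array of shape (J-1, n, n)}`` where layer
    ``j-2`` holds the aggregated coordinate-level coefficient for band
    size ``j``.  The J-aggregated similarity for any ``2 <= J' <= J`` is
    the mean of the first ``J'-1`` layers, so one pass serves every
    smaller J.  Sharing the contingency tables across coefficients is
    what makes sweeping several indices affordable.
    """
    Y = as_expression_matrix(Y)
    aggregation = _check_aggregation(aggregation)
    coefficients = tuple(_check_coefficient(c) for c in coefficients)
    n, d = Y.n, Y.d
    if not 2 <= J <= n:
        raise ValueError(f"J={J} must satisfy 2 <= J <= n={n}")
    stats = column_order_stats(Y)
    L, E = stats.l, stats.eta
    iu, ju = np.triu_indices(n, 1)
    n_pairs = iu.size
    chunk = max(1, _CHUNK_ELEMS // max(d, 1))
    layers = {c: np.empty((J - 1, n, n)) for c in coefficients}
    for j in range(2, J + 1):
        T = binom_table(n, j)
        total = float(T[n])
        N = _single_counts(L, E, n, j, T)
        pair_vals = {c: np.empty(n_pairs) for c in coefficients}
        for start in range(0, n_pairs, chunk):
            sl = slice(start, start + chunk)
            i1, i2 = iu[sl], ju[sl]
            a = _pair_counts(L[i1], E[i1], L[i2], E[i2], n, j, T).astype(float)
            N1 = N[i1].astype(float)
            N2 = N[i2].astype(float)
            b = N1 - a
            c_ = N2 - a
            dd = total - N1 - N2 + a
            _validate_cells(b, c_, dd)
            if aggregation == "coordinate-wise-average":
                for cf in coefficients:
                    pair_vals[cf][sl] = _coefficient_array(a, b, c_, dd, cf).mean(axis=1)
            else:
                A, B, C, D = a.sum(axis=1), b.sum(axis=1), c_.sum(axis=1), dd.sum(axis=1)
                for cf in coefficients:
                    pair_vals[cf][sl] = _coefficient_array(A, B, C, D, cf)
        # self pairs: a = N, b = c = 0, d = C(n,j) - N
        aD = N.astype(float)
        zero = np.zeros_like(aD)
        dD = total - aD
        for cf in coefficients:
            if aggregation == "coordinate-wise-average":
                diag = _coefficient_array(aD, zero, zero, dD, cf).mean(axis=1)
            else:
                diag = _coefficient_array(
                    aD.sum(axis=1), 0.0, 0.0, dD.sum(axis=1), cf
                )
            layer = np.empty((n, n))
            layer[iu, ju] = pair_vals[cf]
            layer[ju, iu] = pair_vals[cf]
            layer[np.arange(n), np.arange(n)] = diag
            layers[cf][j - 2] = layer
    return layers


def band_similarity_matrix(
    Y,
    J: int,
    c: str = "S",
    aggregation: str = "coordinate-wise-average",
) -> SimilarityMatrix:
    """The n x n band-based similarity matrix for one coefficient."""
    Y = as_expression_matrix(Y)
    layers = band_coefficient_layers(Y, J, (c,), aggregation)[c]
    return SimilarityMatrix(
        coefficient=c,
        J=J,
        values=layers.mean(axis=0),
        aggregation=aggregation,
        sample_ids=Y.sample_ids,
    )


def cross_band_coefficient_layers(
    train,
    queries,
    J: int,
    coefficients=COEFFICIENTS,
    aggregation: str = "coordinate-wise-average",
    reference: str = "train",
) -> dict[str, np.ndarray]:
    """Query-by-train similarity layers, shaped (J-1, q, n_train) per coefficient.

    With ``reference="train"`` (inductive, the default) bands are formed
    from the training sample only and query coordinates are located with
    out-of-sample (l, eta) statistics, where eta may be 0.  With
    ``reference="pooled"`` (transductive) bands come from the union of
    training and query rows.
    """
    train = as_expression_matrix(train)
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != train.d:
        raise ValueError(f"queries have {Q.shape[1]} columns, train has {train.d}")
    aggregation = _check_aggregation(aggregation)
    coefficients = tuple(_check_coefficient(c) for c in coefficients)
    if reference == "train":
        stats = column_order_stats(train)
    elif reference == "pooled":
        stats = column_order_stats(np.vstack([train.values, Q]))
    else:
        raise ValueError(f"unknown band reference {reference!r}")
    n_ref, d = stats.n, train.d
    if not 2 <= J <= n_ref:
        raise ValueError(f"J={J} must satisfy 2 <= J <= {n_ref}")
    Lt, Et = stats.locate(train.values)
    Lq, Eq = stats.locate(Q)
    q, nt = Q.shape[0], train.n
    chunk = max(1, _CHUNK_ELEMS // max(nt * d, 1))
    layers = {c: np.empty((J - 1, q, nt)) for c in coefficients}
    for j in range(2, J + 1):
        T = binom_table(n_ref, j)
        total = float(T[n_ref])
        Nt = _single_counts(Lt, Et, n_ref, j, T).astype(float)  # (nt, d)
        Nq = _single_counts(Lq, Eq, n_ref, j, T).astype(float)  # (q, d)
        for start in range(0, q, chunk):
            sl = slice(start, start + chunk)
            a = _pair_counts(
                Lq[sl][:, None, :],
                Eq[sl][:, None, :],
                Lt[None, :, :],
                Et[None, :, :],
                n_ref,
                j,
                T,
            ).astype(float)  # (q_chunk, nt, d)
            b = Nq[sl][:, None, :] - a
            c_ = Nt[None, :, :] - a
            dd = total - Nq[sl][:, None, :] - Nt[None, :, :] + a
            _validate_cells(b, c_, dd)
            if aggregation == "coordinate-wise-average":
                for cf in coefficients:
                    layers[cf][j - 2, sl] = _coefficient_array(a, b, c_, dd, cf).mean(
                        axis=2
                    )
            else:
                A, B, C, D = (x.sum(axis=2) for x in (a, b, c_, dd))
                for cf in coefficients:
                    layers[cf][j - 2, sl] = _coefficient_array(A, B, C, D, cf)
    return layers


def cross_band_similarity(
    train,
    queries,
    J: int,
    c: str = "S",
    aggregation: str = "coordinate-wise-average",
    reference: str = "train",
) -> np.ndarray:
    """Rectangular |queries| x n_train band similarity block."""
    layers = cross_band_coefficient_layers(
        train, queries, J, (c,), aggregation, reference
    )[c]
    return layers.mean(axis=0)


def to_dissimilarity(S: SimilarityMatrix) -> DissimilarityMatrix:
    """Convert a similarity matrix to a dissimilarity via D = 1 - S.

    Forbes is unbounded above, so its matrix is first rescaled by its
    maximum entry (mapping it into [0, 1]); Russell-Rao yields a
    non-reflexive dissimilarity (positive diagonal), which is flagged
    and warned about rather than rejected.
    """
    values = S.values
    if S.coefficient == "F":
        peak = values.max()
        if peak > 0:
            values = values / peak
    D = np.clip(1.0 - values, 0.0, None)
    nonreflexive = S.coefficient == "RR"
    if nonreflexive and np.any(np.diag(D) > 0):
        warnings.warn(
            "Russell-Rao dissimilarity is not reflexive: the diagonal is positive",
            UserWarning,
            stacklevel=2,
        )
    return DissimilarityMatrix(
        values=D,
        coefficient=S.coefficient,
        nonreflexive=nonreflexive,
        sample_ids=S.sample_ids,
    )
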