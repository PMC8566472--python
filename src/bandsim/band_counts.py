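"""Exact combinatorial band-inclusion counts and Modified Band Depth.

A *j-band* of a sample of ``n`` d-dimensional observations is the
coordinate-wise interval spanned by ``j`` distinct observations.  The
Modified Band Depth (MBD) of a point averages, over all bands with
``2 <= j <= J`` and over coordinates, the indicator that the point's
coordinate falls inside the band's interval.  Enumerating the
``C(n, j)`` bands is exponential in ``j``; this module instead uses the
order statistics of each column — the 1-based rank ``l`` of the first
occurrence of a value in the sorted column and its multiplicity
``eta`` — to obtain every count in closed form:

* single point (complement principle)::

      N_k(y) = C(n,j) - C(l-1, j) - C(n-l-eta+1, j)

* pair of points (inclusion-exclusion), with ``m``/``M`` the smaller and
  larger of the two k-th coordinates::

      N_k(y1, y2) = C(n,j) - C(l_M-1, j) - C(n-l_m-eta_m+1, j)
                    + C(l_M-l_m-eta_m, j)

  where the last term vanishes when the coordinates coincide.

All binomial coefficients use exact integer arithmetic; floats only
appear in the final depth ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "ColumnOrderStats",
    "BandCountProfile",
    "PairBandCounts",
    "DepthVector",
    "binom",
    "binom_table",
    "column_order_stats",
    "count_bands_single",
    "count_bands_pair",
    "mbd",
    "mbd2_closed_form",
]

# Largest band count that is guaranteed exact in an int64 table.
_INT64_SAFE = 2**62


@dataclass(frozen=True)
class ExpressionMatrix:
    """A numeric data matrix with samples in rows and variables in columns."""

    values: np.ndarray
    sample_ids: tuple[str, ...] = ()
    variable_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        n, d = values.shape
        if n < 2 or d < 1:
            raise ValueError(f"need at least 2 samples and 1 variable, got {n}x{d}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite entry at sample {r}, variable {c} "
                f"({len(bad)} offending cell(s) in total)"
            )
        object.__setattr__(self, "values", values)
        sample_ids = tuple(self.sample_ids) or tuple(f"s{i + 1}" for i in range(n))
        variable_ids = tuple(self.variable_ids) or tuple(f"v{k + 1}" for k in range(d))
        if len(sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(variable_ids) != d:
            raise ValueError("variable_ids length does not match number of columns")
        if len(set(sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(variable_ids)) != d:
            raise ValueError("duplicate variable ids")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "variable_ids", variable_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def as_expression_matrix(Y) -> ExpressionMatrix:
    """Coerce an array-like or ExpressionMatrix into an ExpressionMatrix."""
    if isinstance(Y, ExpressionMatrix):
        return Y
    return ExpressionMatrix(np.asarray(Y, dtype=float))


def binom(alpha: int, j: int) -> int:
    """Exact binomial coefficient with the convention C(alpha, j) = 0 for alpha < j.

    Both arguments must be non-negative integers; arbitrary-precision
    integer arithmetic is used throughout, so no overflow occurs.
    """
    if alpha < 0 or j < 0:
        raise ValueError(f"binom requires non-negative arguments, got ({alpha}, {j})")
    if alpha < j:
        return 0
    return math.comb(int(alpha), int(j))


def binom_table(n: int, j: int) -> np.ndarray:
    """Lookup table ``T[alpha] = C(alpha, j)`` for ``alpha`` in 0..n.

    Returned as int64 when every entry fits exactly, otherwise float64
    (entries above 2^62 lose the trailing bits but the relative error is
    at machine precision, which only ever enters final depth/similarity
    ratios).
    """
    vals = [binom(a, j) for a in range(n + 1)]
    if vals[-1] < _INT64_SAFE:
        return np.array(vals, dtype=np.int64)
    return np.array(vals, dtype=np.float64)


@dataclass(frozen=True)
class ColumnOrderStats:
    """Per-column order statistics of a sample: the engine of all band counts.

    For every sample value this records ``l`` (1-based rank of the first
    occurrence of the value in the ascending sorted column) and ``eta``
    (its multiplicity).  Arbitrary out-of-sample values can be located
    with :meth:`locate`, where ``l = 1 + #(column values < v)`` and
    ``eta = #(column values == v)`` (possibly zero).
    """

    sorted_columns: np.ndarray  # (n, d), each column ascending
    l: np.ndarray  # (n, d) int64, 1-based first-occurrence ranks of the sample
    eta: np.ndarray  # (n, d) int64, multiplicities of the sample values

    @property
    def n(self) -> int:
        return self.sorted_columns.shape[0]

    @property
    def d(self) -> int:
        return self.sorted_columns.shape[1]

    def locate(self, V) -> tuple[np.ndarray, np.ndarray]:
        """Return (l, eta) arrays for arbitrary query rows ``V`` (q x d)."""
        V = np.atleast_2d(np.asarray(V, dtype=float))
        if V.shape[1] != self.d:
            raise ValueError(f"query has {V.shape[1]} columns, expected {self.d}")
        if not np.all(np.isfinite(V)):
            raise ValueError("non-finite query values")
        q = V.shape[0]
        L = np.empty((q, self.d), dtype=np.int64)
        R = np.empty((q, self.d), dtype=np.int64)
        for k in range(self.d):
            col = self.sorted_columns[:, k]
            lo = np.searchsorted(col, V[:, k], side="left")
            hi = np.searchsorted(col, V[:, k], side="right")
            L[:, k] = lo + 1
            R[:, k] = hi - lo
        return L, R


def column_order_stats(Y) -> ColumnOrderStats:
    """Sort each column and record (l, eta) for every in-sample value."""
    Y = as_expression_matrix(Y)
    sorted_cols = np.sort(Y.values, axis=0)
    stats = ColumnOrderStats(sorted_columns=sorted_cols, l=None, eta=None)  # type: ignore[arg-type]
    L, E = stats.locate(Y.values)
    object.__setattr__(stats, "l", L)
    object.__setattr__(stats, "eta", E)
    return stats


@dataclass(frozen=True)
class BandCountProfile:
    """Per-coordinate counts N^(j)_k(y) of j-bands covering one point."""

    j: int
    counts: np.ndarray  # length d


@dataclass(frozen=True)
class PairBandCounts:
    """Per-coordinate counts N^(j)_k(y1, y2) of j-bands covering both points."""

    j: int
    counts: np.ndarray  # length d


@dataclass(frozen=True)
class DepthVector:
    """MBD values of every sample point, for bands of size 2..J."""

    J: int
    depths: np.ndarray  # length n


def _check_j(j: int, n: int) -> None:
    if not 2 <= j <= n:
        raise ValueError(f"band size j={j} must satisfy 2 <= j <= n={n}")


def _single_counts(L: np.ndarray, E: np.ndarray, n: int, j: int, T: np.ndarray):
    """Vectorised complement principle: N = C(n,j) - C(l-1,j) - C(n-l-eta+1,j)."""
    total = T[n]
    return total - T[L - 1] - T[n - L - E + 1]


def _pair_counts(
    L1: np.ndarray,
    E1: np.ndarray,
    L2: np.ndarray,
    E2: np.ndarray,
    n: int,
    j: int,
    T: np.ndarray,
):
    """Vectorised inclusion-exclusion count of bands covering both coordinates.

    The correction term C(l_M - l_m - eta_m, j) counts bands formed
    entirely from values strictly between the two coordinates; when the
    coordinates coincide the clipped index is negative, the term is zero
    and the formula degenerates to the single-point one.
    """
    lm = np.minimum(L1, L2)
    lM = np.maximum(L1, L2)
    em = np.where(L1 <= L2, E1, E2)
    between = np.clip(lM - lm - em, 0, None)
    return T[n] - T[lM - 1] - T[n - lm - em + 1] + T[between]


def count_bands_single(stats: ColumnOrderStats, point, j: int) -> BandCountProfile:
    """Number of j-bands whose k-th interval contains the point's k-th coordinate."""
    _check_j(j, stats.n)
    L, E = stats.locate(point)
    T = binom_table(stats.n, j)
    counts = _single_counts(L, E, stats.n, j, T)
    return BandCountProfile(j=j, counts=counts[0] if counts.shape[0] == 1 else counts)


def count_bands_pair(stats: ColumnOrderStats, v1, v2, j: int) -> PairBandCounts:
    """Number of j-bands whose k-th interval contains both points' k-th coordinates."""
    _check_j(j, stats.n)
    L1, E1 = stats.locate(v1)
    L2, E2 = stats.locate(v2)
    T = binom_table(stats.n, j)
    counts = _pair_counts(L1, E1, L2, E2, stats.n, j, T)
    return PairBandCounts(j=j, counts=counts[0] if counts.shape[0] == 1 else counts)


def mbd(Y, J: int) -> DepthVector:
    """Modified Band Depth MBD_{n,J} of every sample point.

    ``depths[i] = sum_{j=2..J} (1 / (d C(n,j))) sum_k N^(j)_k(y_i)``,
    computed from the closed-form counts; cost is linear in J.
    """
    Y = as_expression_matrix(Y)
    _check_j(J, Y.n)
    stats = column_order_stats(Y)
    n, d = Y.n, Y.d
    depths = np.zeros(n, dtype=float)
    for j in range(2, J + 1):
        T = binom_table(n, j)
        N = _single_counts(stats.l, stats.eta, n, j, T)
        depths += N.sum(axis=1).astype(float) / (d * float(T[n]))
    return DepthVector(J=J, depths=depths)


def mbd2_closed_form(Y) -> DepthVector:
    """MBD_{n,2} via the direct rank/multiplicity closed form.

    ``depth_i = (1/(d C(n,2))) sum_k [(n-l+1)(l-1+eta) - eta^2 + C(eta,2)]``.
    """
    Y = as_expression_matrix(Y)
    n, d = Y.n, Y.d
    stats = column_order_stats(Y)
    L = stats.l.astype(np.int64)
    E = stats.eta.astype(np.int64)
    term = (n - L + 1) * (L - 1 + E) - E * E + E * (E - 1) // 2
    total = n * (n - 1) // 2
    depths = term.sum(axis=1).astype(float) / (d * float(total))
    return DepthVector(J=2, depths=depths)
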