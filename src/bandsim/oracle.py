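"""Brute-force band enumeration: the reference the fast closed forms are tested against.

Everything here materialises the exponentially large objects the main
implementation avoids: the list of all C(n, j) bands, the binary
inclusion matrices, and their Boolean products.  A hard cap on C(n, j)
keeps accidental misuse from exhausting memory — this module exists for
verification on small instances only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .band_counts import as_expression_matrix, binom

__all__ = ["BandMatrix", "enumerate_bands", "band_matrix", "boolean_product", "naive_mbd"]

DEFAULT_CAP = 10_000


@dataclass(frozen=True)
class BandMatrix:
    """Binary inclusion matrix of one observation: C(n,j) bands x d coordinates."""

    j: int
    matrix: np.ndarray  # (C(n,j), d) of {0, 1}


def enumerate_bands(Y, j: int, cap: int = DEFAULT_CAP):
    """All j-element index tuples in lexicographic order, with min/max envelopes.

    Returns a list of ``(indices, mins, maxs)`` where ``mins``/``maxs``
    are the coordinate-wise envelope of the band.
    """
    Y = as_expression_matrix(Y)
    n = Y.n
    if not 2 <= j <= n:
        raise ValueError(f"band size j={j} must satisfy 2 <= j <= n={n}")
    n_bands = binom(n, j)
    if n_bands > cap:
        raise ValueError(
            f"C({n},{j}) = {n_bands} bands exceeds the oracle cap of {cap}"
        )
    out = []
    for idx in combinations(range(n), j):
        block = Y.values[list(idx), :]
        out.append((idx, block.min(axis=0), block.max(axis=0)))
    return out


def band_matrix(Y, point, j: int, cap: int = DEFAULT_CAP) -> BandMatrix:
    """Explicit C(n,j) x d binary matrix of band inclusions for one point."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    bands = enumerate_bands(Y, j, cap=cap)
    rows = [((mins <= point) & (point <= maxs)).astype(np.int8) for _, mins, maxs in bands]
    return BandMatrix(j=j, matrix=np.array(rows, dtype=np.int8))


def boolean_product(M1: BandMatrix, M2: BandMatrix) -> BandMatrix:
    """Entrywise Boolean AND of two inclusion matrices (same band list)."""
    if M1.j != M2.j or M1.matrix.shape != M2.matrix.shape:
        raise ValueError("band matrices are not conformable")
    return BandMatrix(j=M1.j, matrix=(M1.matrix & M2.matrix).astype(np.int8))


def naive_mbd(Y, J: int, cap: int = DEFAULT_CAP) -> np.ndarray:
    """MBD by direct double summation over enumerated bands and coordinates."""
    Y = as_expression_matrix(Y)
    n, d = Y.n, Y.d
    if not 2 <= J <= n:
        raise ValueError(f"J={J} must satisfy 2 <= J <= n={n}")
    depths = np.zeros(n, dtype=float)
    for j in range(2, J + 1):
        n_bands = binom(n, j)
        for i in range(n):
            M = band_matrix(Y, Y.values[i], j, cap=cap)
            depths[i] += M.matrix.sum() / (d * n_bands)
    return depths
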