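"""Shared fixtures and independent brute-force references.

The naive implementations here enumerate every band explicitly and
re-state the coefficient formulas in plain Python, so they share no code
path with the closed-form implementation they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest


def naive_single_count(column: np.ndarray, value: float, j: int) -> int:
    """Bands (j-subsets) of a column whose [min, max] contains the value."""
    return sum(
        1
        for idx in combinations(range(len(column)), j)
        if min(column[i] for i in idx) <= value <= max(column[i] for i in idx)
    )


def naive_pair_count(column: np.ndarray, v1: float, v2: float, j: int) -> int:
    return sum(
        1
        for idx in combinations(range(len(column)), j)
        if min(column[i] for i in idx) <= min(v1, v2)
        and max(v1, v2) <= max(column[i] for i in idx)
    )


def naive_coefficient(a: float, b: float, c: float, d: float, name: str) -> float:
    n = a + b + c + d
    if name == "SM":
        return (a + d) / n
    if name == "RR":
        return a / n
    if name == "J":
        den = a + b + c
    elif name == "S":
        den = min(a + b, a + c)
    elif name == "F":
        den = (a + b) * (a + c)
    elif name == "D":
        den = 2 * a + b + c
    elif name == "A":
        den = a + 2 * (b + c)
    elif name == "O":
        den = math.sqrt((a + b) * (a + c))
    else:
        raise ValueError(name)
    if den == 0:
        return 0.0
    num = a * n if name == "F" else (2 * a if name == "D" else a)
    return num / den


def naive_band_similarity(Y: np.ndarray, J: int, name: str, aggregation: str) -> np.ndarray:
    """Full similarity matrix via explicit band enumeration."""
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    S = np.zeros((n, n))
    for i1 in range(n):
        for i2 in range(i1, n):
            acc = 0.0
            for j in range(2, J + 1):
                total = math.comb(n, j)
                tables = []
                for k in range(d):
                    N1 = naive_single_count(Y[:, k], Y[i1, k], j)
                    N2 = naive_single_count(Y[:, k], Y[i2, k], j)
                    a = naive_pair_count(Y[:, k], Y[i1, k], Y[i2, k], j)
                    tables.append((a, N1 - a, N2 - a, total - N1 - N2 + a))
                if aggregation == "coordinate-wise-average":
                    acc += sum(naive_coefficient(*t, name) for t in tables) / d
                else:
                    pooled = tuple(sum(t[q] for t in tables) for q in range(4))
                    acc += naive_coefficient(*pooled, name)
            S[i1, i2] = S[i2, i1] = acc / (J - 1)
    return S


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fig1_column():
    """A 4-observation column reproducing the worked toy configuration:

    6 two-bands in total; 3 contain the first point's coordinate, 5
    contain the third point's, and 2 contain both.
    """
    return np.array([[5.0], [1.0], [2.0], [3.0]])
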