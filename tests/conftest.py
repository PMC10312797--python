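"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nmfcc import FactorPair, LabeledMatrix

EPS = 1e-16


def naive_update_step(V: np.ndarray, W: np.ndarray, H: np.ndarray):
    """Triple-loop reference implementation of the multiplicative updates.

    Written element by element, independent of the vectorized kernel,
    with the same epsilon floors: H first, WH recomputed, then W.
    """
    V = np.asarray(V, float)
    n, m = V.shape
    k = W.shape[1]
    W = W.copy().astype(float)
    H = H.copy().astype(float)

    WH = np.empty((n, m))
    for i in range(n):
        for u in range(m):
            s = 0.0
            for a in range(k):
                s += W[i, a] * H[a, u]
            WH[i, u] = max(s, EPS)

    H_new = np.empty_like(H)
    for a in range(k):
        denom = 0.0
        for i in range(n):
            denom += W[i, a]
        denom = max(denom, EPS)
        for u in range(m):
            numer = 0.0
            for i in range(n):
                numer += W[i, a] * V[i, u] / WH[i, u]
            H_new[a, u] = max(H[a, u] * numer / denom, EPS)
    H = H_new

    for i in range(n):
        for u in range(m):
            s = 0.0
            for a in range(k):
                s += W[i, a] * H[a, u]
            WH[i, u] = max(s, EPS)

    W_new = np.empty_like(W)
    for a in range(k):
        denom = 0.0
        for u in range(m):
            denom += H[a, u]
        denom = max(denom, EPS)
        for i in range(n):
            numer = 0.0
            for u in range(m):
                numer += H[a, u] * V[i, u] / WH[i, u]
            W_new[i, a] = max(W[i, a] * numer / denom, EPS)

    return W_new, H


def random_factors(n: int, m: int, k: int, rng: np.random.Generator) -> FactorPair:
    return FactorPair(W=rng.random((n, k)) + 0.1, H=rng.random((k, m)) + 0.1)


def block_consensus(block_sizes: list[int]) -> np.ndarray:
    """Perfect 0/1 consensus matrix with the given contiguous blocks."""
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    return (labels[:, None] == labels[None, :]).astype(float)


@pytest.fixture
def small_labeled_matrix() -> LabeledMatrix:
    return LabeledMatrix(
        values=[[1.0, 0.0, 2.0], [3.0, 1.0, 0.5]],
        row_names=["g1", "g2"],
        column_names=["S1", "S2", "S3"],
        row_descriptions=["d1", "d2"],
    )
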