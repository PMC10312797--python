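"""Single-run NMF with KL-divergence multiplicative updates.

The factorization V ~ W H minimizes the generalized Kullback-Leibler
divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by the classical multiplicative updates: H first,

    H_au <- H_au * ( sum_i W_ia V_iu / (WH)_iu ) / ( sum_i W_ia ),

then, with WH recomputed, W,

    W_ia <- W_ia * ( sum_u H_au V_iu / (WH)_iu ) / ( sum_u H_au ).

Each sample is assigned to its dominant metagene (argmax of its H
column) and a run's clustering is summarized in a binary connectivity
matrix.  Convergence is declared when the connectivity matrix stops
changing for a configured number of consecutive checks, when the
divergence change between checks drops below a tolerance, or when the
iteration cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig

#: Floor applied to WH products, update denominators and factor entries.
#: Keeps every multiplicative ratio finite without perturbing well-scaled
#: problems.
EPS = 1e-16

#: Convergence causes recorded on :class:`NmfRunResult`.
STOP_NO_CHANGE = "no-change checks"
STOP_DIVERGENCE = "divergence delta"
STOP_MAX_ITER = "max iterations"

__all__ = [
    "EPS",
    "STOP_NO_CHANGE",
    "STOP_DIVERGENCE",
    "STOP_MAX_ITER",
    "RankError",
    "FactorPair",
    "ConnectivityMatrix",
    "NmfRunResult",
    "initialize_factors",
    "kl_divergence",
    "update_step",
    "assign_clusters",
    "connectivity_from_labels",
    "run_nmf",
]


class RankError(ValueError):
    """Requested rank exceeds the smaller matrix dimension."""


@dataclass
class FactorPair:
    """Non-negative factors W (n_rows x k) and H (k x n_cols)."""

    W: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2:
            raise ValueError("W and H must be 2-D")
        if self.W.shape[1] != self.H.shape[0]:
            raise ValueError(
                f"inner dimensions disagree: W is {self.W.shape}, H is {self.H.shape}"
            )

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def product(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ConnectivityMatrix:
    """Binary samples x samples co-membership matrix of one run."""

    values: np.ndarray
    sample_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.sample_names)
        if self.values.shape != (n, n):
            raise ValueError(
                f"connectivity shape {self.values.shape} does not match "
                f"{n} sample names"
            )


@dataclass
class NmfRunResult:
    """Complete record of a single NMF run."""

    factors: FactorPair
    assignment: np.ndarray
    connectivity: ConnectivityMatrix
    iterations_run: int
    divergence_trace: list[tuple[int, float]] = field(default_factory=list)
    converged: str = STOP_MAX_ITER


def initialize_factors(
    n_rows: int, n_cols: int, k: int, seed: int
) -> FactorPair:
    """Draw W and H i.i.d. uniform on (0, 1), reproducibly from ``seed``."""
    if n_rows < 1 or n_cols < 1 or k < 1:
        raise ValueError("dimensions and rank must be >= 1")
    if k > min(n_rows, n_cols):
        raise RankError(
            f"rank {k} exceeds min(n_rows, n_cols) = {min(n_rows, n_cols)}"
        )
    rng = np.random.default_rng(seed)
    W = rng.random((n_rows, k))
    H = rng.random((k, n_cols))
    return FactorPair(W=W, H=H)


def kl_divergence(V: np.ndarray, factors: FactorPair) -> float:
    """Generalized KL divergence D(V || WH), with the 0 log 0 = 0 convention."""
    V = np.asarray(V, dtype=float)
    WH = np.maximum(factors.product(), EPS)
    pos = V > 0
    log_term = np.zeros_like(V)
    log_term[pos] = V[pos] * np.log(V[pos] / WH[pos])
    return float(np.sum(log_term - V + WH))


def update_step(V: np.ndarray, factors: FactorPair) -> FactorPair:
    """One multiplicative update of H then W; KL divergence never increases."""
    V = np.asarray(V, dtype=float)
    W, H = factors.W, factors.H
    WH = np.maximum(W @ H, EPS)
    H = H * (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], EPS)
    H = np.maximum(H, EPS)
    WH = np.maximum(W @ H, EPS)
    W = W * ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
    W = np.maximum(W, EPS)
    return FactorPair(W=W, H=H)


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Label each sample with its dominant metagene (ties -> smallest index)."""
    H = np.asarray(H)
    return np.argmax(H, axis=0)


def connectivity_from_labels(
    labels: np.ndarray, sample_names: list[str] | None = None
) -> ConnectivityMatrix:
    """Binary matrix with entry (i, j) = 1 iff samples i and j share a label."""
    labels = np.asarray(labels)
    values = (labels[:, None] == labels[None, :]).astype(np.uint8)
    if sample_names is None:
        sample_names = [str(i) for i in range(len(labels))]
    return ConnectivityMatrix(values=values, sample_names=sample_names)


def run_nmf(
    V: np.ndarray,
    k: int,
    config: RunConfig,
    seed: int,
    sample_names: list[str] | None = None,
    step=update_step,
) -> NmfRunResult:
    """Run one NMF factorization to convergence.

    Every ``config.stop_frequency`` iterations the sample assignment,
    connectivity matrix and KL divergence are evaluated.  The run stops
    when the connectivity matrix has been unchanged for
    ``config.stop_convergence`` consecutive checks, when the absolute
    divergence change between consecutive checks falls below
    ``config.max_error_difference``, or at ``config.max_iterations`` —
    whichever fires first.

    ``step`` is the update kernel; the scheduler substitutes a
    block-parallel kernel under the input-matrix strategy.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("input matrix has negative entries")
    n_rows, n_cols = V.shape
    if sample_names is None:
        sample_names = [str(j) for j in range(n_cols)]
    factors = initialize_factors(n_rows, n_cols, k, seed)

    trace: list[tuple[int, float]] = []
    prev_conn: np.ndarray | None = None
    prev_div: float | None = None
    unchanged = 0
    cause = STOP_MAX_ITER
    iterations = 0

    for it in range(1, config.max_iterations + 1):
        factors = step(V, factors)
        iterations = it
        if it % config.stop_frequency != 0:
            continue
        labels = assign_clusters(factors.H)
        conn = (labels[:, None] == labels[None, :]).astype(np.uint8)
        div = kl_divergence(V, factors)
        trace.append((it, div))
        if prev_conn is not None and np.array_equal(conn, prev_conn):
            unchanged += 1
        else:
            unchanged = 0
        if unchanged >= config.stop_convergence:
            cause = STOP_NO_CHANGE
            break
        if (
            prev_div is not None
            and abs(div - prev_div) < config.max_error_difference
        ):
            cause = STOP_DIVERGENCE
            break
        prev_conn, prev_div = conn, div

    labels = assign_clusters(factors.H)
    connectivity = connectivity_from_labels(labels, sample_names)
    return NmfRunResult(
        factors=factors,
        assignment=labels,
        connectivity=connectivity,
        iterations_run=iterations,
        divergence_trace=trace,
        converged=cause,
    )
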