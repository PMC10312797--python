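"""Execution of the (k range x restarts) run grid under three strategies.

* ``serial`` — every run on a single worker, in (k, run) order.
* ``kfactor`` — all restarts for one k are assigned wholly to one
  worker; k values are spread greedily so total task counts balance.
* ``input-matrix`` — all workers cooperate on every run: the data
  matrix is partitioned into column blocks for the H update and row
  blocks for the W update, each worker computes the update only for its
  block, and the partial factors are exchanged so all workers hold
  identical complete copies.  This is the strategy that lets matrices
  larger than one device's memory be factorized.

Because per-run seeds are derived as ``base_seed + 10000*k + run_index``,
every strategy reproduces the same sequence of runs; serial and kfactor
results are bitwise identical, and input-matrix agrees to reduction-order
tolerance.

The worker backend is a minimal abstraction — broadcast a matrix to all
workers and sum-reduce partial matrices across workers — so the same
scheduler drives an in-process backend or a message-passing one.  This
package ships :class:`SimulatedBackend`, which executes the workers'
block computations within one process while enforcing the same exchange
contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .consensus import (
    ConsensusMatrix,
    StabilityRecord,
    StabilityReport,
    build_consensus,
    cophenetic_coefficient,
    select_k,
)
from .gct import LabeledMatrix
from .nmf import FactorPair, NmfRunResult, RankError, run_nmf, update_step, EPS

#: assigned_worker value meaning "all workers jointly" (input-matrix strategy).
ALL_WORKERS = -1

__all__ = [
    "ALL_WORKERS",
    "Task",
    "TaskPlan",
    "PartitionError",
    "SynchronizationError",
    "RunFailure",
    "WorkerBackend",
    "SimulatedBackend",
    "plan_tasks",
    "partition_rows",
    "blocked_update_step",
    "run_all",
]


class PartitionError(ValueError):
    """More workers than rows to partition."""


class SynchronizationError(RuntimeError):
    """Workers hold inconsistent factor copies after an exchange."""


class RunFailure(RuntimeError):
    """A single NMF run failed; names (k, run_index, seed)."""

    def __init__(self, k: int, run_index: int, seed: int, cause: Exception):
        super().__init__(
            f"NMF run failed at k={k}, run_index={run_index}, seed={seed}: {cause}"
        )
        self.k = k
        self.run_index = run_index
        self.seed = seed
        self.cause = cause


@dataclass(frozen=True)
class Task:
    k: int
    run_index: int
    assigned_worker: int  # ALL_WORKERS under input-matrix
    seed: int


@dataclass
class TaskPlan:
    tasks: list[Task]
    strategy: str


def plan_tasks(config: RunConfig, n_rows: int, n_cols: int) -> TaskPlan:
    """Lay out every (k, run_index) on workers according to the strategy."""
    if config.k_max > min(n_rows, n_cols):
        raise RankError(
            f"k_max {config.k_max} exceeds min(dims) = {min(n_rows, n_cols)}"
        )
    tasks: list[Task] = []
    if config.strategy == "serial":
        for k in config.ks:
            for r in range(config.num_clusterings):
                tasks.append(Task(k, r, 0, config.run_seed(k, r)))
    elif config.strategy == "kfactor":
        # Greedy least-loaded assignment of whole k values; all k carry the
        # same task count here, so order by ascending k for determinism.
        loads = [0] * config.n_workers
        for k in sorted(config.ks):
            worker = int(np.argmin(loads))
            loads[worker] += config.num_clusterings
            for r in range(config.num_clusterings):
                tasks.append(Task(k, r, worker, config.run_seed(k, r)))
    else:  # input-matrix: every run executed cooperatively by all workers
        for k in config.ks:
            for r in range(config.num_clusterings):
                tasks.append(Task(k, r, ALL_WORKERS, config.run_seed(k, r)))
    return TaskPlan(tasks=tasks, strategy=config.strategy)


def partition_rows(n_rows: int, n_workers: int) -> list[range]:
    """Contiguous balanced index ranges, larger blocks first."""
    if n_workers < 1:
        raise PartitionError("n_workers must be >= 1")
    if n_rows < n_workers:
        raise PartitionError(
            f"cannot split {n_rows} rows across {n_workers} workers"
        )
    base, rem = divmod(n_rows, n_workers)
    blocks: list[range] = []
    start = 0
    for w in range(n_workers):
        size = base + (1 if w < rem else 0)
        blocks.append(range(start, start + size))
        start += size
    return blocks


class WorkerBackend:
    """Exchange contract a worker pool must provide.

    ``broadcast`` distributes one worker's matrix to all workers;
    ``allreduce_sum`` sums per-worker partial matrices and hands every
    worker the identical total.  These two collectives are sufficient
    for the blocked multiplicative updates.
    """

    n_workers: int

    def broadcast(self, matrix: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def allreduce_sum(self, partials: list[np.ndarray]) -> list[np.ndarray]:
        raise NotImplementedError


class SimulatedBackend(WorkerBackend):
    """In-process worker pool executing block computations sequentially.

    Workers are simulated within one process but the data flow is the
    real one: each worker sees only its block of V during an update,
    and factors circulate exclusively through the two collectives.
    ``allreduce_sum`` verifies that the copies it returns are identical
    (the synchronization contract) and raises
    :class:`SynchronizationError` otherwise.
    """

    def __init__(self, n_workers: int):
        if n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        self.n_workers = n_workers

    def broadcast(self, matrix: np.ndarray) -> list[np.ndarray]:
        return [np.array(matrix, copy=True) for _ in range(self.n_workers)]

    def allreduce_sum(self, partials: list[np.ndarray]) -> list[np.ndarray]:
        if len(partials) != self.n_workers:
            raise SynchronizationError(
                f"expected {self.n_workers} partial matrices, got {len(partials)}"
            )
        total = partials[0].copy()
        for p in partials[1:]:
            total = total + p
        copies = [total.copy() for _ in range(self.n_workers)]
        for c in copies[1:]:
            if not np.array_equal(c, copies[0]):
                raise SynchronizationError("factor copies diverged after exchange")
        return copies


def blocked_update_step(
    V: np.ndarray, factors: FactorPair, backend: WorkerBackend
) -> FactorPair:
    """One multiplicative update computed block-parallel across workers.

    The H update partitions V by columns and the W update partitions V
    by rows; W and H are fully replicated on every worker.  Each worker
    fills only its slice of the updated factor; a sum-reduce of the
    zero-padded slices reassembles the complete factor on all workers.
    With one worker this is exactly :func:`nmf.update_step`.
    """
    V = np.asarray(V, dtype=float)
    n_rows, n_cols = V.shape
    nw = backend.n_workers
    col_blocks = partition_rows(n_cols, nw)
    row_blocks = partition_rows(n_rows, nw)

    W_copies = backend.broadcast(factors.W)
    H_copies = backend.broadcast(factors.H)

    # --- H update: worker w sees V[:, cols_w] ---
    partials = []
    for w in range(nw):
        W_w, H_w = W_copies[w], H_copies[w]
        cols = col_blocks[w]
        Vb = V[:, cols]
        WHb = np.maximum(W_w @ H_w[:, cols], EPS)
        numer = W_w.T @ (Vb / WHb)
        denom = np.maximum(W_w.sum(axis=0)[:, None], EPS)
        partial = np.zeros_like(H_w)
        partial[:, cols] = np.maximum(H_w[:, cols] * numer / denom, EPS)
        partials.append(partial)
    H_copies = backend.allreduce_sum(partials)

    # --- W update: worker w sees V[rows_w, :] ---
    partials = []
    for w in range(nw):
        W_w, H_w = W_copies[w], H_copies[w]
        rows = row_blocks[w]
        Vb = V[rows, :]
        WHb = np.maximum(W_w[rows, :] @ H_w, EPS)
        numer = (Vb / WHb) @ H_w.T
        denom = np.maximum(H_w.sum(axis=1)[None, :], EPS)
        partial = np.zeros_like(W_w)
        partial[rows, :] = np.maximum(W_w[rows, :] * numer / denom, EPS)
        partials.append(partial)
    W_copies = backend.allreduce_sum(partials)

    # Convergence checks read the replicated factors; worker 0's copy is
    # identical to all others per the allreduce contract.
    return FactorPair(W=W_copies[0], H=H_copies[0])


def run_all(
    V: LabeledMatrix, config: RunConfig, backend: WorkerBackend | None = None
) -> tuple[dict[int, tuple[ConsensusMatrix, list[NmfRunResult]]], StabilityReport]:
    """Execute the full run grid, build per-k consensus, select k.

    Returns ``(results, report)`` where ``results[k]`` is the consensus
    matrix and the per-restart run records for rank k.
    """
    plan = plan_tasks(config, *V.shape)
    if config.strategy == "input-matrix":
        if backend is None:
            backend = SimulatedBackend(config.n_workers)
        step = lambda M, f: blocked_update_step(M, f, backend)  # noqa: E731
    else:
        step = update_step

    runs: dict[int, list[NmfRunResult]] = {k: [] for k in config.ks}
    for task in sorted(plan.tasks, key=lambda t: (t.k, t.run_index)):
        try:
            result = run_nmf(
                V.values,
                task.k,
                config,
                task.seed,
                sample_names=V.column_names,
                step=step,
            )
        except Exception as exc:  # abort with a report naming the run
            raise RunFailure(task.k, task.run_index, task.seed, exc) from exc
        runs[task.k].append(result)

    results: dict[int, tuple[ConsensusMatrix, list[NmfRunResult]]] = {}
    records: list[StabilityRecord] = []
    for k in config.ks:
        consensus = build_consensus([r.connectivity for r in runs[k]], k)
        coph = cophenetic_coefficient(consensus) if consensus.n_samples >= 3 else None
        results[k] = (consensus, runs[k])
        records.append(StabilityRecord(k=k, cophenetic=coph, n_runs=len(runs[k])))
    selected = select_k(records)
    return results, StabilityReport(records=records, selected_k=selected)
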