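"""Consensus matrices and cophenetic stability scoring.

For each candidate rank k, the binary connectivity matrices of all
random restarts are averaged into a consensus matrix whose entry (i, j)
is the fraction of runs in which samples i and j landed in the same
cluster.  A stable clustering drives the consensus toward a 0/1 block
matrix.  Stability is scored by the cophenetic correlation coefficient:
the Pearson correlation between the distances 1 - consensus and the
ultrametric (cophenetic) distances induced by average-linkage
hierarchical clustering of those same distances.  The rank with the
highest coefficient is selected; ties go to the smaller, more
parsimonious k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .nmf import ConnectivityMatrix

__all__ = [
    "ConsensusMatrix",
    "StabilityRecord",
    "StabilityReport",
    "AggregationError",
    "build_consensus",
    "reorder_consensus",
    "cophenetic_coefficient",
    "select_k",
]


class AggregationError(ValueError):
    """Connectivity matrices disagree in shape or sample order."""


@dataclass
class ConsensusMatrix:
    """Per-k average of connectivity matrices; entries in [0, 1]."""

    values: np.ndarray
    sample_names: list[str]
    k: int
    n_runs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_names)
        if self.values.shape != (n, n):
            raise ValueError(
                f"consensus shape {self.values.shape} does not match "
                f"{n} sample names"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)


@dataclass
class StabilityRecord:
    k: int
    cophenetic: float | None
    n_runs: int


@dataclass
class StabilityReport:
    """Per-k cophenetic coefficients plus the selected rank."""

    records: list[StabilityRecord]
    selected_k: int


def build_consensus(
    connectivities: list[ConnectivityMatrix], k: int
) -> ConsensusMatrix:
    """Entrywise mean of the restarts' connectivity matrices."""
    if not connectivities:
        raise AggregationError("no connectivity matrices to aggregate")
    first = connectivities[0]
    for c in connectivities[1:]:
        if c.values.shape != first.values.shape:
            raise AggregationError(
                f"shape mismatch: {c.values.shape} vs {first.values.shape}"
            )
        if c.sample_names != first.sample_names:
            raise AggregationError("sample order differs across runs")
    stacked = np.stack([c.values.astype(float) for c in connectivities])
    return ConsensusMatrix(
        values=stacked.mean(axis=0),
        sample_names=list(first.sample_names),
        k=k,
        n_runs=len(connectivities),
    )


def _average_linkage(consensus: ConsensusMatrix) -> np.ndarray:
    """Average-linkage tree on the distance matrix 1 - consensus."""
    d = 1.0 - consensus.values
    # symmetrize against floating asymmetry; diagonal of a consensus is 1
    condensed = squareform((d + d.T) / 2.0, checks=False)
    condensed = np.maximum(condensed, 0.0)
    return hierarchy.linkage(condensed, method="average")


def reorder_consensus(
    consensus: ConsensusMatrix,
) -> tuple[ConsensusMatrix, np.ndarray]:
    """Permute samples to dendrogram leaf order for block display.

    Returns the reordered matrix and the leaf permutation (new position
    -> original index).
    """
    n = consensus.n_samples
    if n < 2:
        return consensus, np.arange(n)
    Z = _average_linkage(consensus)
    order = hierarchy.leaves_list(Z)
    reordered = ConsensusMatrix(
        values=consensus.values[np.ix_(order, order)],
        sample_names=[consensus.sample_names[i] for i in order],
        k=consensus.k,
        n_runs=consensus.n_runs,
    )
    return reordered, order


def cophenetic_coefficient(consensus: ConsensusMatrix) -> float | None:
    """Cophenetic correlation of the consensus-induced distances.

    Pearson correlation between the strict upper triangle of
    1 - consensus and the cophenetic distances of its average-linkage
    dendrogram.  Returns ``None`` (undefined) when either distance
    vector has zero variance, e.g. for a consensus whose off-diagonal
    entries are all equal.
    """
    if consensus.n_samples < 3:
        raise ValueError(
            f"cophenetic coefficient needs >= 3 samples, got {consensus.n_samples}"
        )
    d = 1.0 - consensus.values
    condensed = np.maximum(squareform((d + d.T) / 2.0, checks=False), 0.0)
    Z = hierarchy.linkage(condensed, method="average")
    coph = hierarchy.cophenet(Z)
    if np.ptp(condensed) == 0.0 or np.ptp(coph) == 0.0:
        return None
    return float(np.corrcoef(condensed, coph)[0, 1])


def select_k(report: StabilityReport | list[StabilityRecord]) -> int:
    """Rank with the maximum cophenetic coefficient; ties -> smallest k."""
    records = report.records if isinstance(report, StabilityReport) else report
    defined = [r for r in records if r.cophenetic is not None]
    if not defined:
        raise ValueError("no k has a defined cophenetic coefficient")
    ordered = sorted(defined, key=lambda r: r.k)
    best = ordered[0]
    for r in ordered[1:]:
        if r.cophenetic > best.cophenetic:  # strict: ties keep smaller k
            best = r
    return best.k
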