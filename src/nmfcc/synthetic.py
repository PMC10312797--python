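"""Planted-cluster synthetic expression matrices with ground truth.

The generator emulates the block signal NMF assumes: each of the
``k_true`` clusters owns a disjoint block of genes with elevated weight
in W, each sample's H column is elevated for its planted cluster, and
V = W_true H_true plus half-normal noise.  Because the gene blocks are
disjoint the planted metagenes are identifiable, so recovery can be
scored exactly against the true labels.

It does not attempt realistic scRNA-seq artefacts (dropout, library
size variation, overdispersion) — it exists so the factorization,
consensus and scheduling machinery are testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gct import LabeledMatrix

#: Baseline weight of every W/H entry; planted blocks sit at
#: BACKGROUND + separation.
BACKGROUND = 0.1

__all__ = ["BACKGROUND", "PlantedDataset", "generate_planted_data"]


@dataclass
class PlantedDataset:
    matrix: LabeledMatrix
    true_labels: np.ndarray
    k_true: int
    separation: float
    noise_scale: float
    seed: int


def generate_planted_data(
    n_genes: int,
    n_samples: int,
    k_true: int,
    separation: float = 5.0,
    noise_scale: float = 0.1,
    seed: int = 0,
) -> PlantedDataset:
    """Generate a non-negative matrix with ``k_true`` planted clusters.

    Samples are assigned to clusters round-robin; cluster c elevates a
    disjoint block of roughly ``n_genes / k_true`` genes by
    ``separation`` above the 0.1 background.  Noise is half-normal
    (|N(0, noise_scale^2)|) added entrywise, then clipped at zero, so
    the matrix stays non-negative without zero-inflating the signal.
    """
    if k_true < 2:
        raise ValueError(f"k_true must be >= 2, got {k_true}")
    if n_samples < 2 * k_true:
        raise ValueError(
            f"need n_samples >= 2*k_true ({2 * k_true}), got {n_samples}"
        )
    if n_genes < k_true:
        raise ValueError(f"need n_genes >= k_true ({k_true}), got {n_genes}")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")

    rng = np.random.default_rng(seed)
    labels = np.arange(n_samples) % k_true

    W_true = np.full((n_genes, k_true), BACKGROUND)
    base, rem = divmod(n_genes, k_true)
    start = 0
    gene_block = np.empty(n_genes, dtype=int)
    for c in range(k_true):
        size = base + (1 if c < rem else 0)
        W_true[start : start + size, c] += separation
        gene_block[start : start + size] = c
        start += size

    H_true = np.full((k_true, n_samples), BACKGROUND)
    H_true[labels, np.arange(n_samples)] += separation

    V = W_true @ H_true
    if noise_scale > 0:
        V = V + noise_scale * np.abs(rng.standard_normal(V.shape))
    V = np.clip(V, 0.0, None)

    matrix = LabeledMatrix(
        values=V,
        row_names=[f"g{i}" for i in range(n_genes)],
        column_names=[f"s{j}" for j in range(n_samples)],
        row_descriptions=[f"block{gene_block[i]}" for i in range(n_genes)],
    )
    return PlantedDataset(
        matrix=matrix,
        true_labels=labels,
        k_true=k_true,
        separation=separation,
        noise_scale=noise_scale,
        seed=seed,
    )
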