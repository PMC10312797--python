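"""Per-k consensus artifacts with column-count gating.

For every rank k a consensus GCT is always written.  When the input has
fewer than 1,000 columns a dendrogram-sorted consensus GCT is added;
with fewer than 100 columns each sorted consensus is also plotted as a
PDF heatmap.  A tab-delimited stability report records the cophenetic
coefficient per k and flags the selected rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .consensus import ConsensusMatrix, StabilityReport, reorder_consensus
from .gct import LabeledMatrix, write_gct

#: Column thresholds below which the sorted GCT / heatmap are emitted.
SORTED_MAX_COLUMNS = 1000
HEATMAP_MAX_COLUMNS = 100

__all__ = [
    "SORTED_MAX_COLUMNS",
    "HEATMAP_MAX_COLUMNS",
    "GatingError",
    "OutputManifest",
    "emit_outputs",
    "plot_consensus",
]


class GatingError(ValueError):
    """An artifact was requested above its column-count threshold."""


@dataclass
class OutputManifest:
    """Files produced for one job: per-k artifacts plus the report."""

    consensus: dict[int, Path] = field(default_factory=dict)
    sorted_consensus: dict[int, Path] = field(default_factory=dict)
    heatmaps: dict[int, Path] = field(default_factory=dict)
    stability_report: Path | None = None

    def all_files(self) -> list[Path]:
        files = (
            list(self.consensus.values())
            + list(self.sorted_consensus.values())
            + list(self.heatmaps.values())
        )
        if self.stability_report is not None:
            files.append(self.stability_report)
        return files


def _consensus_to_labeled(consensus: ConsensusMatrix) -> LabeledMatrix:
    return LabeledMatrix(
        values=consensus.values,
        row_names=list(consensus.sample_names),
        column_names=list(consensus.sample_names),
        row_descriptions=list(consensus.sample_names),
    )


def plot_consensus(
    consensus: ConsensusMatrix, leaf_order: np.ndarray, path: str | Path
) -> Path:
    """Write a PDF heatmap of the reordered consensus matrix.

    The color scale is fixed to [0, 1], samples are labelled on both
    axes and the rank appears in the title.  Figure geometry is fixed
    and PDF metadata is stripped so identical inputs produce identical
    bytes.
    """
    n = consensus.n_samples
    if n >= HEATMAP_MAX_COLUMNS:
        raise GatingError(
            f"heatmaps are produced only below {HEATMAP_MAX_COLUMNS} samples, got {n}"
        )
    order = np.asarray(leaf_order)
    values = consensus.values[np.ix_(order, order)]
    labels = [consensus.sample_names[i] for i in order]
    path = Path(path)

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(values, vmin=0.0, vmax=1.0, cmap="bwr", interpolation="nearest")
    ax.set_xticks(range(n))
    ax.set_yticks(range(n))
    fontsize = max(2.0, min(8.0, 400.0 / max(n, 1)))
    ax.set_xticklabels(labels, rotation=90, fontsize=fontsize)
    ax.set_yticklabels(labels, fontsize=fontsize)
    ax.set_title(f"Consensus matrix, k={consensus.k} ({consensus.n_runs} runs)")
    fig.colorbar(im, ax=ax, label="co-clustering fraction")
    fig.savefig(path, format="pdf", metadata={"CreationDate": None})
    plt.close(fig)
    return path


def emit_outputs(
    results: dict[int, ConsensusMatrix],
    report: StabilityReport,
    out_dir: str | Path,
) -> OutputManifest:
    """Write every gated artifact for each k and the stability report."""
    if not results:
        raise ValueError("no consensus matrices to emit")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = OutputManifest()

    for k in sorted(results):
        consensus = results[k]
        n_cols = consensus.n_samples
        path = out_dir / f"consensus.k.{k}.gct"
        write_gct(_consensus_to_labeled(consensus), path)
        manifest.consensus[k] = path
        if n_cols < SORTED_MAX_COLUMNS:
            reordered, order = reorder_consensus(consensus)
            sorted_path = out_dir / f"consensus.sorted.k.{k}.gct"
            write_gct(_consensus_to_labeled(reordered), sorted_path)
            manifest.sorted_consensus[k] = sorted_path
            if n_cols < HEATMAP_MAX_COLUMNS:
                pdf_path = out_dir / f"consensus.k.{k}.pdf"
                plot_consensus(consensus, order, pdf_path)
                manifest.heatmaps[k] = pdf_path

    report_path = out_dir / "stability.report.txt"
    with report_path.open("w", encoding="utf-8") as fh:
        fh.write("k\tcophenetic\tselected\n")
        for rec in sorted(report.records, key=lambda r: r.k):
            coph = "NA" if rec.cophenetic is None else repr(rec.cophenetic)
            sel = "1" if rec.k == report.selected_k else "0"
            fh.write(f"{rec.k}\t{coph}\t{sel}\n")
    manifest.stability_report = report_path
    return manifest
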