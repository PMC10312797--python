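"""Reading and writing of GCT (#1.2) tab-delimited expression matrices.

The GCT dialect understood here is the GenePattern one: a ``#1.2``
version line, a ``<nrows>\\t<ncols>`` dimensions line, a header row
``Name\\tDescription\\t<sample names...>`` and one row per feature.  All
values must be finite and non-negative, since the matrices flow into a
non-negative factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabeledMatrix",
    "GctError",
    "GctFormatError",
    "GctDimensionError",
    "GctParseError",
    "NegativeValueError",
    "read_gct",
    "write_gct",
]


class GctError(ValueError):
    """Base class for GCT format violations."""


class GctFormatError(GctError):
    """The file does not follow the #1.2 GCT layout."""


class GctDimensionError(GctError):
    """Declared row/column counts disagree with the file body."""


class GctParseError(GctError):
    """A data cell could not be parsed as a number."""


class NegativeValueError(ValueError):
    """A matrix value is negative; NMF requires non-negative input."""


@dataclass
class LabeledMatrix:
    """A dense non-negative matrix with row and column identifiers.

    Rows are features (genes/transcripts), columns are samples.  Row
    descriptions are free text and default to the row names.
    """

    values: np.ndarray
    row_names: list[str]
    column_names: list[str]
    row_descriptions: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_names = [str(r) for r in self.row_names]
        self.column_names = [str(c) for c in self.column_names]
        if self.row_descriptions is None:
            self.row_descriptions = list(self.row_names)
        else:
            self.row_descriptions = [str(d) for d in self.row_descriptions]
        if self.values.ndim != 2:
            raise GctDimensionError("values must be a 2-D matrix")
        n_rows, n_cols = self.values.shape
        if len(self.row_names) != n_rows:
            raise GctDimensionError(
                f"{len(self.row_names)} row names for {n_rows} rows"
            )
        if len(self.row_descriptions) != n_rows:
            raise GctDimensionError(
                f"{len(self.row_descriptions)} descriptions for {n_rows} rows"
            )
        if len(self.column_names) != n_cols:
            raise GctDimensionError(
                f"{len(self.column_names)} column names for {n_cols} columns"
            )
        if len(set(self.row_names)) != n_rows:
            raise GctError("duplicate row names")
        if len(set(self.column_names)) != n_cols:
            raise GctError("duplicate column names")
        if not np.all(np.isfinite(self.values)):
            raise GctError("matrix contains non-finite values")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise NegativeValueError(
                f"negative value at row {self.row_names[i]!r}, "
                f"column {self.column_names[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledMatrix):
            return NotImplemented
        return (
            self.row_names == other.row_names
            and self.column_names == other.column_names
            and self.row_descriptions == other.row_descriptions
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )


def read_gct(path: str | Path) -> LabeledMatrix:
    """Parse a GCT #1.2 file into a :class:`LabeledMatrix`.

    Raises :class:`GctFormatError` for a bad version line or header,
    :class:`GctDimensionError` when the declared dimensions disagree
    with the body, :class:`GctParseError` for non-numeric cells and
    :class:`NegativeValueError` for negative values.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GctFormatError(f"{path}: fewer than 3 lines")
    if lines[0].strip() != "#1.2":
        raise GctFormatError(
            f"{path}: version line is {lines[0]!r}, expected '#1.2'"
        )
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise GctFormatError(f"{path}: dimensions line is {lines[1]!r}")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except ValueError as exc:
        raise GctFormatError(f"{path}: non-integer dimensions {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise GctFormatError(
            f"{path}: header must start with 'Name\\tDescription'"
        )
    column_names = header[2:]
    if len(column_names) != n_cols:
        raise GctDimensionError(
            f"{path}: declared {n_cols} columns but header has {len(column_names)}"
        )
    body = [ln for ln in lines[3:] if ln != ""]
    if len(body) != n_rows:
        raise GctDimensionError(
            f"{path}: declared {n_rows} rows but body has {len(body)}"
        )
    row_names: list[str] = []
    row_descriptions: list[str] = []
    values = np.empty((n_rows, n_cols), dtype=float)
    for i, line in enumerate(body):
        cells = line.split("\t")
        if len(cells) != n_cols + 2:
            raise GctDimensionError(
                f"{path}: row {i + 1} has {len(cells) - 2} values, expected {n_cols}"
            )
        row_names.append(cells[0])
        row_descriptions.append(cells[1])
        for j, cell in enumerate(cells[2:]):
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise GctParseError(
                    f"{path}: non-numeric value {cell!r} at row {cells[0]!r}, "
                    f"column {column_names[j]!r}"
                ) from exc
    return LabeledMatrix(
        values=values,
        row_names=row_names,
        column_names=column_names,
        row_descriptions=row_descriptions,
    )


def write_gct(matrix: LabeledMatrix, path: str | Path) -> Path:
    """Write a :class:`LabeledMatrix` as a GCT #1.2 file.

    Values are serialized with shortest round-trip (``repr``) precision
    so that read(write(m)) reproduces m exactly, including consensus
    fractions such as multiples of 1/n_runs.
    """
    path = Path(path)
    n_rows, n_cols = matrix.shape
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.column_names) + "\n")
        for i in range(n_rows):
            row = matrix.values[i]
            cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{matrix.row_names[i]}\t{matrix.row_descriptions[i]}\t{cells}\n")
    return path
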