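"""Similarity-matrix I/O.

The pipeline starts from an ``n x n`` matrix ``S`` of pairwise percent-identity
scores in ``[0, 100]`` over ``n`` protein sequences (one node per sequence).
Aligners report directional scores, so ``S_ij`` may differ from ``S_ji``; the
network construction uses the conservative symmetrization
``S_ij <- min(S_ij, S_ji)``.

Supported on-disk dialects:

``labeled-tsv`` / ``labeled-csv``
    First row and first column carry the sequence labels; the top-left corner
    cell is ignored.  Written files round-trip bit-identically.
``phylip-square``
    A count line ``n`` followed by ``n`` rows of ``name v1 ... vn``
    (whitespace separated).
``blast-tabular``
    An ``outfmt 6``-style pair list; see :func:`read_blast_tabular`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DimensionError,
    DuplicateLabelError,
    EmptyInputError,
    RangeError,
)

__all__ = [
    "SimilarityMatrix",
    "read_square_matrix",
    "write_square_matrix",
    "from_pairwise_records",
    "read_blast_tabular",
    "symmetrize",
]

_DIALECTS = ("labeled-tsv", "labeled-csv", "phylip-square")


@dataclass(frozen=True)
class SimilarityMatrix:
    """A labeled square matrix of percent-identity scores.

    Invariants (enforced on construction): values is square and matches
    ``labels``; every entry lies in ``[0, 100]``; the diagonal is exactly 100
    (self-similarity, forced regardless of input — threshold networks never
    use self-scores).
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    symmetrized: bool = False

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=float, copy=True)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise DimensionError(
                f"similarity matrix must be square, got shape {values.shape}"
            )
        if values.shape[0] != len(self.labels):
            raise DimensionError(
                f"{len(self.labels)} labels but {values.shape[0]} rows"
            )
        if len(set(self.labels)) != len(self.labels):
            seen: set[str] = set()
            dup = next(l for l in self.labels if l in seen or seen.add(l))
            raise DuplicateLabelError(f"duplicate label {dup!r}")
        lo, hi = values.min(initial=100.0), values.max(initial=0.0)
        if lo < 0.0 or hi > 100.0:
            i, j = divmod(
                int(np.argmax((values < 0) | (values > 100))), values.shape[1]
            )
            raise RangeError(
                f"score {values[i, j]} at ({self.labels[i]!r}, "
                f"{self.labels[j]!r}) outside [0, 100]"
            )
        np.fill_diagonal(values, 100.0)
        values.setflags(write=False)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def score(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.values, self.values.T))


def symmetrize(S: SimilarityMatrix) -> SimilarityMatrix:
    """Return the min-symmetrized matrix: ``S'_ij = min(S_ij, S_ji)``.

    Idempotent; never increases an entry; the diagonal stays 100.
    """
    values = np.minimum(S.values, S.values.T)
    return SimilarityMatrix(S.labels, values, symmetrized=True)


def _parse_cell(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise RangeError(f"cell {where} is not a number: {text!r}") from None


def _check_range(value: float, where: str) -> float:
    if not 0.0 <= value <= 100.0:
        raise RangeError(f"score {value} at {where} outside [0, 100]")
    return value


def read_square_matrix(
    path: str | Path, dialect: str = "labeled-tsv"
) -> SimilarityMatrix:
    """Read a square similarity matrix from *path*.

    Returns an unsymmetrized :class:`SimilarityMatrix` (``symmetrized=False``)
    with labels from the header/first column (labeled dialects) or the PHYLIP
    name field.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    text = Path(path).read_text()
    if dialect == "phylip-square":
        labels, values = _parse_phylip(text)
    else:
        sep = "\t" if dialect == "labeled-tsv" else ","
        labels, values = _parse_labeled(text, sep)
    return SimilarityMatrix(tuple(labels), values, symmetrized=False)


def _parse_labeled(text: str, sep: str) -> tuple[list[str], np.ndarray]:
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=sep) if r]
    if not rows:
        raise EmptyInputError("empty matrix file")
    header = rows[0][1:]
    n = len(header)
    body = rows[1:]
    if len(body) != n:
        raise DimensionError(f"{n} column labels but {len(body)} data rows")
    labels: list[str] = []
    values = np.empty((n, n), dtype=float)
    for i, row in enumerate(body):
        if len(row) - 1 != n:
            raise DimensionError(
                f"row {i + 1} has {len(row) - 1} cells, expected {n}"
            )
        labels.append(row[0])
        for j, cell in enumerate(row[1:]):
            where = f"({row[0]!r}, {header[j]!r})"
            values[i, j] = _check_range(_parse_cell(cell, where), where)
    if labels != header:
        # Row/column orders must agree; anything else is a malformed table.
        raise DimensionError("row labels do not match column labels")
    if len(set(labels)) != len(labels):
        raise DuplicateLabelError("duplicate label in matrix file")
    return labels, values


def _parse_phylip(text: str) -> tuple[list[str], np.ndarray]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError("empty matrix file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise DimensionError(f"bad PHYLIP count line: {lines[0]!r}") from None
    body = lines[1:]
    if len(body) != n:
        raise DimensionError(f"PHYLIP header says {n} rows, found {len(body)}")
    labels: list[str] = []
    values = np.empty((n, n), dtype=float)
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) - 1 != n:
            raise DimensionError(
                f"row {i + 1} has {len(parts) - 1} values, expected {n}"
            )
        labels.append(parts[0])
        for j, cell in enumerate(parts[1:]):
            where = f"({parts[0]!r}, column {j})"
            values[i, j] = _check_range(_parse_cell(cell, where), where)
    if len(set(labels)) != len(labels):
        raise DuplicateLabelError("duplicate name in PHYLIP matrix")
    return labels, values


def write_square_matrix(
    S: SimilarityMatrix, path: str | Path, dialect: str = "labeled-tsv"
) -> None:
    """Write *S* to *path*.  labeled-tsv/csv round-trip bit-identically
    (floats are rendered with Python's shortest round-trip repr)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    lines: list[str] = []
    if dialect == "phylip-square":
        lines.append(str(S.n))
        for label, row in zip(S.labels, S.values):
            lines.append(" ".join([label, *(repr(float(v)) for v in row)]))
    else:
        sep = "\t" if dialect == "labeled-tsv" else ","
        lines.append(sep.join(["", *S.labels]))
        for label, row in zip(S.labels, S.values):
            lines.append(sep.join([label, *(repr(float(v)) for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n")


def from_pairwise_records(
    records: Iterable[tuple[str, str, float]],
) -> SimilarityMatrix:
    """Assemble a similarity matrix from (query, subject, percent-identity)
    triples, e.g. parsed BLAST tabular output.

    The matrix spans the union of all ids (sorted).  When a pair is reported
    more than once (multiple local alignments) the maximum percent identity
    wins.  Absent ordered pairs default to 0 — no detectable homology, hence
    no edge at any threshold >= 1.  The diagonal is forced to 100.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("no pairwise records")
    for q, s, pid in records:
        if not 0.0 <= float(pid) <= 100.0:
            raise RangeError(f"score {pid} for pair ({q!r}, {s!r}) outside [0, 100]")
    labels = sorted({x for q, s, _ in records for x in (q, s)})
    idx = {lab: i for i, lab in enumerate(labels)}
    values = np.zeros((len(labels), len(labels)), dtype=float)
    for q, s, pid in records:
        i, j = idx[q], idx[s]
        values[i, j] = max(values[i, j], float(pid))
    np.fill_diagonal(values, 100.0)
    return SimilarityMatrix(tuple(labels), values, symmetrized=False)


def read_blast_tabular(
    path: str | Path,
    columns: Sequence[int] = (0, 1, 2),
) -> list[tuple[str, str, float]]:
    """Parse an outfmt-6-like tab/whitespace-separated pair list.

    *columns* gives the 0-based positions of (query id, subject id, percent
    identity); the defaults match ``blastp -outfmt 6``.
    """
    qcol, scol, pcol = columns
    need = max(columns) + 1
    records: list[tuple[str, str, float]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < need:
            raise DimensionError(
                f"line {ln}: {len(parts)} columns, need at least {need}"
            )
        records.append((parts[qcol], parts[scol], float(parts[pcol])))
    if not records:
        raise EmptyInputError(f"no records in {path}")
    return records
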