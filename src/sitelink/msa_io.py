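"""Alignment container, readers/writers, reference numbering and column filters.

The central object is :class:`Alignment`: a rectangular residue matrix whose
rows are species and whose columns are aligned sites.  One row (by default the
first) is the *reference* sequence; after :func:`apply_first_row_mapping` every
retained column carries a 1-based position in that reference sequence, which is
the coordinate system used by every downstream report.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GAP",
    "Alignment",
    "RaggedAlignmentError",
    "read_alignment",
    "write_alignment_csv",
    "write_alignment_fasta",
    "apply_first_row_mapping",
    "filter_non_insertion",
]

#: Canonical gap symbol.  '.' is accepted on input and normalised to '-'.
GAP = "-"

_GAP_INPUT = {"-", "."}
# Standard 20 amino acids plus ambiguity/rare codes kept as distinct symbols.
_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | set("BZXUO")
_VALID = _RESIDUES | {GAP}


class RaggedAlignmentError(ValueError):
    """Raised when input rows do not all share the same length."""


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment.

    Parameters
    ----------
    row_ids
        One identifier per row, in file order.
    residues
        ``(n_rows, n_cols)`` array of single upper-case characters; gaps are
        ``'-'``.
    reference_row
        Index of the reference sequence used for position numbering.
    column_positions
        1-based reference-sequence position of each column, or ``None`` before
        first-row mapping has been applied.
    """

    row_ids: list[str]
    residues: np.ndarray
    reference_row: int = 0
    column_positions: list[int] | None = None

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype="<U1")
        if self.residues.ndim != 2:
            raise ValueError("residues must be a 2-D character array")
        if len(self.row_ids) != self.residues.shape[0]:
            raise ValueError(
                f"{len(self.row_ids)} row ids for {self.residues.shape[0]} rows"
            )
        if self.column_positions is not None:
            if len(self.column_positions) != self.residues.shape[1]:
                raise ValueError("column_positions length != number of columns")
        if not 0 <= self.reference_row < self.residues.shape[0]:
            raise ValueError(f"reference_row {self.reference_row} out of range")

    @property
    def n_rows(self) -> int:
        return self.residues.shape[0]

    @property
    def n_cols(self) -> int:
        return self.residues.shape[1]

    def positions(self) -> list[int]:
        """Reference positions of the current columns (1-based).

        Falls back to sequential numbering when first-row mapping has not been
        applied.
        """
        if self.column_positions is not None:
            return list(self.column_positions)
        return list(range(1, self.n_cols + 1))

    def column(self, position: int) -> np.ndarray:
        """Residue column for a 1-based reference *position*."""
        return self.residues[:, self.column_index(position)]

    def column_index(self, position: int) -> int:
        try:
            return self.positions().index(position)
        except ValueError:
            raise KeyError(f"position {position} not present in alignment") from None

    def reference_residue(self, position: int) -> str:
        return str(self.residues[self.reference_row, self.column_index(position)])

    def is_gap(self) -> np.ndarray:
        """Boolean mask of gap cells, same shape as ``residues``."""
        return self.residues == GAP


def _clean_sequence(seq: str, row_label: str) -> str:
    out = []
    for ch in seq:
        c = ch.upper()
        if c in _GAP_INPUT:
            out.append(GAP)
        elif c in _RESIDUES:
            out.append(c)
        else:
            raise ValueError(
                f"row {row_label!r}: invalid alignment character {ch!r}"
            )
    return "".join(out)


def _build(rows: list[tuple[str, str]], source: str) -> Alignment:
    if not rows:
        raise ValueError(f"{source}: no sequences found")
    cleaned = [(rid, _clean_sequence(seq, rid)) for rid, seq in rows]
    length = len(cleaned[0][1])
    for i, (rid, seq) in enumerate(cleaned, start=1):
        if len(seq) != length:
            raise RaggedAlignmentError(
                f"{source}: row {i} ({rid!r}) has length {len(seq)}, "
                f"expected {length}"
            )
    grid = np.array([list(seq) for _, seq in cleaned], dtype="<U1")
    return Alignment(row_ids=[rid for rid, _ in cleaned], residues=grid)


def _read_csv_rows(path: Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for record in csv.reader(fh):
            if not record or all(not cell.strip() for cell in record):
                continue
            rid = record[0].strip()
            cells = [c.strip() for c in record[1:] if c.strip() != ""]
            if not cells:
                raise ValueError(f"{path}: row {rid!r} has no sequence data")
            if len(cells) == 1:
                # identifier + whole-sequence-string dialect
                rows.append((rid, cells[0]))
            else:
                # identifier + one character per cell dialect
                bad = [c for c in cells if len(c) != 1]
                if bad:
                    raise ValueError(
                        f"{path}: row {rid!r} mixes multi-character cells "
                        f"{bad[:3]} with per-cell layout"
                    )
                rows.append((rid, "".join(cells)))
    return rows


def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read a protein MSA from FASTA or CSV.

    ``format`` is ``"fasta"`` or ``"csv"``; when ``None`` it is inferred from
    the file suffix.  Characters are upper-cased, ``'.'`` gaps are normalised
    to ``'-'``, and rare/ambiguous residue codes (B, Z, X, U, O) are kept as
    distinct symbols.  Ragged input raises :class:`RaggedAlignmentError`
    naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() in {".csv", ".tsv"} else "fasta"
    if format == "fasta":
        records = [(r.id if r.id else f"row{i+1}", str(r.seq))
                   for i, r in enumerate(SeqIO.parse(str(path), "fasta"))]
        return _build(records, str(path))
    if format == "csv":
        return _build(_read_csv_rows(path), str(path))
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.row_ids, aln.residues):
            fh.write(f">{rid}\n{''.join(row)}\n")


def write_alignment_csv(aln: Alignment, path: str | Path) -> None:
    """Write one row per species: identifier then one residue per cell."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for rid, row in zip(aln.row_ids, aln.residues):
            writer.writerow([rid, *row])


def apply_first_row_mapping(aln: Alignment) -> Alignment:
    """Number columns by the reference sequence and drop its gap columns.

    Columns where the reference row holds a gap are removed; the survivors are
    numbered 1..N along the reference sequence, so every downstream position
    refers to a residue of the reference protein.
    """
    ref = aln.residues[aln.reference_row]
    keep = ref != GAP
    if not keep.any():
        raise ValueError("reference row is entirely gaps")
    residues = aln.residues[:, keep]
    return Alignment(
        row_ids=list(aln.row_ids),
        residues=residues,
        reference_row=aln.reference_row,
        column_positions=list(range(1, int(keep.sum()) + 1)),
    )


def filter_non_insertion(aln: Alignment, pct: float) -> Alignment:
    """Keep columns whose fraction of non-gap characters is >= ``pct`` percent.

    ``pct`` is expressed as a percentage in (0, 100]; a column survives when
    ``non_gap / n_rows >= pct / 100``.  Reference positions of surviving
    columns are preserved.
    """
    if not 0 < pct <= 100:
        raise ValueError(f"non-insertion percentage must be in (0, 100], got {pct}")
    nongap = (~aln.is_gap()).sum(axis=0)
    keep = nongap / aln.n_rows >= pct / 100.0
    positions = aln.positions()
    return Alignment(
        row_ids=list(aln.row_ids),
        residues=aln.residues[:, keep],
        reference_row=aln.reference_row,
        column_positions=[p for p, k in zip(positions, keep) if k],
    )
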