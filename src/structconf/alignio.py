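"""Reading, validating and writing structure-aware multiple alignments.

Row order is semantically significant: the confidence metric scores adjacent
row pairs, so readers preserve input order exactly and writers emit it
unchanged.  Clustal and aligned FASTA are supported through Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    EmptyInputError,
    GapOnlyRowWarning,
    RaggedAlignmentError,
)
from .matrix import GAP, SubstitutionMatrix

_INPUT_GAPS = {"-", "."}


@dataclass(frozen=True)
class StructureAwareSequence:
    """An ungapped string of structural-alphabet characters with a label."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise EmptyInputError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Ordered gapped rows of equal length.

    ``rows`` is a tuple of (id, gapped string) in input-file order; the
    order is part of the alignment's meaning under adjacent-pair scoring.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.rows:
            raise EmptyInputError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise RaggedAlignmentError(f"row lengths differ: {sorted(lengths)}")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate row ids: {dupes}")
        canon = tuple(
            (rid, _canonicalize(seq)) for rid, seq in self.rows
        )
        object.__setattr__(self, "rows", canon)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def column(self, j: int) -> tuple[str, ...]:
        """Characters of 0-based column ``j``, top to bottom."""
        return tuple(seq[j] for _, seq in self.rows)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(f"no row with id {row_id!r}")

    def take_columns(self, indices) -> "Alignment":
        """New alignment of the given 0-based columns, original row order."""
        idx = list(indices)
        return Alignment(
            tuple(
                (rid, "".join(seq[j] for j in idx)) for rid, seq in self.rows
            )
        )


def _canonicalize(seq: str) -> str:
    out = []
    for ch in seq:
        out.append(GAP if ch in _INPUT_GAPS else ch.upper())
    return "".join(out)


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.lstrip().startswith(">"):
                return "fasta"
            if line.upper().lstrip().startswith("CLUSTAL"):
                return "clustal"
            break
    raise EmptyInputError(f"cannot detect alignment format of {path} (empty or unknown)")


def read_alignment(path: str | Path, format_hint: str | None = None) -> Alignment:
    """Read a Clustal or aligned-FASTA alignment, preserving row order.

    ``.`` gaps are converted to ``-`` and characters upper-cased.  Raises
    :class:`RaggedAlignmentError` for unequal row lengths,
    :class:`DuplicateIdError` for repeated ids and :class:`EmptyInputError`
    for empty files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    fmt = format_hint or _detect_format(path)
    if fmt not in ("clustal", "fasta"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        msg = str(exc).lower()
        if "length" in msg or "same" in msg:
            raise RaggedAlignmentError(str(exc)) from exc
        if "no records" in msg or "empty" in msg:
            raise EmptyInputError(str(exc)) from exc
        raise
    rows = tuple((rec.id, str(rec.seq)) for rec in msa)
    if not rows:
        raise EmptyInputError(f"no sequences in {path}")
    return Alignment(rows)


def write_alignment(aln: Alignment, path: str | Path, format: str = "clustal") -> None:
    """Write the alignment as Clustal or aligned FASTA (round-trip safe)."""
    if format not in ("clustal", "fasta"):
        raise ValueError(f"unsupported format {format!r}")
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.rows
    ]
    msa = MultipleSeqAlignment(records)
    AlignIO.write(msa, str(path), format)


@dataclass(frozen=True)
class ValidationReport:
    """Characters not scoreable against a matrix, plus gap-only rows.

    ``violations`` holds (row_id, column_1based, character) triples;
    column indices are 1-based for display.
    """

    violations: tuple[tuple[str, int, str], ...]
    gap_only_rows: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_alignment(aln: Alignment, matrix: SubstitutionMatrix) -> ValidationReport:
    """Report every alignment character missing from the matrix alphabet.

    An empty-violation report means the alignment is scoreable.  All-gap
    rows are flagged as warnings (they contribute no valid pairs).
    """
    violations = []
    gap_only = []
    for rid, seq in aln.rows:
        non_gap = 0
        for j, ch in enumerate(seq):
            if ch == matrix.alphabet.gap_symbol:
                continue
            non_gap += 1
            if ch not in matrix.alphabet:
                violations.append((rid, j + 1, ch))
        if non_gap == 0:
            gap_only.append(rid)
            warnings.warn(f"row {rid!r} is gap-only", GapOnlyRowWarning, stacklevel=2)
    return ValidationReport(tuple(violations), tuple(gap_only))
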