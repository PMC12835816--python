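"""Substitution matrices over structural alphabets.

The confidence metric scores adjacent alignment rows with a symmetric
substitution matrix S over a structural alphabet (Foldseek's 20-state 3Di
alphabet in production use; tiny toy alphabets in tests).  Matrices are read
from BLAST/NCBI-style square text files — the dialect both ClustalW2 and
MAFFT consume — and symmetry can be verified on load.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    GapSymbolError,
    MatrixFormatError,
    MatrixSymmetryError,
    UnknownSymbolError,
)

GAP = "-"


@dataclass(frozen=True)
class StructureAlphabet:
    """Ordered set of residue symbols plus the gap symbol.

    Symbols are canonicalized to upper case; the gap symbol is never a
    member of ``symbols``.
    """

    symbols: tuple[str, ...]
    gap_symbol: str = GAP

    def __post_init__(self):
        canon = tuple(s.upper() for s in self.symbols)
        object.__setattr__(self, "symbols", canon)
        if len(set(canon)) != len(canon):
            raise MatrixFormatError(f"duplicate symbols in alphabet: {canon}")
        if self.gap_symbol in canon:
            raise MatrixFormatError("gap symbol cannot be an alphabet member")
        if any(len(s) != 1 for s in canon) or len(self.gap_symbol) != 1:
            raise MatrixFormatError("alphabet symbols must be single characters")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Square real-valued score table S(x, y) over a structure alphabet.

    There is no row or column for the gap symbol: gap handling is the
    caller's responsibility (adjacent pairs involving gaps are excluded
    from scoring upstream).
    """

    alphabet: StructureAlphabet
    scores: Mapping[tuple[str, str], float] = field(repr=False)

    def __post_init__(self):
        for x in self.alphabet.symbols:
            for y in self.alphabet.symbols:
                if (x, y) not in self.scores:
                    raise MatrixFormatError(f"missing score cell ({x}, {y})")

    def score(self, x: str, y: str) -> float:
        """Return S(x, y).  Gap symbols are a usage error, not a zero."""
        x, y = x.upper(), y.upper()
        for s in (x, y):
            if s == self.alphabet.gap_symbol:
                raise GapSymbolError(
                    "gap symbol passed to score(); gap pairs must be excluded upstream"
                )
            if s not in self.alphabet:
                raise UnknownSymbolError(s)
        return self.scores[(x, y)]

    def is_symmetric(self, tol: float = 0.0) -> bool:
        syms = self.alphabet.symbols
        return all(
            abs(self.scores[(x, y)] - self.scores[(y, x)]) <= tol
            for x in syms
            for y in syms
        )


def score_pair(matrix: SubstitutionMatrix, x: str, y: str) -> float:
    """Functional alias for :meth:`SubstitutionMatrix.score`."""
    return matrix.score(x, y)


def _parse_square_matrix(text: str) -> tuple[tuple[str, ...], dict]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise MatrixFormatError("no content lines in matrix file")
    header = tuple(tok.upper() for tok in lines[0].split())
    if any(len(t) != 1 for t in header):
        raise MatrixFormatError(f"header symbols must be single characters: {header}")
    if len(set(header)) != len(header):
        raise MatrixFormatError("duplicate symbol in matrix header")
    scores: dict[tuple[str, str], float] = {}
    seen_rows: set[str] = set()
    for ln in lines[1:]:
        toks = ln.split()
        row_sym = toks[0].upper()
        if row_sym in seen_rows:
            raise MatrixFormatError(f"duplicate row for symbol {row_sym!r}")
        if row_sym not in header:
            raise MatrixFormatError(f"row symbol {row_sym!r} not in header")
        seen_rows.add(row_sym)
        vals = toks[1:]
        if len(vals) != len(header):
            raise MatrixFormatError(
                f"row {row_sym!r} has {len(vals)} cells, expected {len(header)}"
            )
        for col_sym, v in zip(header, vals):
            try:
                scores[(row_sym, col_sym)] = float(v)
            except ValueError as exc:
                raise MatrixFormatError(
                    f"non-numeric cell ({row_sym}, {col_sym}): {v!r}"
                ) from exc
    missing = set(header) - seen_rows
    if missing:
        raise MatrixFormatError(f"missing rows for symbols: {sorted(missing)}")
    return header, scores


def load_substitution_matrix(
    path: str | Path,
    expect_symmetric: bool = True,
    exclude: Iterable[str] = (),
) -> SubstitutionMatrix:
    """Load a BLAST-style square substitution matrix from a text file.

    Parameters
    ----------
    path
        Matrix file: a header row of symbols, then one labeled row per
        symbol with whitespace-separated numbers; ``#`` lines are comments.
    expect_symmetric
        Verify S(x, y) == S(y, x) for every pair and raise
        :class:`MatrixSymmetryError` on violation.
    exclude
        Header symbols to drop (e.g. a gap or wildcard column the caller
        does not want in the alphabet).
    """
    text = Path(path).read_text()
    return loads_substitution_matrix(text, expect_symmetric=expect_symmetric, exclude=exclude)


def loads_substitution_matrix(
    text: str,
    expect_symmetric: bool = True,
    exclude: Iterable[str] = (),
) -> SubstitutionMatrix:
    """As :func:`load_substitution_matrix` but from an in-memory string."""
    header, scores = _parse_square_matrix(text)
    drop = {s.upper() for s in exclude} | {GAP, "*"}
    kept = tuple(s for s in header if s not in drop)
    if not kept:
        raise MatrixFormatError("no alphabet symbols left after exclusions")
    scores = {
        (x, y): v for (x, y), v in scores.items() if x in kept and y in kept
    }
    matrix = SubstitutionMatrix(StructureAlphabet(kept), scores)
    if expect_symmetric and not matrix.is_symmetric():
        bad = next(
            (x, y)
            for x in kept
            for y in kept
            if scores[(x, y)] != scores[(y, x)]
        )
        raise MatrixSymmetryError(
            f"scores{bad} = {scores[bad]} but scores{bad[::-1]} = {scores[bad[::-1]]}"
        )
    return matrix


def dump_substitution_matrix(matrix: SubstitutionMatrix, path: str | Path | None = None) -> str:
    """Serialize back to the BLAST-style square layout (round-trip safe)."""
    syms = matrix.alphabet.symbols
    buf = io.StringIO()
    buf.write("   " + "  ".join(syms) + "\n")
    for x in syms:
        cells = []
        for y in syms:
            v = matrix.scores[(x, y)]
            cells.append(f"{v:g}")
        buf.write(x + "  " + "  ".join(cells) + "\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def foldseek_3di_matrix() -> SubstitutionMatrix:
    """The Foldseek 3Di substitution matrix (20-state structural alphabet).

    Sourced from biotite's packaged copy of the matrix distributed with
    Foldseek; symbols are canonicalized to upper case.
    """
    import biotite.sequence.align as _align

    m = _align.SubstitutionMatrix.std_3di_matrix()
    syms = tuple(str(s).upper() for s in m.get_alphabet1())
    arr = m.score_matrix()
    scores = {
        (sx, sy): float(arr[i, j])
        for i, sx in enumerate(syms)
        for j, sy in enumerate(syms)
    }
    return SubstitutionMatrix(StructureAlphabet(syms), scores)
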