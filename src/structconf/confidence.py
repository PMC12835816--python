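"""Per-column confidence scoring of structure-aware alignments.

The raw confidence of column j is the sum of substitution scores over
adjacent row pairs:

    C_j = sum_{i=1}^{N-1} S(r_i, r_{i+1})

where r_i is the structural character of row i at column j and pairs in
which either member is a gap are excluded.  Raw scores are min-max scaled
within the alignment to [0, 1]:

    Chat_j = (C_j - C_min) / (C_max - C_min)

and their mean Chat_avg = (1/L) * sum_j Chat_j summarizes the whole
alignment.  Scoring only adjacent pairs keeps the cost linear in the row
count; because the row order is fixed, the score is deterministic for a
given input.  The all-versus-all sum-of-pairs alternative scales
quadratically and exists in this package only as a test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignio import Alignment
from .errors import (
    DegenerateNormalizationWarning,
    EmptyInputError,
    TooFewRowsError,
)
from .matrix import GAP, SubstitutionMatrix

DEFAULT_DROP_THRESHOLD = 0.5


@dataclass(frozen=True)
class ColumnConfidence:
    """Scores for one alignment column.

    ``index`` is 0-based (internal convention; user-facing tables are
    1-based).  ``dropped`` marks gap fraction strictly greater than the
    drop threshold.  ``valid_pairs`` counts gap-free adjacent row pairs;
    when it is 0 the raw score is 0 by convention and the column is still
    normalized alongside the others.
    """

    index: int
    raw: float
    valid_pairs: int
    normalized: float
    gap_fraction: float
    dropped: bool


@dataclass(frozen=True)
class ConfidenceProfile:
    """Full per-column profile plus alignment-level summaries."""

    columns: tuple[ColumnConfidence, ...]
    c_min: float
    c_max: float
    c_avg: float
    n_rows: int
    n_cols: int

    @property
    def raw(self) -> np.ndarray:
        return np.array([c.raw for c in self.columns])

    @property
    def normalized(self) -> np.ndarray:
        return np.array([c.normalized for c in self.columns])

    @property
    def gap_fractions(self) -> np.ndarray:
        return np.array([c.gap_fraction for c in self.columns])

    def to_dataframe(self) -> pd.DataFrame:
        """Per-column table with 1-based ``column_index`` for display."""
        return pd.DataFrame(
            {
                "column_index": [c.index + 1 for c in self.columns],
                "raw": [c.raw for c in self.columns],
                "valid_pairs": [c.valid_pairs for c in self.columns],
                "gap_fraction": [c.gap_fraction for c in self.columns],
                "normalized": [c.normalized for c in self.columns],
                "dropped": [c.dropped for c in self.columns],
            }
        )

    def summary(self) -> dict:
        dropped = sum(c.dropped for c in self.columns)
        return {
            "c_min": self.c_min,
            "c_max": self.c_max,
            "c_avg": self.c_avg,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "columns_total": self.n_cols,
            "columns_dropped": dropped,
            "columns_valid": self.n_cols - dropped,
        }


def raw_column_score(
    column: Sequence[str], matrix: SubstitutionMatrix
) -> tuple[float, int]:
    """Adjacent-pair raw score C_j and the count of gap-free pairs.

    Pairs in which either member is a gap contribute nothing; a column
    with no valid pair scores 0.  Unknown symbols are a hard error — a
    silent zero would corrupt the alignment's C_min/C_max.
    """
    n = len(column)
    if n < 2:
        raise TooFewRowsError("adjacent-pair scoring needs at least 2 rows")
    gap = matrix.alphabet.gap_symbol
    total = 0.0
    valid = 0
    for i in range(n - 1):
        a, b = column[i], column[i + 1]
        if a == gap or b == gap:
            continue
        total += matrix.score(a, b)
        valid += 1
    return total, valid


def normalize_scores(raws: Sequence[float]) -> list[float]:
    """Min-max scale raw scores into [0, 1] within the alignment.

    When every raw score is identical the scaling is undefined; every
    column then gets 0.5 and a :class:`DegenerateNormalizationWarning`
    is emitted.
    """
    if len(raws) == 0:
        raise EmptyInputError("no raw scores to normalize")
    arr = np.asarray(raws, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn(
            "all raw column scores identical; min-max normalization degenerate, "
            "assigning 0.5 to every column",
            DegenerateNormalizationWarning,
            stacklevel=2,
        )
        return [0.5] * len(arr)
    return list((arr - lo) / (hi - lo))


def compute_profile(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
    include_zero_pair_columns: bool = True,
) -> ConfidenceProfile:
    """Score every column and summarize the alignment.

    ``c_avg`` is the mean normalized score over all L columns of the full,
    untrimmed alignment.  ``include_zero_pair_columns`` controls whether
    columns without any gap-free adjacent pair (raw 0 by convention) enter
    the C_min/C_max extremes; they do by default, keeping L consistent
    with the averaging formula.  With the option off, extremes come from
    scoreable columns only and zero-pair columns are normalized against
    those extremes, clipped to [0, 1].
    """
    if aln.n_rows < 2:
        raise TooFewRowsError(
            f"alignment has {aln.n_rows} row(s); scoring needs at least 2"
        )
    raws: list[float] = []
    pairs: list[int] = []
    gapfracs: list[float] = []
    for j in range(aln.n_cols):
        col = aln.column(j)
        r, v = raw_column_score(col, matrix)
        raws.append(r)
        pairs.append(v)
        gapfracs.append(col.count(GAP) / len(col))

    raw_arr = np.asarray(raws)
    if include_zero_pair_columns or all(v > 0 for v in pairs):
        normalized = normalize_scores(raws)
        c_min, c_max = float(raw_arr.min()), float(raw_arr.max())
    else:
        scoreable = raw_arr[np.asarray(pairs) > 0]
        if scoreable.size == 0:
            raise EmptyInputError("no column has a gap-free adjacent pair")
        c_min, c_max = float(scoreable.min()), float(scoreable.max())
        if c_max == c_min:
            warnings.warn(
                "all scoreable raw scores identical; normalization degenerate",
                DegenerateNormalizationWarning,
                stacklevel=2,
            )
            normalized = [0.5] * len(raws)
        else:
            normalized = list(
                np.clip((raw_arr - c_min) / (c_max - c_min), 0.0, 1.0)
            )

    cols = tuple(
        ColumnConfidence(
            index=j,
            raw=float(raws[j]),
            valid_pairs=pairs[j],
            normalized=float(normalized[j]),
            gap_fraction=gapfracs[j],
            dropped=gapfracs[j] > drop_threshold,
        )
        for j in range(aln.n_cols)
    )
    return ConfidenceProfile(
        columns=cols,
        c_min=c_min,
        c_max=c_max,
        c_avg=float(np.mean(normalized)),
        n_rows=aln.n_rows,
        n_cols=aln.n_cols,
    )


def column_summary(
    aln: Alignment, drop_threshold: float = DEFAULT_DROP_THRESHOLD
) -> tuple[int, int, int]:
    """(total, valid, dropped) column counts.

    A column is dropped iff its gap fraction is strictly greater than
    ``drop_threshold`` — a 4-row column with exactly 2 gaps stays valid
    at the default 0.5 threshold.
    """
    total = aln.n_cols
    dropped = sum(
        1 for j in range(total) if aln.gap_fraction(j) > drop_threshold
    )
    return total, total - dropped, dropped
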