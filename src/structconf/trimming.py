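"""Column trimming: gap-fraction rule and confidence-threshold filters.

Two complementary filters operate on a scored alignment:

* ``gap_trim`` removes columns whose gap content exceeds 50% (strictly),
  the Gblocks-style rule used to expose the conserved structural core.
* ``confidence_filter`` keeps columns by normalized confidence, either
  ``retain_ge`` (inclusion: keep Chat_j >= t, discarding the noisiest
  columns first) or ``retain_lt`` (exclusion/negative control: keep
  Chat_j < t, discarding the strongest columns first).

``sweep`` applies the filter across a threshold grid, recording retained
column counts and the mean confidence of what remains — the raw material
of robustness/negative-control curves.  Mean confidences reuse the original
profile's normalized values; retained columns are not re-normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .alignio import Alignment
from .confidence import ConfidenceProfile
from .errors import EmptyResultError, InconsistentInputError

Mode = Literal["retain_ge", "retain_lt"]


@dataclass(frozen=True)
class TrimResult:
    """Retained columns (original row order) and where they came from.

    ``retained_indices`` are 0-based original column indices, strictly
    increasing.  ``mean_confidence_retained`` is the mean of the original
    profile's normalized scores over the retained columns, or None when no
    profile was supplied.
    """

    alignment: Alignment
    retained_indices: tuple[int, ...]
    mean_confidence_retained: float | None

    @property
    def n_cols(self) -> int:
        return len(self.retained_indices)


@dataclass(frozen=True)
class SweepPoint:
    threshold: float
    n_columns: int
    mean_confidence: float  # NaN when nothing retained
    retained_indices: tuple[int, ...]


@dataclass(frozen=True)
class SweepResult:
    mode: Mode
    points: tuple[SweepPoint, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": [p.threshold for p in self.points],
                "n_columns": [p.n_columns for p in self.points],
                "mean_confidence_retained": [p.mean_confidence for p in self.points],
            }
        )


def _mean_conf(profile: ConfidenceProfile, idx: Sequence[int]) -> float:
    if not idx:
        return math.nan
    return float(np.mean([profile.columns[j].normalized for j in idx]))


def gap_trim(
    aln: Alignment,
    max_gap_fraction: float = 0.5,
    profile: ConfidenceProfile | None = None,
) -> TrimResult:
    """Drop columns with gap fraction strictly above ``max_gap_fraction``.

    The boundary is inclusive on the keep side: a 4-row column with exactly
    2 gaps (fraction 0.5) is retained at the default threshold.  Idempotent.
    Raises :class:`EmptyResultError` if nothing survives.
    """
    keep = tuple(
        j for j in range(aln.n_cols) if aln.gap_fraction(j) <= max_gap_fraction
    )
    if not keep:
        raise EmptyResultError(
            f"gap trim at max_gap_fraction={max_gap_fraction} removed every column"
        )
    mean_conf = _mean_conf(profile, keep) if profile is not None else None
    return TrimResult(aln.take_columns(keep), keep, mean_conf)


def _check_profile(aln: Alignment, profile: ConfidenceProfile) -> None:
    if profile.n_cols != aln.n_cols or profile.n_rows != aln.n_rows:
        raise InconsistentInputError(
            f"profile is {profile.n_rows}x{profile.n_cols} but alignment is "
            f"{aln.n_rows}x{aln.n_cols}"
        )


def _retained(profile: ConfidenceProfile, t: float, mode: Mode) -> tuple[int, ...]:
    if mode == "retain_ge":
        return tuple(j for j, c in enumerate(profile.columns) if c.normalized >= t)
    if mode == "retain_lt":
        return tuple(j for j, c in enumerate(profile.columns) if c.normalized < t)
    raise ValueError(f"unknown mode {mode!r}")


def confidence_filter(
    aln: Alignment, profile: ConfidenceProfile, t: float, mode: Mode
) -> TrimResult:
    """Keep columns by normalized confidence against threshold ``t``.

    Boundary semantics: inclusion keeps Chat_j >= t, exclusion keeps
    Chat_j < t — the two modes partition the columns at every t.
    """
    _check_profile(aln, profile)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold t={t} outside [0, 1]")
    keep = _retained(profile, t, mode)
    if not keep:
        raise EmptyResultError(f"{mode} at t={t} retained no columns")
    return TrimResult(aln.take_columns(keep), keep, _mean_conf(profile, keep))


def default_grid(step: float = 0.05) -> list[float]:
    """Threshold grid 0.00..1.00 inclusive (21 points at the default step)."""
    n = round(1.0 / step)
    return [round(i * step, 10) for i in range(n + 1)]


def sweep(
    aln: Alignment,
    profile: ConfidenceProfile,
    grid: Sequence[float] | None = None,
    mode: Mode = "retain_ge",
) -> SweepResult:
    """Apply the confidence filter across an ascending threshold grid.

    Empty retained sets are recorded as zero-column points, not errors:
    a sweep is a diagnostic curve and its tail is informative.
    """
    _check_profile(aln, profile)
    grid = list(default_grid() if grid is None else grid)
    if grid != sorted(grid):
        raise ValueError("threshold grid must be sorted ascending")
    points = []
    for t in grid:
        keep = _retained(profile, t, mode)
        points.append(
            SweepPoint(
                threshold=float(t),
                n_columns=len(keep),
                mean_confidence=_mean_conf(profile, keep),
                retained_indices=keep,
            )
        )
    return SweepResult(mode=mode, points=tuple(points))
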