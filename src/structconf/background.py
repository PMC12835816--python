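"""Empirical background distributions of alignment confidence and Z-scores.

Although each alignment is min-max normalized independently, the mean
normalized confidence Chat_avg of many family alignments forms a meaningful
empirical distribution.  A user alignment's Chat_avg is standardized against
one or more such backgrounds (e.g. SCOP- and CATH-derived collections, one
per aligner):

    Z = (Chat_avg - mu) / sigma

and the mean Z over the supplied backgrounds (Z_avg) maps to a qualitative
category by statistical rarity:

    Z >= 2          Statistically Rare Alignment
    1 <= Z < 2      Above Average, Less Common
    -1 < Z < 1      Common, Expected Range
    -2 < Z <= -1    Below Average, Less Common
    Z <= -2         Statistically Rare Alignment

No default background ships with the package: published reference values
are collection-specific, so users either load a JSON config of labeled
{mu, sigma, n} entries or build one from a directory of alignments.
Assessments carry the background labels so a rebuilt background can never
be mistaken for someone else's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignio import Alignment, StructureAwareSequence, read_alignment
from .confidence import compute_profile
from .errors import DegenerateBackgroundError, MissingBackgroundError
from .matrix import SubstitutionMatrix

#: Families larger than this are subsampled to their longest members.
FAMILY_SIZE_CAP = 300
#: Qualification thresholds for background membership.
MIN_ROWS = 10
MIN_COLS = 100

CATEGORY_RARE = "Statistically Rare Alignment"
CATEGORY_ABOVE = "Above Average, Less Common"
CATEGORY_COMMON = "Common, Expected Range"
CATEGORY_BELOW = "Below Average, Less Common"


@dataclass(frozen=True)
class BackgroundDistribution:
    """Mean/spread of Chat_avg over a labeled alignment collection."""

    label: str
    mu: float
    sigma: float
    n: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise DegenerateBackgroundError(
                f"background {self.label!r} has sigma={self.sigma} (must be > 0)"
            )
        if self.n < 2:
            raise DegenerateBackgroundError(
                f"background {self.label!r} built from n={self.n} (< 2) alignments"
            )

    def z(self, c_avg: float) -> float:
        return (c_avg - self.mu) / self.sigma


@dataclass(frozen=True)
class ZAssessment:
    """Z-scores of one alignment against each background, plus the category."""

    c_avg: float
    z_per_background: tuple[tuple[str, float], ...]
    z_avg: float
    category: str

    def to_dict(self) -> dict:
        return {
            "c_avg": self.c_avg,
            "z_per_background": {label: z for label, z in self.z_per_background},
            "z_avg": self.z_avg,
            "category": self.category,
        }


def subsample_family(
    seqs: Sequence[StructureAwareSequence], cap: int = FAMILY_SIZE_CAP
) -> list[StructureAwareSequence]:
    """Cap a family at its ``cap`` longest members.

    Families at or under the cap pass through unchanged.  Larger families
    keep the ``cap`` longest sequences (ties broken by lexicographically
    smaller id), returned in their original relative order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    seqs = list(seqs)
    if len(seqs) <= cap:
        return seqs
    ranked = sorted(seqs, key=lambda s: (-len(s), s.id))
    chosen = {id(s) for s in ranked[:cap]}
    return [s for s in seqs if id(s) in chosen]


def qualifies(
    aln: Alignment, min_rows: int = MIN_ROWS, min_cols: int = MIN_COLS
) -> bool:
    """True iff the alignment has at least ``min_rows`` rows and ``min_cols`` columns."""
    return aln.n_rows >= min_rows and aln.n_cols >= min_cols


def build_background(
    c_avgs: Sequence[float], label: str
) -> BackgroundDistribution:
    """Fit mu (mean) and sigma (sample sd, n-1 denominator) to a collection's Chat_avg values."""
    vals = np.asarray(list(c_avgs), dtype=float)
    if vals.size < 2:
        raise DegenerateBackgroundError(
            f"background {label!r} needs >= 2 alignments, got {vals.size}"
        )
    sigma = float(vals.std(ddof=1))
    if sigma == 0:
        raise DegenerateBackgroundError(
            f"background {label!r} has zero variance across {vals.size} alignments"
        )
    return BackgroundDistribution(
        label=label, mu=float(vals.mean()), sigma=sigma, n=int(vals.size)
    )


def build_background_from_dir(
    aln_dir: str | Path,
    matrix: SubstitutionMatrix,
    label: str,
    min_rows: int = MIN_ROWS,
    min_cols: int = MIN_COLS,
) -> BackgroundDistribution:
    """Score every qualifying alignment in a directory and fit a background.

    Files are taken in sorted-name order; alignments failing the row/column
    qualification thresholds are silently excluded (mirroring benchmark
    curation).
    """
    c_avgs = []
    paths = sorted(
        p
        for p in Path(aln_dir).iterdir()
        if p.suffix.lower() in (".aln", ".clustal", ".fa", ".fasta", ".afa")
    )
    for p in paths:
        aln = read_alignment(p)
        if not qualifies(aln, min_rows=min_rows, min_cols=min_cols):
            continue
        c_avgs.append(compute_profile(aln, matrix).c_avg)
    return build_background(c_avgs, label)


def categorize(z_avg: float) -> str:
    """Map an average Z-score to its qualitative rarity category.

    Boundaries (inclusive/exclusive ends as listed in the module docstring):
    +/-2 belong to the rare category, -1 to "Below Average", +1 to
    "Above Average".  Values within 1e-9 of a boundary are snapped to it so
    that float round-off in (c_avg - mu) / sigma cannot flip a category
    whose exact-arithmetic value sits on the boundary.
    """
    for b in (-2.0, -1.0, 1.0, 2.0):
        if abs(z_avg - b) < 1e-9:
            z_avg = b
            break
    if z_avg >= 2 or z_avg <= -2:
        return CATEGORY_RARE
    if 1 <= z_avg < 2:
        return CATEGORY_ABOVE
    if -2 < z_avg <= -1:
        return CATEGORY_BELOW
    return CATEGORY_COMMON


def assess(
    c_avg: float, backgrounds: Sequence[BackgroundDistribution]
) -> ZAssessment:
    """Standardize a Chat_avg against each background and categorize Z_avg."""
    if not backgrounds:
        raise MissingBackgroundError("at least one background distribution is required")
    zs = tuple((b.label, b.z(c_avg)) for b in backgrounds)
    z_avg = float(np.mean([z for _, z in zs]))
    return ZAssessment(
        c_avg=c_avg, z_per_background=zs, z_avg=z_avg, category=categorize(z_avg)
    )


def save_backgrounds(
    backgrounds: Sequence[BackgroundDistribution], path: str | Path
) -> None:
    payload = [
        {"label": b.label, "mu": b.mu, "sigma": b.sigma, "n": b.n}
        for b in backgrounds
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_backgrounds(path: str | Path) -> list[BackgroundDistribution]:
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, dict):
        raw = [raw]
    return [
        BackgroundDistribution(
            label=e["label"], mu=float(e["mu"]), sigma=float(e["sigma"]), n=int(e["n"])
        )
        for e in raw
    ]
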