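"""Deterministic synthetic fixtures: alignments, family collections, CA traces.

These generators stand in for curated structural-family collections and
case-study inputs so every layer of the package is exercisable without
downloads or external tools.  An alignment column is either "conserved"
(one symbol repeated down all rows, with probability ``conservation``) or
free (symbols drawn independently and uniformly); gaps are then introduced
per cell at ``gap_rate``.  Raising conservation raises confidence; raising
the gap rate lowers it — the qualitative behaviour of real family
alignments — but no attempt is made to simulate realistic 3Di evolution
or fold divergence.

Everything is a pure function of (spec, seed) via a single explicitly
seeded generator; no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .alignio import Alignment, StructureAwareSequence, write_alignment
from .errors import SynthSpecError
from .matrix import GAP, StructureAlphabet

#: Foldseek's 20-state 3Di alphabet (canonical upper case).
DEFAULT_ALPHABET = StructureAlphabet(tuple("ACDEFGHIKLMNPQRSTVWY"))

CA_CA_DISTANCE = 3.8


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic alignment."""

    n_rows: int
    n_cols: int
    conservation: float = 0.5
    gap_rate: float = 0.05
    alphabet: StructureAlphabet = field(default=DEFAULT_ALPHABET)
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 2:
            raise SynthSpecError(f"n_rows={self.n_rows} < 2")
        if self.n_cols < 1:
            raise SynthSpecError(f"n_cols={self.n_cols} < 1")
        for name in ("conservation", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthSpecError(f"{name}={v} outside [0, 1]")


def make_alignment(spec: SynthSpec) -> Alignment:
    """Generate a seeded synthetic alignment of exactly (n_rows, n_cols)."""
    rng = np.random.default_rng(spec.seed)
    symbols = np.array(spec.alphabet.symbols)
    cols = np.empty((spec.n_cols, spec.n_rows), dtype="<U1")
    for j in range(spec.n_cols):
        if rng.random() < spec.conservation:
            cols[j, :] = rng.choice(symbols)
        else:
            cols[j, :] = rng.choice(symbols, size=spec.n_rows)
    if spec.gap_rate > 0:
        gap_mask = rng.random((spec.n_cols, spec.n_rows)) < spec.gap_rate
        cols[gap_mask] = GAP
    rows = tuple(
        (f"seq{i + 1}", "".join(cols[:, i])) for i in range(spec.n_rows)
    )
    return Alignment(rows)


def make_family_collection(
    out_dir: str | Path,
    k_families: int = 20,
    seed: int = 0,
    n_rows_range: tuple[int, int] = (10, 20),
    n_cols_range: tuple[int, int] = (100, 160),
    conservation_range: tuple[float, float] = (0.3, 0.9),
    gap_rate_range: tuple[float, float] = (0.0, 0.2),
    n_row_violators: int = 0,
    n_col_violators: int = 0,
) -> dict:
    """Write ``k_families`` Clustal alignments plus a manifest to a directory.

    The first ``n_row_violators`` families are generated with too few rows
    and the next ``n_col_violators`` with too few columns, deliberately
    failing the background qualification thresholds; the manifest records
    which rule each family violates so filter behaviour can be checked
    against ground truth.  Returns the manifest (also written as
    ``manifest.json``).
    """
    if k_families < 2:
        raise SynthSpecError(f"k_families={k_families} < 2")
    if n_row_violators + n_col_violators > k_families:
        raise SynthSpecError("more violators requested than families")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(k_families):
        violates: list[str] = []
        n_rows = int(rng.integers(n_rows_range[0], n_rows_range[1] + 1))
        n_cols = int(rng.integers(n_cols_range[0], n_cols_range[1] + 1))
        if i < n_row_violators:
            n_rows = max(2, n_rows_range[0] - 1)
            violates.append("min_rows")
        elif i < n_row_violators + n_col_violators:
            n_cols = max(1, n_cols_range[0] - 1)
            violates.append("min_cols")
        spec = SynthSpec(
            n_rows=n_rows,
            n_cols=n_cols,
            conservation=float(rng.uniform(*conservation_range)),
            gap_rate=float(rng.uniform(*gap_rate_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        name = f"family{i + 1:03d}"
        path = out_dir / f"{name}.aln"
        write_alignment(make_alignment(spec), path, format="clustal")
        entries.append(
            {
                "name": name,
                "file": path.name,
                "n_rows": spec.n_rows,
                "n_cols": spec.n_cols,
                "conservation": spec.conservation,
                "gap_rate": spec.gap_rate,
                "seed": spec.seed,
                "violates": violates,
            }
        )
    manifest = {"k_families": k_families, "seed": seed, "families": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def make_toy_structure(
    seq: StructureAwareSequence, seed: int = 0
) -> gemmi.Structure:
    """Straight-line CA trace with one residue per sequence character.

    Consecutive CA-CA distances are exactly 3.8 (the trans-peptide
    convention); the chain direction is seeded.  Geometry is deliberately
    unrealistic — the trace only needs to exercise structure I/O and
    column-to-residue mapping, since structural-alphabet encoding of real
    geometry is out of scope.  All B-factors start at 0.00.
    """
    if len(seq) == 0:
        raise SynthSpecError("sequence is empty")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    st = gemmi.Structure()
    st.name = seq.id
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for k in range(len(seq)):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(k + 1, " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        pos = direction * CA_CA_DISTANCE * k
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def make_planted_pairs_alignment(
    pair_ids: Sequence[tuple[str, str]] = (("A1", "A2"), ("B1", "B2"), ("C1", "C2")),
    n_signal_cols: int = 70,
    n_noise_cols: int = 30,
    within_pair_identity: float = 0.95,
    alphabet: StructureAlphabet = DEFAULT_ALPHABET,
    seed: int = 0,
) -> tuple[Alignment, dict[str, list[str]]]:
    """Alignment with a planted pairwise ground truth, plus the partition.

    Rows come in named pairs (adjacent in the alignment, one pair after
    another).  In a signal column each pair draws its own symbol, shared by
    both members with probability ``within_pair_identity``; pairs are
    independent, so signal columns separate the pairs.  Noise columns are
    uniform random per row.  Mimics, at desk scale, a divergent-family
    alignment whose phylogenetic signal lives in the high-confidence
    columns: trees inferred from signal-rich subsets should recover every
    pair as monophyletic, trees from noise-only subsets should not.

    Returns the alignment and a {pair_name: [member ids]} partition dict
    (pair name = the ids joined with '+').
    """
    if len(pair_ids) < 2:
        raise SynthSpecError("need at least two pairs for a meaningful topology")
    rng = np.random.default_rng(seed)
    symbols = np.array(alphabet.symbols)
    members = [m for pair in pair_ids for m in pair]
    cols: list[dict[str, str]] = []
    for _ in range(n_signal_cols):
        col = {}
        for pair in pair_ids:
            s = str(rng.choice(symbols))
            for m in pair:
                col[m] = (
                    s
                    if rng.random() < within_pair_identity
                    else str(rng.choice(symbols))
                )
        cols.append(col)
    for _ in range(n_noise_cols):
        cols.append({m: str(rng.choice(symbols)) for m in members})
    rows = tuple((m, "".join(c[m] for c in cols)) for m in members)
    partition = {"+".join(pair): list(pair) for pair in pair_ids}
    return Alignment(rows), partition


def gap_rate_gradient_specs(
    n_alignments: int = 10,
    gap_rates: Sequence[float] | None = None,
    n_rows: int = 12,
    n_cols: int = 120,
    conservation: float = 0.6,
    seed: int = 0,
) -> list[SynthSpec]:
    """Specs for a gap-rate gradient at otherwise fixed conditions.

    Used to reproduce, at desk scale, the negative association between an
    alignment's overall gap fraction and its mean confidence.
    """
    if gap_rates is None:
        gap_rates = np.linspace(0.0, 0.45, n_alignments)
    rng = np.random.default_rng(seed)
    return [
        SynthSpec(
            n_rows=n_rows,
            n_cols=n_cols,
            conservation=conservation,
            gap_rate=float(g),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for g in gap_rates
    ]
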