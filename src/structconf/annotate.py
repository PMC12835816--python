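"""Column-to-residue mapping and B-factor encoding of confidence.

The k-th non-gap character of an alignment row corresponds to residue
ordinal k of the chain the row was derived from (structural-alphabet
strings are generated in file order, one character per polymer residue).
Normalized column confidence is written into the B-factor field —
scaled to 0..100 by default so conventional B-factor color ramps resolve
the full range — turning any structure viewer into a confidence map.

Single-chain structures only: one row maps to one chain.  mmCIF is the
primary format, PDB secondary; both go through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi

from .alignio import Alignment
from .confidence import ConfidenceProfile
from .errors import InconsistentInputError, MappingMismatchError
from .matrix import GAP

DEFAULT_BFACTOR_SCALE = 100.0
DEFAULT_BFACTOR = 0.0


@dataclass(frozen=True)
class ResidueMapping:
    """(column, residue ordinal) pairs for each non-gap character of a row.

    Both coordinates are 1-based and strictly increasing; the pair count
    equals the row's non-gap character count.
    """

    row_id: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def n_residues(self) -> int:
        return len(self.pairs)

    def column_of(self, residue_ordinal: int) -> int:
        """1-based column for a 1-based residue ordinal."""
        for col, k in self.pairs:
            if k == residue_ordinal:
                return col
        raise KeyError(f"residue ordinal {residue_ordinal} not in mapping")


def map_row_to_residues(aln: Alignment, row_id: str) -> ResidueMapping:
    """Map a row's non-gap characters to consecutive residue ordinals.

    An all-gap row yields an empty mapping (nothing to annotate).
    """
    seq = aln.row(row_id)  # KeyError -> lookup error for unknown ids
    pairs = []
    k = 0
    for j, ch in enumerate(seq):
        if ch == GAP:
            continue
        k += 1
        pairs.append((j + 1, k))
    return ResidueMapping(row_id=row_id, pairs=tuple(pairs))


def read_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def write_structure(st: gemmi.Structure, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def _polymer_residues(chain: gemmi.Chain) -> list[gemmi.Residue]:
    # file order; waters and ligands (HETATM) are not polymer positions
    return [res for res in chain if res.het_flag == "A"]


def annotate_bfactors(
    structure: gemmi.Structure,
    profile: ConfidenceProfile,
    mapping: ResidueMapping,
    scale: float = DEFAULT_BFACTOR_SCALE,
) -> gemmi.Structure:
    """Return a copy with per-residue confidence written into B-factors.

    Every atom of polymer residue k gets ``round(scale * Chat_j, 2)``
    where j is the alignment column mapped to k; unmapped polymer
    residues and all hetero/solvent atoms get 0.00.  The input structure
    must contain exactly one chain whose polymer length covers the
    mapping's largest residue ordinal.
    """
    st = structure.clone()
    if len(st) == 0:
        raise MappingMismatchError("structure has no models")
    model = st[0]
    if len(model) != 1:
        raise MappingMismatchError(
            f"expected a single-chain structure, found {len(model)} chains; "
            "extract the chain of interest first"
        )
    chain = model[0]
    polymer = _polymer_residues(chain)
    max_ordinal = max((k for _, k in mapping.pairs), default=0)
    if max_ordinal > len(polymer):
        raise MappingMismatchError(
            f"row {mapping.row_id!r} maps {max_ordinal} residues but chain "
            f"{chain.name!r} has only {len(polymer)} polymer residues"
        )
    col_by_ordinal = {k: col for col, k in mapping.pairs}
    for col, _ in mapping.pairs:
        if not 1 <= col <= profile.n_cols:
            raise InconsistentInputError(
                f"mapping column {col} outside profile length {profile.n_cols}"
            )
    # default everything first (hetero, solvent, unmapped)
    for res in chain:
        for atom in res:
            atom.b_iso = DEFAULT_BFACTOR
    for k, res in enumerate(polymer, start=1):
        col = col_by_ordinal.get(k)
        if col is None:
            continue
        b = round(scale * profile.columns[col - 1].normalized, 2)
        for atom in res:
            atom.b_iso = b
    return st


def annotated_bfactor_count(
    st: gemmi.Structure, default: float = DEFAULT_BFACTOR
) -> int:
    """Number of polymer residues carrying a non-default B-factor."""
    chain = st[0][0]
    return sum(
        1
        for res in _polymer_residues(chain)
        if any(atom.b_iso != default for atom in res)
    )
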