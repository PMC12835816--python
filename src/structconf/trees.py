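"""Monophyly and bootstrap-support diagnostics against a ground-truth partition.

Trees inferred from trimmed alignments (e.g. by IQ-TREE with ultrafast
bootstrap) are checked for whether each expected group of tips is
monophyletic and, if so, how well supported the corresponding edge is.
Monophyly is defined on the unrooted tree: a tip set is monophyletic iff
the bipartition (tips | all-tips) exists as an edge, so verdicts are
invariant under re-rooting and need no outgroup.

Support values are read from internal-node labels, the convention used by
IQ-TREE's ultrafast bootstrap; tree inference itself is external and this
module only consumes Newick text.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from .alignio import Alignment, write_alignment
from .confidence import ConfidenceProfile
from .errors import CoverageError, EmptyResultError, NonNumericSupportWarning, UnknownTipError
from .trimming import Mode, confidence_filter


@dataclass(frozen=True)
class GroundTruthPartition:
    """Named, disjoint tip-label sets expected to be monophyletic."""

    clades: tuple[tuple[str, frozenset[str]], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]]) -> "GroundTruthPartition":
        clades = tuple((name, frozenset(tips)) for name, tips in d.items())
        seen: set[str] = set()
        for name, tips in clades:
            if not tips:
                raise CoverageError(f"clade {name!r} is empty")
            if seen & tips:
                raise CoverageError(f"clade {name!r} overlaps another clade")
            seen |= tips
        return cls(clades)

    @property
    def all_tips(self) -> frozenset[str]:
        out: set[str] = set()
        for _, tips in self.clades:
            out |= tips
        return frozenset(out)


@dataclass(frozen=True)
class CladeStatus:
    name: str
    monophyletic: bool
    support: float | None


@dataclass(frozen=True)
class TreeDiagnostics:
    per_clade: tuple[CladeStatus, ...]
    overall_correct: bool

    @property
    def min_support(self) -> float | None:
        """Minimum support over clades that are monophyletic and labeled."""
        vals = [c.support for c in self.per_clade if c.support is not None]
        return min(vals) if vals else None

    def to_dict(self) -> dict:
        return {
            "clades": [
                {"name": c.name, "monophyletic": c.monophyletic, "support": c.support}
                for c in self.per_clade
            ],
            "overall_correct": self.overall_correct,
            "min_support": self.min_support,
        }


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        return dendropy.Tree.get(path=str(source), schema="newick")
    return dendropy.Tree.get(data=source, schema="newick")


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _parse_support(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        warnings.warn(
            f"internal node label {label!r} is not numeric; support treated as absent",
            NonNumericSupportWarning,
            stacklevel=3,
        )
        return None


def clade_status(
    tree: dendropy.Tree | str, tips: Sequence[str] | frozenset[str]
) -> tuple[bool, float | None]:
    """Whether ``tips`` form an edge-bipartition of the unrooted tree.

    Returns (monophyletic, support); support is the numeric internal-node
    label on the separating edge when present.  Singleton tip sets and the
    full tip set are trivially monophyletic with absent support.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    tips = frozenset(tips)
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = tips - all_tips
    if missing:
        raise UnknownTipError(f"tips not in tree: {sorted(missing)}")
    if len(tips) in (1, len(all_tips)):
        return True, None
    complement = all_tips - tips
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = _leaf_labels(node)
        if below == tips or below == complement:
            return True, _parse_support(node)
    return False, None


def evaluate_ground_truth(
    tree: dendropy.Tree | str, partition: GroundTruthPartition
) -> TreeDiagnostics:
    """Check every expected clade; overall_correct iff all are monophyletic."""
    if isinstance(tree, str):
        tree = read_tree(tree)
    tree_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    expected = partition.all_tips
    if tree_tips != expected:
        raise CoverageError(
            f"partition tips and tree tips differ: only-in-partition="
            f"{sorted(expected - tree_tips)}, only-in-tree={sorted(tree_tips - expected)}"
        )
    statuses = []
    for name, tips in partition.clades:
        mono, support = clade_status(tree, tips)
        statuses.append(CladeStatus(name=name, monophyletic=mono, support=support))
    return TreeDiagnostics(
        per_clade=tuple(statuses),
        overall_correct=all(s.monophyletic for s in statuses),
    )


@dataclass(frozen=True)
class CaseStudyPoint:
    threshold: float
    n_columns: int
    diagnostics: TreeDiagnostics | None  # None when nothing retained


def run_case_study(
    aln: Alignment,
    profile: ConfidenceProfile,
    partition: GroundTruthPartition,
    tree_cmd: str,
    grid: Sequence[float],
    mode: Mode = "retain_ge",
    workdir: str | Path | None = None,
) -> list[CaseStudyPoint]:
    """Sweep-then-infer-then-check loop around an external tree program.

    ``tree_cmd`` is a shell template with ``{aln}`` and ``{tree}``
    placeholders, e.g. ``"fasttree -lg {aln} > {tree}"``.  Thresholds whose
    retained set is empty are recorded with no diagnostics.  This is thin
    orchestration plumbing; all verdict logic lives in
    :func:`evaluate_ground_truth`.
    """
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="casestudy_"))
    base.mkdir(parents=True, exist_ok=True)
    points: list[CaseStudyPoint] = []
    for t in grid:
        try:
            trim = confidence_filter(aln, profile, t, mode)
        except EmptyResultError:
            points.append(CaseStudyPoint(float(t), 0, None))
            continue
        aln_path = base / f"trimmed_t{t:.2f}.fasta"
        tree_path = base / f"tree_t{t:.2f}.nwk"
        write_alignment(trim.alignment, aln_path, format="fasta")
        subprocess.run(
            tree_cmd.format(aln=aln_path, tree=tree_path),
            shell=True,
            check=True,
            capture_output=True,
        )
        diag = evaluate_ground_truth(read_tree(tree_path), partition)
        points.append(CaseStudyPoint(float(t), trim.n_cols, diag))
    return points
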