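import random

import dendropy
import pytest

from structconf import (
    Alignment,
    GroundTruthPartition,
    clade_status,
    compute_profile,
    evaluate_ground_truth,
    read_tree,
    run_case_study,
)
from structconf.errors import (
    CoverageError,
    NonNumericSupportWarning,
    UnknownTipError,
)

THREE_PAIRS = "((A1,A2)95,(B1,B2)88,(C1,C2)91);"
SCRAMBLED = "((A1,B1),(A2,B2),(C1,C2));"
PARTITION = GroundTruthPartition.from_dict(
    {"A": ["A1", "A2"], "B": ["B1", "B2"], "C": ["C1", "C2"]}
)


def _random_newick(labels, rng):
    labels = list(labels)
    if len(labels) == 1:
        return labels[0]
    rng.shuffle(labels)
    k = rng.randint(1, len(labels) - 1)
    return f"({_random_newick(labels[:k], rng)},{_random_newick(labels[k:], rng)})"


def _mrca_oracle(newick, tips):
    """Independent monophyly oracle: root at an outside tip, compare MRCA leafset."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    others = sorted(all_tips - tips)
    if not others or len(tips) == 1:
        return True
    out_leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == others[0]
    )
    tree.reroot_at_edge(out_leaf.edge)
    taxa = [t for t in tree.taxon_namespace if t.label in tips]
    mrca = tree.mrca(taxa=taxa)
    return {lf.taxon.label for lf in mrca.leaf_iter()} == tips


def test_literal_clade_with_support():
    assert clade_status(THREE_PAIRS, {"A1", "A2"}) == (True, 95.0)


def test_non_clade_in_scrambled_tree():
    assert clade_status(SCRAMBLED, {"A1", "A2"}) == (False, None)


def test_singleton_and_full_sets_trivially_monophyletic():
    assert clade_status(THREE_PAIRS, {"A1"}) == (True, None)
    tips = {"A1", "A2", "B1", "B2", "C1", "C2"}
    assert clade_status(THREE_PAIRS, tips) == (True, None)


def test_unknown_tip_raises():
    with pytest.raises(UnknownTipError, match="Z9"):
        clade_status(THREE_PAIRS, {"A1", "Z9"})


def test_complement_symmetry():
    tips = {"A1", "A2"}
    complement = {"B1", "B2", "C1", "C2"}
    assert clade_status(THREE_PAIRS, tips)[0] == clade_status(THREE_PAIRS, complement)[0]
    assert clade_status(SCRAMBLED, tips)[0] == clade_status(SCRAMBLED, complement)[0]


def test_non_numeric_support_label_warns():
    with pytest.warns(NonNumericSupportWarning):
        mono, support = clade_status("((A1,A2)foo,(B1,B2),(C1,C2));", {"A1", "A2"})
    assert mono and support is None


def test_evaluate_correct_tree():
    diag = evaluate_ground_truth(THREE_PAIRS, PARTITION)
    assert diag.overall_correct
    assert [c.support for c in diag.per_clade] == [95.0, 88.0, 91.0]
    assert diag.min_support == 88.0


def test_evaluate_detects_broken_clades():
    diag = evaluate_ground_truth(SCRAMBLED, PARTITION)
    flags = {c.name: c.monophyletic for c in diag.per_clade}
    assert flags == {"A": False, "B": False, "C": True}
    assert not diag.overall_correct


def test_missing_tip_is_a_coverage_error():
    with pytest.raises(CoverageError, match="C2"):
        evaluate_ground_truth("((A1,A2),(B1,B2),C1);", PARTITION)


def test_overlapping_partition_rejected():
    with pytest.raises(CoverageError):
        GroundTruthPartition.from_dict({"A": ["x", "y"], "B": ["y", "z"]})


def test_monophyly_invariant_under_all_rerootings():
    """Verdicts agree with an MRCA-based oracle under every rooting of random 8-tip trees."""
    rng = random.Random(7)
    labels = [f"t{i}" for i in range(8)]
    for rep in range(10):
        newick = _random_newick(labels, rng) + ";"
        tips = frozenset(rng.sample(labels, rng.randint(2, 4)))
        expected = _mrca_oracle(newick, tips)
        base = read_tree(newick)
        n_edges = len(base.edges())
        for i in range(n_edges):
            tree = read_tree(newick)
            edge = tree.edges()[i]
            if edge.head_node.parent_node is None:
                continue
            tree.reroot_at_edge(edge)
            assert clade_status(tree, tips)[0] == expected, (newick, sorted(tips), i)


def test_case_study_orchestration_with_stub_tree_command(
    toy_matrix, tmp_path
):
    """The sweep->infer->check loop wired to a stand-in external command."""
    rows = tuple(
        (rid, seq)
        for rid, seq in [
            ("A1", "AAABBB"),
            ("A2", "AAABBB"),
            ("B1", "BBBAAA"),
            ("B2", "BBBAAA"),
            ("C1", "CCCCCC"),
            ("C2", "CCCCCA"),
        ]
    )
    aln = Alignment(rows)
    profile = compute_profile(aln, toy_matrix)
    fixture_tree = tmp_path / "fixed.nwk"
    fixture_tree.write_text(THREE_PAIRS + "\n")
    points = run_case_study(
        aln,
        profile,
        PARTITION,
        tree_cmd=f"cp {fixture_tree} {{tree}}",
        grid=[0.0, 1.0],
        mode="retain_ge",
        workdir=tmp_path / "work",
    )
    assert points[0].n_columns == 6
    assert points[0].diagnostics.overall_correct
    assert points[0].diagnostics.min_support == 88.0
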