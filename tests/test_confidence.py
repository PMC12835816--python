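import numpy as np
import pytest

from structconf import (
    Alignment,
    SynthSpec,
    column_summary,
    compute_profile,
    make_alignment,
    normalize_scores,
    raw_column_score,
)
from structconf.errors import (
    DegenerateNormalizationWarning,
    EmptyInputError,
    TooFewRowsError,
    UnknownSymbolError,
)
from .conftest import adjacent_pair_oracle


@pytest.mark.parametrize(
    "column, expected",
    [
        (("A", "A", "A"), (4, 2)),   # two identical pairs at +2
        (("A", "-", "A"), (0, 0)),   # both adjacent pairs touch the gap
        (("A", "B", "A"), (-2, 2)),  # S(A,B) + S(B,A) = -1 + -1
        (("A", "B", "-", "B"), (-1, 1)),
    ],
)
def test_raw_score_hand_examples(column, expected, toy_matrix):
    assert raw_column_score(column, toy_matrix) == expected


def test_raw_score_requires_two_rows(toy_matrix):
    with pytest.raises(TooFewRowsError):
        raw_column_score(("A",), toy_matrix)


def test_raw_score_unknown_symbol_is_hard_error(toy_matrix):
    with pytest.raises(UnknownSymbolError):
        raw_column_score(("A", "Z"), toy_matrix)


def test_raw_score_matches_brute_force_oracle_on_random_columns(
    toy_matrix, matrix_3di
):
    """Implementation vs independent adjacent-pair loop, 1000 random columns."""
    rng = np.random.default_rng(42)
    for matrix in (toy_matrix, matrix_3di):
        pool = list(matrix.alphabet.symbols) + ["-"] * 3
        for _ in range(500):
            n = rng.integers(2, 12)
            col = tuple(rng.choice(pool, size=n))
            assert raw_column_score(col, matrix) == adjacent_pair_oracle(col, matrix)


@pytest.mark.parametrize(
    "raws, expected",
    [
        ([4, -2, 1], [1.0, 0.0, 0.5]),
        ([0, 10], [0.0, 1.0]),
    ],
)
def test_min_max_normalization(raws, expected):
    assert normalize_scores(raws) == pytest.approx(expected)


def test_degenerate_normalization_gives_midpoint_with_warning():
    with pytest.warns(DegenerateNormalizationWarning):
        assert normalize_scores([3, 3, 3]) == [0.5, 0.5, 0.5]


def test_normalize_empty_input_rejected():
    with pytest.raises(EmptyInputError):
        normalize_scores([])


def test_worked_example_profile(toy_alignment, toy_matrix):
    """3x3 toy alignment: raws, normalized and average all hand-derivable."""
    p = compute_profile(toy_alignment, toy_matrix)
    assert list(p.raw) == [4, 1, 0]
    assert list(p.normalized) == pytest.approx([1.0, 0.25, 0.0])
    assert p.c_avg == pytest.approx(1.25 / 3, abs=1e-9)
    assert (p.c_min, p.c_max) == (0, 4)
    assert [c.valid_pairs for c in p.columns] == [2, 2, 0]
    assert [c.gap_fraction for c in p.columns] == [0, 0, pytest.approx(1 / 3)]


def test_single_row_alignment_rejected(toy_matrix):
    with pytest.raises(TooFewRowsError):
        compute_profile(Alignment((("s1", "AAA"),)), toy_matrix)


def test_identical_rows_give_degenerate_profile(toy_matrix):
    aln = Alignment((("s1", "AAAA"), ("s2", "AAAA")))
    with pytest.warns(DegenerateNormalizationWarning):
        p = compute_profile(aln, toy_matrix)
    assert set(p.normalized) == {0.5}


def test_zero_pair_columns_configurable_out_of_extremes(toy_alignment, toy_matrix):
    p = compute_profile(toy_alignment, toy_matrix, include_zero_pair_columns=False)
    # extremes from scoreable columns only: raw 4 and 1
    assert (p.c_min, p.c_max) == (1, 4)
    assert list(p.normalized) == pytest.approx([1.0, 0.0, 0.0])  # col3 clipped


def test_normalized_bounds_and_endpoint_attainment(matrix_3di):
    aln = make_alignment(SynthSpec(n_rows=8, n_cols=60, conservation=0.5, seed=11))
    p = compute_profile(aln, matrix_3di)
    norm = p.normalized
    assert np.all((norm >= 0) & (norm <= 1))
    assert norm.min() == 0.0 and norm.max() == 1.0


def test_row_reversal_leaves_raw_scores_unchanged(matrix_3di):
    """Symmetric matrix => reversing row order preserves every adjacent-pair sum."""
    aln = make_alignment(SynthSpec(n_rows=7, n_cols=40, gap_rate=0.15, seed=3))
    rev = Alignment(tuple(reversed(aln.rows)))
    p1 = compute_profile(aln, matrix_3di)
    p2 = compute_profile(rev, matrix_3di)
    assert list(p1.raw) == list(p2.raw)


def test_general_row_permutation_can_change_raw_scores(toy_matrix):
    """Regression: adjacent-pair scoring depends on row order beyond reversal."""
    aln = Alignment((("s1", "A"), ("s2", "A"), ("s3", "B")))
    swapped = Alignment((("s1", "A"), ("s3", "B"), ("s2", "A")))
    r1, _ = raw_column_score(aln.column(0), toy_matrix)
    r2, _ = raw_column_score(swapped.column(0), toy_matrix)
    assert r1 == 1 and r2 == -2  # (2 - 1) vs (-1 - 1)


def test_gapping_a_character_never_increases_valid_pairs(toy_matrix):
    col = ["A", "A", "B", "A", "A"]
    _, base_pairs = raw_column_score(col, toy_matrix)
    for i in range(len(col)):
        gapped = list(col)
        gapped[i] = "-"
        _, pairs = raw_column_score(gapped, toy_matrix)
        assert pairs <= base_pairs


def test_profile_is_deterministic(matrix_3di):
    aln = make_alignment(SynthSpec(n_rows=6, n_cols=30, seed=9))
    p1 = compute_profile(aln, matrix_3di)
    p2 = compute_profile(aln, matrix_3di)
    assert p1 == p2


@pytest.mark.parametrize(
    "rows, expected",
    [
        # gap fractions [0, 1/3, 2/3] at threshold 0.5 -> one dropped
        ((("a", "AAA"), ("b", "A-A"), ("c", "A--")), (3, 2, 1)),
        # gap-free alignment -> nothing dropped
        ((("a", "AA"), ("b", "AA")), (2, 2, 0)),
    ],
)
def test_column_summary_counts(rows, expected):
    assert column_summary(Alignment(rows)) == expected


def test_half_gapped_column_is_retained_at_default_threshold():
    """Strict '>' boundary: 2 gaps in 4 rows (exactly 0.5) counts as valid."""
    aln = Alignment((("a", "A"), ("b", "A"), ("c", "-"), ("d", "-")))
    assert column_summary(aln) == (1, 1, 0)
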