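import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structconf import (
    Alignment,
    compute_profile,
    confidence_filter,
    default_grid,
    gap_trim,
    sweep,
)
from structconf.errors import EmptyResultError, InconsistentInputError


@pytest.fixture()
def scored_toy(toy_alignment, toy_matrix):
    return toy_alignment, compute_profile(toy_alignment, toy_matrix)


def test_gap_trim_drops_only_majority_gap_columns(toy_matrix):
    # per-column gap counts [0, 1, 2] over 3 rows -> only 2/3 column dropped
    aln = Alignment((("a", "AAA"), ("b", "AA-"), ("c", "A--")))
    res = gap_trim(aln)
    assert res.retained_indices == (0, 1)
    assert res.alignment.row("c") == "A-"


def test_gap_trim_boundary_half_is_retained():
    aln = Alignment((("a", "A"), ("b", "A"), ("c", "-"), ("d", "-")))
    assert gap_trim(aln).retained_indices == (0,)


def test_gap_trim_identity_on_gap_free_alignment(toy_matrix):
    aln = Alignment((("a", "ABC"), ("b", "ABC")))
    assert gap_trim(aln).alignment.rows == aln.rows


def test_gap_trim_is_idempotent():
    aln = Alignment((("a", "AA-"), ("b", "A--"), ("c", "A-A")))
    once = gap_trim(aln)
    twice = gap_trim(once.alignment)
    assert twice.alignment.rows == once.alignment.rows


def test_gap_trim_all_dropped_is_an_error():
    aln = Alignment((("a", "A-"), ("b", "--"), ("c", "--")))
    with pytest.raises(EmptyResultError, match="0.5"):
        gap_trim(aln)


def test_confidence_filter_inclusion_boundary(scored_toy):
    aln, profile = scored_toy  # normalized [1.0, 0.25, 0.0]
    res = confidence_filter(aln, profile, 0.5, "retain_ge")
    assert tuple(i + 1 for i in res.retained_indices) == (1,)
    assert res.mean_confidence_retained == pytest.approx(1.0)


def test_confidence_filter_exclusion_boundary(scored_toy):
    aln, profile = scored_toy
    res = confidence_filter(aln, profile, 0.5, "retain_lt")
    assert tuple(i + 1 for i in res.retained_indices) == (2, 3)
    assert res.mean_confidence_retained == pytest.approx(0.125)


def test_inclusion_at_zero_is_identity(scored_toy):
    aln, profile = scored_toy
    res = confidence_filter(aln, profile, 0.0, "retain_ge")
    assert res.alignment.rows == aln.rows


def test_exclusion_at_zero_is_empty(scored_toy):
    aln, profile = scored_toy
    with pytest.raises(EmptyResultError):
        confidence_filter(aln, profile, 0.0, "retain_lt")


def test_profile_alignment_mismatch_rejected(scored_toy, toy_matrix):
    _, profile = scored_toy
    other = Alignment((("a", "AB"), ("b", "AB")))
    with pytest.raises(InconsistentInputError):
        confidence_filter(other, profile, 0.5, "retain_ge")


def test_sweep_counts_on_worked_example(scored_toy):
    aln, profile = scored_toy
    ge = sweep(aln, profile, [0, 0.5, 1.0], "retain_ge")
    assert [p.n_columns for p in ge.points] == [3, 1, 1]
    lt = sweep(aln, profile, [0, 0.5, 1.0], "retain_lt")
    assert [p.n_columns for p in lt.points] == [0, 2, 2]
    assert math.isnan(lt.points[0].mean_confidence)


def test_default_grid_is_21_points():
    grid = default_grid()
    assert len(grid) == 21
    assert grid[0] == 0.0 and grid[-1] == 1.0


@settings(derandomize=True, max_examples=50)
@given(
    norm=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
)
def test_sweep_monotonicity_and_partition(norm, toy_matrix):
    """Inclusion counts non-increasing, exclusion non-decreasing; both modes
    partition the columns at every threshold."""
    # build an alignment/profile whose normalized scores are the given ones
    # by monkey-constructing a profile-like object via compute on a dummy and
    # replacing columns is brittle; instead filter on a synthetic profile.
    from structconf.confidence import ColumnConfidence, ConfidenceProfile

    cols = tuple(
        ColumnConfidence(j, v, 1, v, 0.0, False) for j, v in enumerate(norm)
    )
    profile = ConfidenceProfile(cols, min(norm), max(norm), float(np.mean(norm)), 2, len(norm))
    aln = Alignment((("a", "A" * len(norm)), ("b", "A" * len(norm))))
    grid = default_grid()
    ge = sweep(aln, profile, grid, "retain_ge")
    lt = sweep(aln, profile, grid, "retain_lt")
    ge_counts = [p.n_columns for p in ge.points]
    lt_counts = [p.n_columns for p in lt.points]
    assert all(a >= b for a, b in zip(ge_counts, ge_counts[1:]))
    assert all(a <= b for a, b in zip(lt_counts, lt_counts[1:]))
    for pg, pl in zip(ge.points, lt.points):
        assert set(pg.retained_indices) | set(pl.retained_indices) == set(range(len(norm)))
        assert not (set(pg.retained_indices) & set(pl.retained_indices))


def test_sweep_rejects_unsorted_grid(scored_toy):
    aln, profile = scored_toy
    with pytest.raises(ValueError, match="ascending"):
        sweep(aln, profile, [0.5, 0.1], "retain_ge")
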