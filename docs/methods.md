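# Methods

## The confidence model

An alignment is an ordered list of N gapped rows of equal length L over a
structural alphabet (3Di in production use). The raw per-column score

    C_j = sum_{i=1}^{N-1} S(r_i, r_{i+1})

sums substitution scores over *adjacent* row pairs only; pairs in which
either member is a gap are skipped, and `valid_pairs` records how many
pairs actually contributed. This is a deliberately restricted sum-of-pairs:
it is linear in N instead of quadratic, and because the row order is fixed
it is deterministic for a given input. The price is order dependence —
general row permutations change C_j (a regression test documents one such
change) — but reversal of the row order is invariant because S is
symmetric. The full all-versus-all sum exists only as an explicitly
rejected alternative; it is not implemented as a scoring path.

Raw scores are min-max normalized within the alignment,
`(C_j - C_min) / (C_max - C_min)`, so every alignment spans [0, 1] and at
least one column attains each endpoint in the non-degenerate case. The
alignment-level summary `c_avg` is the mean normalized score over **all L
columns of the untrimmed alignment**; post-trim means are reported
separately (`mean_confidence_retained`) and never conflated with it.

### Edge cases and numerical choices

* **Zero-valid-pair columns** (every adjacent pair gapped) score raw 0 and
  are included in C_min/C_max and in the average. Excluding gap pairs is a
  pair-level rule; no column is excluded from normalization, keeping L
  consistent with the averaging formula. A configuration flag
  (`include_zero_pair_columns=False`) instead takes the extremes over
  scoreable columns and clips the zero-pair columns into [0, 1], for users
  who consider the raw-0 convention an artifact.
* **Degenerate normalization** (C_max == C_min): every column gets 0.5 and
  a `DegenerateNormalizationWarning` is emitted. The midpoint avoids
  asserting either extreme when relative ranking is undefined.
* **Unknown symbols are hard errors**, never silent zeros — a zero cell
  would contaminate C_min/C_max. Characters are upper-cased before lookup;
  `.` gaps are canonicalized to `-` on input.
* Scores accumulate in double precision; test comparisons use absolute
  tolerance 1e-9.
* **C_j is not divided by valid_pairs**: the raw sum confounds confidence
  with gap count (fewer valid pairs ⇒ smaller magnitude). The metric keeps
  the raw sum; the gap confound is acknowledged, surfaced via
  `valid_pairs` and `gap_fraction` per column, and not corrected.
* N = 1 alignments load but are rejected by scoring (no adjacent pairs).

## Trimming semantics

* **Gap trimming** drops columns with gap fraction strictly greater than
  0.5 (a 4-row column with exactly 2 gaps is retained). Idempotent; only
  the column rule is implemented, not Gblocks' contiguity/flank logic.
* **Confidence filtering** is threshold-based, not rank-based: inclusion
  keeps `normalized >= t`, exclusion keeps `normalized < t`. The two modes
  partition the columns at every t, inclusion counts are non-increasing in
  t and exclusion counts non-decreasing — all property-tested. Ties at
  exactly t follow these boundary conventions with no epsilon fuzzing.
* **Sweeps** reuse the original profile's normalized values when reporting
  the mean confidence of retained columns; retained sets are *not*
  re-normalized. Re-normalizing would re-span [0, 1] at every threshold
  and destroy comparability across the sweep. Default grid: 0.00–1.00 in
  steps of 0.05 (21 points). Inside a sweep an empty retained set is a
  zero-count data point, not an error.

## Background distributions and Z-scores

Although each alignment is normalized independently, `c_avg` over a
collection of homologous-family alignments forms a meaningful empirical
distribution. Collection curation follows two rules: families above 300
members are subsampled to their 300 longest sequences (ties at the cap
boundary broken by lexicographically smaller id, original order preserved),
and only alignments with at least 10 rows and 100 columns qualify.
`build_background` fits mu (mean) and sigma (sample standard deviation,
n−1 denominator — collections are samples of a family universe). A user
alignment gets one Z per background and the arithmetic mean Z_avg over
however many backgrounds are supplied (the count is recorded, not forced
to two); Z_avg maps to a category by statistical rarity:

| Z_avg            | category                     |
|------------------|------------------------------|
| Z ≥ 2 or Z ≤ −2  | Statistically Rare Alignment |
| 1 ≤ Z < 2        | Above Average, Less Common   |
| −1 < Z < 1       | Common, Expected Range       |
| −2 < Z ≤ −1      | Below Average, Less Common   |

Boundary membership is exact (±2 rare, −1 below-average, +1
above-average); values within 1e-9 of a boundary are snapped to it so that
float round-off in `(c_avg − mu)/sigma` cannot flip a category whose
exact-arithmetic value sits on the boundary. The package ships **no
default background**: published values are collection- and aligner-
specific, so users load a JSON of labeled {mu, sigma, n} entries or build
one from a directory; every assessment carries its background labels.

## Structure annotation

The k-th non-gap character of a row maps to polymer residue ordinal k of
its single chain, in file order (structural-alphabet strings are generated
in file order, not author numbering). Normalized confidence is written to
B-factors as `round(100 * normalized, 2)`: the ×100 scale fills the
conventional B range so default viewer ramps resolve the whole interval,
and fits fixed-width PDB columns; it is configurable (`scale=`). Unmapped
polymer residues and hetero/solvent atoms get B = 0.00. Multi-chain files
are rejected with instructions to extract the chain; a mapping whose
largest ordinal exceeds the chain's polymer length is a hard error naming
both lengths.

## Tree diagnostics

A tip set is monophyletic iff the bipartition it induces exists as an edge
of the **unrooted** tree — equivalently, it is a clade under some rooting.
This makes verdicts independent of where the inference program happened to
root the output (property-tested against an MRCA-based oracle over all
rootings of random 8-tip trees). Singleton and full-tip sets are trivially
monophyletic with absent support. Support is read from the internal-node
label of the separating edge (the ultrafast-bootstrap convention);
non-numeric labels yield absent support with a warning. Because a
reported support threshold can mean either the minimum across clades or
each clade's own value, diagnostics report all per-clade supports *and*
their minimum. Tree inference itself is external: `run_case_study` is thin
orchestration around a user-supplied shell template (`{aln}`, `{tree}`
placeholders) and all tested logic consumes Newick text.

## Synthetic data

The generators define the conditions under which the package is exercised:

* `make_alignment(SynthSpec)`: a column is conserved (one symbol repeated
  down all rows) with probability `conservation`, else i.i.d. uniform;
  cells are then gapped independently at `gap_rate`. Defaults
  (`conservation=0.5`, `gap_rate=0.05`) give mid-range confidence
  profiles.
* `make_family_collection`: 20 families by default, rows uniform in
  10–20, columns in 100–160, conservation in 0.3–0.9, gap rate in 0.0–0.2
  — sizes chosen to straddle the qualification thresholds the way a small
  curated family benchmark would, while keeping the whole collection
  scoreable in seconds. Deliberate threshold violators can be planted and
  are recorded in a manifest.
* `make_planted_pairs_alignment`: three row pairs with 95% within-pair
  identity in 70 signal columns plus 30 uniform-noise columns. Signal
  columns separate the pairs; noise columns carry no phylogenetic
  information, so trees inferred from high-confidence subsets should
  recover all pairs and trees from noise-only subsets should not — the
  desk-scale version of a divergent-family case study.
* `make_toy_structure`: a straight-line CA trace at 3.8 Å spacing with a
  seeded direction. Geometry is deliberately unrealistic; it exists to
  exercise structure I/O and residue mapping only.

Everything is a pure function of (spec, seed) through one
`numpy.random.default_rng` per call; no global random state.

What the synthetic data does **not** emulate: real 3Di strings derived
from folds (columns are exchangeable and have no spatial autocorrelation),
indel placement (gaps are i.i.d., not block-structured), realistic
family-size or length distributions, and evolutionary covariance between
rows beyond the planted pair structure. Passing tests therefore establish
the correctness of the arithmetic, the boundary semantics and the
qualitative responses (confidence rises with conservation, falls with gap
content, phylogenetic signal concentrates in high-confidence columns) —
they do not establish calibration of absolute confidence values on real
structural families, which depends on the background collection a user
supplies.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on desk-scale inputs chosen
as the package's own verification conditions: 1000 random columns for the
scoring oracle, 20-family collections (rows 10–20, columns 100–160) for
background construction, 20 replicates against an independent
100–replicate reference for mean recovery (bound 3σ/√n with σ estimated
from the reference sample), a 10-point gap-rate gradient for the
anticorrelation, and the 6×100 planted-pair alignment with FastTree for
the case-study loop.

## Known limitations

* Order dependence of C_j is inherited from the adjacent-pair design; the
  metric is only meaningful for the row order the aligner produced.
* The gap/confidence confound (above) means sparse columns score low even
  when their few residues agree perfectly.
* Min-max normalization is relative: a uniformly bad alignment still spans
  [0, 1]. Cross-alignment comparison is only meaningful through the
  background Z machinery.
* Structure annotation handles single chains only, and assumes the row's
  character count does not exceed the chain's polymer residue count.
* Generating 3Di strings from structures, computing the alignments
  themselves, and maximum-likelihood inference are all external to this
  package by design.
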