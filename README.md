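# structconf

Confidence scoring, trimming and diagnostics for **structure-aware multiple
alignments** — alignments of 3Di strings, in which each protein's 3D
structure is encoded as a sequence over Foldseek's 20-state structural
alphabet. Structure-aware alignment reaches into the twilight zone where
sequence identity fails, but divergent folds produce locally misaligned
regions; `structconf` quantifies, per column, how much structural agreement
an alignment actually contains, and builds practical operations on top of
that metric.

## The metric

For an alignment of N rows and L columns with fixed row order, each column
*j* receives a raw confidence

&nbsp;&nbsp;&nbsp;&nbsp;C<sub>j</sub> = Σ<sub>i=1..N−1</sub> S(r<sub>i</sub>, r<sub>i+1</sub>)

the sum of substitution scores S (Foldseek's 3Di matrix, or any BLAST-style
square matrix) over **adjacent** row pairs; pairs involving a gap are
excluded. Adjacent-pair scoring is linear in N (a full all-versus-all
sum-of-pairs would be quadratic) and deterministic for a fixed row order.
Raw scores are min-max normalized within the alignment,

&nbsp;&nbsp;&nbsp;&nbsp;Ĉ<sub>j</sub> = (C<sub>j</sub> − C<sub>min</sub>) / (C<sub>max</sub> − C<sub>min</sub>) ∈ [0, 1],

and their mean Ĉ<sub>avg</sub> = (1/L) Σ<sub>j</sub> Ĉ<sub>j</sub> summarizes
the whole alignment. On top of this the package provides:

* **Trimming** — drop columns with >50% gap content (Gblocks-style, strict
  boundary), or filter by confidence threshold *t* in inclusion
  (keep Ĉ<sub>j</sub> ≥ t) or exclusion (keep Ĉ<sub>j</sub> < t) mode, with
  full threshold sweeps.
* **Empirical Z-scores** — build background distributions of
  Ĉ<sub>avg</sub> over alignment collections (with the family subsampling
  cap of 300 longest members and ≥10-row / ≥100-column qualification
  thresholds), then standardize a user alignment:
  Z = (Ĉ<sub>avg</sub> − μ)/σ, with Z<sub>avg</sub> mapped to a qualitative
  rarity category (|Z| ≥ 2 ⇒ statistically rare, etc.).
* **B-factor annotation** — write Ĉ<sub>j</sub> × 100 into the B-factors of
  single-chain mmCIF/PDB structures so any viewer's color ramp becomes a
  confidence map.
* **Tree diagnostics** — given a Newick tree and a ground-truth tip
  partition, report per-clade monophyly (via unrooted bipartitions, so
  verdicts are rooting-invariant) and the bootstrap support on the
  separating edge, plus a sweep→infer→check orchestrator around an external
  tree program.
* **Synthetic fixtures** — seeded generators of alignments, family
  collections, planted-pair case studies and toy CA-trace structures, so
  everything above is testable without downloads.

## Worked example

```python
from structconf import Alignment, compute_profile, loads_substitution_matrix

matrix = loads_substitution_matrix("   A  B  C\nA  2 -1 -1\nB -1  2 -1\nC -1 -1  2\n")
aln = Alignment((("s1", "AAA"), ("s2", "AB-"), ("s3", "ABA")))
profile = compute_profile(aln, matrix)
```

`python examples/score_alignment.py` prints:

```
 column_index  raw  valid_pairs  gap_fraction  normalized  dropped
            1  4.0            2      0.000000        1.00    False
            2  1.0            2      0.000000        0.25    False
            3  0.0            0      0.333333        0.00    False

C_min=0.0  C_max=4.0  mean normalized confidence = 0.41667
```

Column 1 (A/A/A) contributes two +2 matches (raw 4); column 2 mixes a
mismatch and a match (−1 + 2 = 1); column 3 has no gap-free adjacent pair
and scores 0 by convention. Min-max scaling maps these to 1.0 / 0.25 / 0.0,
and their mean, 0.41667, is the alignment-level confidence.

The other scripts in `examples/` each demonstrate one capability
(trimming/sweeps, background Z-scores, B-factor annotation, tree
diagnostics) on inputs they generate themselves.

A thin CLI mirrors the library: `structconf score|trim|sweep|assess|annotate|treecheck`,
`structconf matrix validate`, `structconf aln validate`,
`structconf background build`, `structconf fixtures ...`,
`structconf casestudy run`. Run any of them with `--help`.

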