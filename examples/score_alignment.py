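"""Score a small structure-aware alignment column by column.

Builds the three-row toy alignment whose arithmetic can be checked by hand
(match +2, mismatch -1), scores each column over adjacent row pairs,
normalizes, and prints the profile.
"""

from structconf import Alignment, compute_profile, loads_substitution_matrix

TOY_MATRIX = """\
   A  B  C
A  2 -1 -1
B -1  2 -1
C -1 -1  2
"""

matrix = loads_substitution_matrix(TOY_MATRIX)
aln = Alignment((("s1", "AAA"), ("s2", "AB-"), ("s3", "ABA")))

profile = compute_profile(aln, matrix)
print(profile.to_dataframe().to_string(index=False))
print(f"\nC_min={profile.c_min}  C_max={profile.c_max}  "
      f"mean normalized confidence = {profile.c_avg:.5f}")
print(
    "\nColumn 1 (A/A/A) is the best-supported column (normalized 1.0); "
    "column 3 has no gap-free adjacent pair, scores 0 raw and anchors the "
    "bottom of the min-max scale."
)
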