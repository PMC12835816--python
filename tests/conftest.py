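import pytest

from structconf import (
    Alignment,
    foldseek_3di_matrix,
    loads_substitution_matrix,
)

TOY_MATRIX_TEXT = """\
# toy 3-symbol matrix: match +2, mismatch -1
   A  B  C
A  2 -1 -1
B -1  2 -1
C -1 -1  2
"""


@pytest.fixture(scope="session")
def toy_matrix():
    return loads_substitution_matrix(TOY_MATRIX_TEXT)


@pytest.fixture(scope="session")
def matrix_3di():
    return foldseek_3di_matrix()


@pytest.fixture()
def toy_alignment():
    """3x3 worked example: hand-derivable scores under the toy matrix."""
    return Alignment((("s1", "AAA"), ("s2", "AB-"), ("s3", "ABA")))


def adjacent_pair_oracle(column, matrix):
    """Independent brute-force oracle: loop adjacent index pairs explicitly."""
    gap = matrix.alphabet.gap_symbol
    total, valid = 0.0, 0
    for i in range(len(column) - 1):
        a, b = column[i], column[i + 1]
        if gap in (a, b):
            continue
        total += matrix.scores[(a.upper(), b.upper())]
        valid += 1
    return total, valid
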