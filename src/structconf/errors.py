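"""Exception and warning types shared across the package."""


class StructconfError(Exception):
    """Base class for all package-specific errors."""


class MatrixFormatError(StructconfError):
    """Malformed substitution-matrix file (missing cell, duplicate symbol...)."""


class MatrixSymmetryError(MatrixFormatError):
    """scores(x, y) != scores(y, x) when symmetry was required."""


class UnknownSymbolError(StructconfError):
    """A character is absent from the substitution-matrix alphabet."""

    def __init__(self, symbol: str, context: str = ""):
        self.symbol = symbol
        msg = f"symbol {symbol!r} is not in the matrix alphabet"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class GapSymbolError(StructconfError):
    """A gap symbol was passed where only residue symbols are allowed."""


class RaggedAlignmentError(StructconfError):
    """Alignment rows have unequal lengths."""


class DuplicateIdError(StructconfError):
    """Two alignment rows share an identifier."""


class EmptyInputError(StructconfError):
    """An input (file, list, alignment) is empty where content is required."""


class TooFewRowsError(StructconfError):
    """Fewer than two rows: adjacent-pair scoring is undefined."""


class InconsistentInputError(StructconfError):
    """Two inputs that must describe the same alignment disagree."""


class EmptyResultError(StructconfError):
    """A trim operation retained no columns."""


class DegenerateBackgroundError(StructconfError):
    """Background collection too small or with zero variance."""


class MissingBackgroundError(StructconfError):
    """No background distribution supplied to an assessment."""


class MappingMismatchError(StructconfError):
    """Column-to-residue mapping does not fit the structure's chain."""


class UnknownTipError(StructconfError):
    """A requested tip label is absent from the tree."""


class CoverageError(StructconfError):
    """Ground-truth partition does not cover (exactly) the tree's tips."""


class SynthSpecError(StructconfError):
    """Invalid synthetic-data specification."""


class DegenerateNormalizationWarning(UserWarning):
    """All raw column scores equal: min-max scaling is undefined, midpoint used."""


class GapOnlyRowWarning(UserWarning):
    """An alignment row consists entirely of gap characters."""


class NonNumericSupportWarning(UserWarning):
    """An internal-node label could not be parsed as a numeric support value."""
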