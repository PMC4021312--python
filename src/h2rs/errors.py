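"""Exception hierarchy."""


class H2rsError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(H2rsError):
    """The alignment file is malformed (ragged rows, empty, unparseable)."""


class AlphabetError(H2rsError):
    """A sequence contains a character outside the accepted alphabet."""


class DegenerateColumnError(H2rsError):
    """No sequence contributes a canonical residue pair at the requested columns."""


class DegenerateNullError(H2rsError):
    """All randomized statistics are identical; no extreme-value model can be fit."""


class MatrixValidationError(H2rsError):
    """A pair-similarity or density matrix violates its invariants."""


class MatrixConstructionError(H2rsError):
    """Substitution counts are unusable for building a similarity matrix."""


class AnnotationError(H2rsError):
    """A functional-site annotation refers to a residue absent from the structure."""


class SyntheticSpecError(H2rsError):
    """A synthetic-alignment specification is internally inconsistent."""
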