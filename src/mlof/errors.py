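"""Exception hierarchy.

User errors (bad input files, malformed variants) and data errors
(inputs that are valid but insufficient for the computation, e.g. too few
structured variant positions) are distinguished so the CLI can map them to
different exit codes.
"""


class MlofError(Exception):
    """Base class for all package errors."""


class UserInputError(MlofError):
    """Malformed or unreadable user input."""


class DataError(MlofError):
    """Valid input that does not support the requested computation."""


class ParseError(UserInputError):
    """Unparseable file or token."""


class EmptyModelError(UserInputError):
    """Structure file contains no usable CA atoms."""


class AmbiguityError(UserInputError):
    """Duplicate residue numbering in a structure."""


class CoverageError(DataError):
    """No structure fragment covers any variant position."""


class InsufficientPositionsError(DataError):
    """Too few variant positions survive the confidence filter."""


class EmptyStructureError(DataError):
    """All residues removed by the confidence filter."""


class DegenerateGeometryError(DataError):
    """Mean nearest-neighbour distance <= 1 Angstrom; log ratio undefined."""


class InsufficientReferenceError(DataError):
    """Reference class has too few values to fit a density."""


class BandwidthError(DataError):
    """Bandwidth selection failed (e.g. zero-variance sample)."""


class AlphabetError(UserInputError):
    """Unknown amino-acid letter."""
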