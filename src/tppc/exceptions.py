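"""Exception hierarchy.

Every error raised by this package derives from :class:`TPPCError`, so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class TPPCError(Exception):
    """Base class for all package errors."""


class IdentifierError(TPPCError):
    """Duplicate or otherwise invalid variable/sample identifiers."""


class TableFormatError(TPPCError):
    """Malformed input table (ragged rows, missing header, ...)."""


class TableParseError(TableFormatError):
    """A cell could not be parsed as a number; message names row and column."""


class InsufficientOverlapError(TPPCError):
    """Too few shared samples between the transcript and metabolite layers."""


class DimensionError(TPPCError):
    """Not enough samples / residual degrees of freedom for the computation."""


class DegenerateInputError(TPPCError):
    """Constant variables, all-zero eigenvalues or similar degenerate input."""


class CollinearityError(TPPCError):
    """A (1 - r^2) factor or residual variance fell below the guard threshold."""


class InsufficientNullError(TPPCError):
    """Too few randomizations/permutations to build a null distribution."""


class SpecificationError(TPPCError):
    """Invalid simulation or analysis configuration."""
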