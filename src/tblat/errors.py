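"""Exception types shared across the package."""


class TblatError(Exception):
    """Base class for all package-specific errors."""


class UnalignableTokenError(TblatError):
    """Raised when a token is too short to decompose into k-mers."""


class EmptyMatrixError(TblatError):
    """Raised when matrix construction would produce no entries."""


class MatrixFormatError(TblatError):
    """Raised on a malformed matrix file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateScoreSpaceError(TblatError):
    """Raised when a percentile is requested from a degenerate score space."""


class OntologyFormatError(TblatError):
    """Raised when an ontology file cannot be parsed or is empty."""


class PolicyError(TblatError):
    """Raised when a cut-off policy has no percentile for a token length."""
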