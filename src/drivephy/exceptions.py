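"""Exception hierarchy."""


class DrivephyError(Exception):
    """Base class for all package errors."""


class NewickParseError(DrivephyError):
    """Malformed Newick input; message carries position information when available."""


class MissingBranchLengthError(DrivephyError):
    """A non-root edge lacks a branch length."""


class PolytomyError(DrivephyError):
    """Operation requires a fully bifurcating tree."""


class ValidationError(DrivephyError):
    """Input table or parameter failed validation."""


class FitError(DrivephyError):
    """Model fitting failed to converge from every starting point."""
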