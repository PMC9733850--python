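"""Exception hierarchy.

Every error raised by lamellaflex derives from :class:`LamellaflexError`,
so callers can catch the package's failures without masking bugs in the
underlying numerical libraries.
"""


class LamellaflexError(Exception):
    """Base class for all lamellaflex errors."""


class InvalidParameterError(LamellaflexError, ValueError):
    """A parameter violates an operation's preconditions."""


class GeometryError(LamellaflexError):
    """A generated or supplied geometry is physically inconsistent."""


class NoPeakError(LamellaflexError):
    """The requested fit window contains no interior maximum."""


class FitFailureError(LamellaflexError):
    """The optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidFitError(LamellaflexError):
    """A PeakFit carries non-physical parameters (q0 <= 0, fwhm <= 0)."""


class IndexingError(LamellaflexError):
    """Lamellar order assignment is inconsistent with the peak positions."""


class DegenerateLipidError(LamellaflexError):
    """A lipid has a zero-length head-to-tail vector or missing beads."""


class DegenerateBondError(LamellaflexError):
    """A bond vector has zero length."""


class UnderdeterminedError(LamellaflexError):
    """Too few independent observations to fit the requested model."""


class UndefinedCorrelationError(LamellaflexError):
    """The correlation normalization is zero (all reference tilts vanish)."""


class FileFormatError(LamellaflexError):
    """A file does not conform to the expected on-disk format."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
        self.line_number = line_number
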