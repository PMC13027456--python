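"""Exception hierarchy for the qeegdep pipeline.

All errors raised by this package derive from :class:`QEEGError`, so callers
can catch pipeline failures without masking programming errors.
"""


class QEEGError(Exception):
    """Base class for all qeegdep errors."""


class FormatError(QEEGError):
    """Input file is not readable EDF (corrupt header, truncated records)."""


class SessionError(QEEGError):
    """A session could be read but contains no usable segments."""


class MontageError(QEEGError):
    """A requested bipolar derivation cannot be built from the stored channels."""


class EmptySegmentError(QEEGError):
    """Artifact rejection removed every epoch of a segment."""


class InsufficientDataError(QEEGError):
    """Segment too short for the requested spectral estimate."""


class ResolutionError(QEEGError):
    """Frequency grid too coarse to resolve a requested band."""


class DegenerateInputError(QEEGError):
    """Zero-power or otherwise degenerate signal where a ratio is required."""


class SelectionError(QEEGError):
    """A channel/region selection matched nothing."""


class DomainError(QEEGError):
    """Input value outside the documented domain of an operation."""


class PipelineError(QEEGError):
    """Batch run produced no successful subjects."""
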