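"""Named error types raised by the cyclicity pipeline.

Every validation failure has its own class so callers (and the CLI) can map
failures to exit codes and messages without string matching.
"""


class CyclicityError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CyclicityError, ValueError):
    """Invalid input data or parameters."""


class MissingLabelError(ValidationError):
    """Header row absent or contains empty channel labels."""


class DuplicateLabelError(ValidationError):
    """Two channels share the same label."""


class RaggedRowError(ValidationError):
    """A data row has a different number of cells than the header."""


class NonNumericError(ValidationError):
    """A data cell could not be parsed as a finite number."""


class TooFewFramesError(ValidationError):
    """Fewer than 3 time frames."""


class TooFewChannelsError(ValidationError):
    """Fewer than 2 channels."""


class NonFiniteError(ValidationError):
    """NaN or infinite values in the data."""


class DegenerateChannelError(ValidationError):
    """A channel is constant (zero quadratic variation) and cannot be normalized."""


class NotSkewSymmetricError(ValidationError):
    """A matrix expected to be skew-symmetric is not, beyond tolerance."""


class DegenerateConstellationError(ValidationError):
    """Constellation geometry is degenerate (all-zero matrix, centroid at origin, ...)."""


class SpecError(ValidationError):
    """Invalid simulation specification."""
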