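"""Exception hierarchy for the ir2 pipeline.

All errors derive from :class:`IR2Error` (a ``ValueError``) so callers can
catch pipeline problems with a single except clause while standard-library
semantics are preserved.
"""


class IR2Error(ValueError):
    """Base class for all ir2 errors."""


class InvalidSpecError(IR2Error):
    """A generator or configuration object carries impossible parameters."""


class DegenerateInputError(IR2Error):
    """Input lacks the variation the operation requires (e.g. constant image)."""


class DegenerateReferenceError(DegenerateInputError):
    """Reference image is degenerate for a ratio/normalised metric."""


class InfeasibleWeightingError(IR2Error):
    """Selective sampling weights demand mass on an empty voxel class."""


class GeometryError(IR2Error):
    """A patch, offset or search box does not fit inside its volume."""


class InvalidConfigError(IR2Error):
    """Configuration value outside its legal range."""


class EmptySelectionError(IR2Error):
    """A selection rule matched no candidates."""


class AlignmentError(IR2Error):
    """Series or volumes that must correspond do not."""


class FormatError(IR2Error):
    """File content does not conform to the expected on-disk format."""


class DivergenceError(IR2Error):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
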