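"""Exception hierarchy for the segmentation pipeline."""


class ImsctError(Exception):
    """Base class for all pipeline errors."""


class GeometryError(ImsctError):
    """Grid too small (or otherwise unable) to contain the requested geometry."""


class FormatError(ImsctError):
    """Malformed or unreadable image file."""


class DegenerateInputError(ImsctError):
    """Input without enough information to process (e.g. constant intensity)."""


class ConsistencyError(ImsctError):
    """Volumes or transform records that should agree do not."""


class LocalizationFailure(ImsctError):
    """The cord localizer produced an empty mask for a subject."""
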