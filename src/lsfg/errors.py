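"""Exception hierarchy for the lsfg package."""


class LSFGError(Exception):
    """Base class for all lsfg errors."""


class FormatError(LSFGError):
    """Raised when an on-disk artifact (metadata, frame file, ROI file) is
    missing or cannot be parsed."""


class ValidationError(LSFGError):
    """Raised when data violate a structural invariant (dimension mismatch,
    negative MBR, empty ROI, missing protocol stage, ...)."""


class CompleteOcclusion(LSFGError):
    """Signalled when the perfusion index is requested for an eye whose flow
    during occlusion is exactly zero: the ratio baseline/occluded is not a
    number and the condition is reported as complete occlusion instead."""
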