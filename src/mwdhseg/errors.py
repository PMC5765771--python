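"""Exception hierarchy shared across the package."""


class MwdhsegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MwdhsegError, ValueError):
    """An input violates a documented precondition (non-finite pixels, bad shape...)."""


class DegenerateInputError(MwdhsegError, ValueError):
    """The input admits no meaningful answer (e.g. a constant image has no two classes)."""


class SegmentationEmptyError(MwdhsegError, RuntimeError):
    """Segmentation produced no object at the seed: the seed pixel fell outside the mask."""


class UndefinedMetricError(MwdhsegError, ValueError):
    """A metric is undefined for the given masks (empty ground truth)."""


class FormatError(MwdhsegError, ValueError):
    """A file could not be read as any supported image format."""
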