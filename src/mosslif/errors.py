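"""Exception hierarchy for the mosslif pipeline.

Every error raised deliberately by this package derives from
:class:`MossLifError`, so callers (and the CLI) can distinguish analysis
errors from programming bugs.
"""


class MossLifError(Exception):
    """Base class for all mosslif errors."""


class ImageFormatError(MossLifError):
    """Input raster is not an 8-bit, 3-channel RGB image."""


class RoiBoundsError(MossLifError):
    """Requested region of interest falls outside the image bounds."""


class ValidationError(MossLifError):
    """Input violates a documented precondition (e.g. non-normalized histogram)."""


class InsufficientDataError(MossLifError):
    """Too few observations for the requested statistic."""


class DegenerateVarianceError(MossLifError):
    """Both samples are constant; the Welch statistic is undefined."""


class ConfigError(MossLifError):
    """Run configuration is inconsistent or refers to missing inputs."""
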