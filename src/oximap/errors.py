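"""Exception hierarchy shared across the pipeline.

Every contract violation raises a subclass of :class:`OximapError` with a
module-qualified message, so the CLI can map any of them to exit status 1.
"""


class OximapError(Exception):
    """Base class for all contract violations raised by this package."""


class ValidationError(OximapError, ValueError):
    """An input value violates a documented precondition."""


class RangeError(OximapError, ValueError):
    """A query falls outside the supported domain (e.g. wavelength grid)."""


class ConstructionError(OximapError, ValueError):
    """A derived object cannot be built (e.g. degenerate wavelength pair)."""


class StreamIntegrityError(OximapError, ValueError):
    """The interleaved stream violates the 445/473 alternation contract."""


class GeometryError(OximapError, ValueError):
    """An ROI or shape does not fit inside the image it addresses."""


class InsufficientDataError(OximapError, ValueError):
    """Too few valid pixels to compute a requested statistic."""


class ConfigurationError(OximapError, ValueError):
    """Mismatched configuration between pipeline stages (e.g. LUT vs frames)."""
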