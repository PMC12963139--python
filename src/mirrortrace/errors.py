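"""Exception hierarchy for mirrortrace."""


class MirrorTraceError(Exception):
    """Base class for all package errors."""


class InvalidShapeError(MirrorTraceError):
    """Star-shape parameters produce an undefined or non-positive radius."""


class InvalidBandError(MirrorTraceError):
    """Double-contour band parameters are inconsistent (e.g. r_ext <= r_int)."""


class GeometryError(MirrorTraceError):
    """A star does not fit the requested raster."""


class FitError(MirrorTraceError):
    """Star-parameter fitting failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FormatError(MirrorTraceError):
    """Unreadable or non-RGB input image."""


class ConfigurationError(MirrorTraceError):
    """Analysis configuration incompatible with the raster (e.g. empty bins)."""


class SummaryError(MirrorTraceError):
    """A drawing could not be summarized (e.g. no usable bins)."""
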