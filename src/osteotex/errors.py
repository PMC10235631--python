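"""Exception hierarchy."""


class OsteotexError(Exception):
    """Base class for all package errors."""


class ParameterError(OsteotexError, ValueError):
    """A parameter is outside its documented range."""


class DataError(OsteotexError, ValueError):
    """Input data violates an invariant (non-finite, wrong shape, ...)."""


class DegenerateBackgroundError(OsteotexError):
    """Flat-field background contains zeros."""


class CalibrationError(OsteotexError):
    """Projection geometry is inconsistent (e.g. SOD > SID)."""


class DegeneratePolygonError(OsteotexError):
    """ROI corners are collinear or self-intersecting."""


class ConfigurationError(OsteotexError):
    """A scale/series configuration cannot produce a valid fit."""


class BoundaryError(OsteotexError):
    """A measuring disk exits the image."""


class EmptyResultError(OsteotexError):
    """An operation produced no valid pixels/boxes."""


class LabelError(OsteotexError, ValueError):
    """Class labels are missing or single-class."""


class SchemaError(OsteotexError, ValueError):
    """Feature-table columns do not match the expected schema."""


class UnstableCIError(OsteotexError):
    """Bootstrap metric undefined on too many resamples."""
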