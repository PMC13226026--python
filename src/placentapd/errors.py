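"""Exception hierarchy."""


class PlacentapdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlacentapdError):
    """Invalid or incomplete study configuration / calibration."""


class SchemaError(PlacentapdError):
    """A serialized table does not match its declared schema."""


class InvalidMeasurementError(PlacentapdError):
    """A measurement cannot be quantified (e.g. non-positive PSV, empty ROI)."""


class DegenerateReferenceError(PlacentapdError):
    """FRI reference means are too close for the normalization to be defined."""


class UnbalancedDesignError(PlacentapdError):
    """Repeated-measures input has missing subject x time cells."""


class UndefinedSlopeError(PlacentapdError):
    """A per-subject slope is requested on a degenerate time grid."""
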