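"""Exception hierarchy for the ramancell pipeline.

Every stage raises a subclass of :class:`RamanCellError`, so callers (and the
CLI) can distinguish configuration problems from data problems.
"""


class RamanCellError(Exception):
    """Base class for all ramancell errors."""


class MalformedInputError(RamanCellError, ValueError):
    """A file or in-memory structure violates the interchange contract."""


class AxisError(RamanCellError, ValueError):
    """Wavenumber axis is invalid (non-increasing, non-positive, too short)."""


class DimensionError(RamanCellError, ValueError):
    """Array shapes are inconsistent (map vs mask vs background)."""


class CalibrationError(RamanCellError, RuntimeError):
    """No usable silicon reference peak found in the calibration window."""


class ParameterError(RamanCellError, ValueError):
    """A parameter is out of its documented range (geometry, K, k, ...)."""


class ConfigError(RamanCellError, ValueError):
    """A run configuration fails schema validation."""


class DataError(RamanCellError, ValueError):
    """Data fail a precondition of a pipeline stage (empty mask, zero map, ...)."""
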