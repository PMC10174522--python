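"""Exception hierarchy for eitdct."""


class EitdctError(Exception):
    """Base class for all package errors."""


class GeometryError(EitdctError):
    """Invalid input geometry (e.g. self-intersecting boundary polygon)."""


class MeshError(EitdctError):
    """Mesh generation produced an unusable triangulation."""


class SolverError(EitdctError):
    """Forward or inverse linear system could not be solved."""


class NormalizationError(EitdctError):
    """Baseline voltages too small for normalized difference imaging."""


class CalibrationError(EitdctError):
    """Requested noise figure is not attainable within the lambda bracket."""

    def __init__(self, message, attainable_range=None):
        super().__init__(message)
        self.attainable_range = attainable_range


class RegistrationError(EitdctError):
    """Pixel raster and mesh do not overlap in physical coordinates."""


class ShapeError(EitdctError):
    """Mismatched array dimensions."""


class UsageError(EitdctError):
    """Invalid argument value."""


class MetricError(EitdctError):
    """Degenerate input to an image metric (e.g. zero denominator)."""


class DataError(EitdctError):
    """Non-finite or otherwise corrupt numeric data."""
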