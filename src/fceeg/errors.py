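"""Exception types shared across the pipeline stages."""

from .montage import MappingError

__all__ = [
    "ConfigurationError",
    "ParameterError",
    "InputError",
    "InterpolationError",
    "CalibrationError",
    "EstimationError",
    "MappingError",
]


class ConfigurationError(ValueError):
    """A configuration field violates its invariant; the message names it."""


class ParameterError(ValueError):
    """An operation parameter is outside its admissible range."""


class InputError(ValueError):
    """Input data are empty or structurally invalid."""


class InterpolationError(RuntimeError):
    """Too few good channels to solve the spherical-spline system."""


class CalibrationError(RuntimeError):
    """Effect-size calibration failed to converge; carries the best ratio."""

    def __init__(self, message: str, best_ratio: float | None = None):
        super().__init__(message)
        self.best_ratio = best_ratio


class EstimationError(RuntimeError):
    """Spectral estimation impossible (e.g. every data chunk too short)."""
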