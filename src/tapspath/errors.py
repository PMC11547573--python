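"""Exception hierarchy shared across the package."""


class TapsPathError(Exception):
    """Base class for all package errors."""


class RegistryError(TapsPathError, KeyError):
    """Unknown name looked up in a registry of named objects."""


class ValidationError(TapsPathError, ValueError):
    """A parameter or specification field failed validation."""


class DegeneracyError(TapsPathError, ValueError):
    """Geometric input is degenerate (collinear align set, coincident points)."""


class ShapeError(TapsPathError, ValueError):
    """Array shapes incompatible with the requested operation."""


class DivergenceError(TapsPathError, RuntimeError):
    """Dynamics produced non-finite coordinates or energies."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ZeroDistanceError(TapsPathError, ValueError):
    """Adjacent path nodes coincide; the path metric is ill-defined."""


class SupportError(TapsPathError, ValueError):
    """Histogram support is disconnected; WHAM cannot bridge the gap."""


class SelectionError(TapsPathError, ValueError):
    """An atom/particle selection is empty or out of range."""


class StarvationWarning(UserWarning):
    """A sampling bin received no (or too few) frames."""


class LowSupportWarning(UserWarning):
    """An estimate rests on very few samples."""


class CoverageWarning(UserWarning):
    """Adjacent umbrella windows overlap poorly."""
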