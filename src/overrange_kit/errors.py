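"""Exception hierarchy for overrange-kit.

The CLI maps these onto exit codes: configuration problems exit with 2,
data/measurement problems with 3.
"""

from __future__ import annotations


class OverrangeKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidProtocolError(OverrangeKitError, ValueError):
    """A scan protocol or model parameter is outside its valid domain."""


class ConfigError(OverrangeKitError, ValueError):
    """A run configuration is malformed (empty sweep list, bad key, ...)."""


class SimulationGeometryError(OverrangeKitError):
    """The requested simulation geometry is unrealisable.

    Raised e.g. when a table dosimeter never passes through the beam, or
    when it does not complete its transit strictly inside the beam-on
    window at steady table speed.
    """


class NoSignalError(OverrangeKitError):
    """A trace carries no usable peak (all zero or flat)."""


class AmbiguousPeakError(OverrangeKitError):
    """More than one disjoint above-threshold run was found in a trace."""

    def __init__(self, message: str, runs: list[tuple[float, float]]):
        super().__init__(message)
        #: list of (start_time, stop_time) for each above-threshold run
        self.runs = runs


class EdgeOrderingError(OverrangeKitError, ValueError):
    """Edge times are not ordered as the geometry requires."""


class InconsistentGeometryError(OverrangeKitError):
    """Measured durations/speeds contradict the declared scan geometry."""


class InsufficientDataError(OverrangeKitError, ValueError):
    """Too few data points for the requested fit."""


class GroupingError(OverrangeKitError, ValueError):
    """Results from different protocol groups were mixed in one comparison."""


class CalibrationError(OverrangeKitError, ValueError):
    """Fiducial-marker calibration is impossible (coincident markers)."""


class BandDetectionError(OverrangeKitError):
    """No single exposed band could be found on a film image."""


class TraceFormatError(OverrangeKitError, ValueError):
    """A trace file violates the expected format.

    ``row_index`` points at the first offending data row (0-based,
    counted over data rows only), or is ``None`` for header problems.
    """

    def __init__(self, message: str, row_index: int | None = None):
        super().__init__(message)
        self.row_index = row_index
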