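"""Threshold-crossing analysis of dosimeter traces.

All durations in the methodology are read at a fixed fraction (by default
10%) of the trace maximum: the bore plateau's crossing pair gives the
beam-on time, and the delay between the two table dosimeters' leading
crossings, divided into their known separation, gives the table speed.
Crossings are refined below the sampling period by linear interpolation
between the two straddling samples; sample-aligned crossings (no
interpolation) are also supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .errors import AmbiguousPeakError, EdgeOrderingError, NoSignalError
from .simulator import DosimeterTrace

__all__ = [
    "EdgeTimes",
    "detect_edges",
    "beam_on_duration",
    "table_speed_from_traces",
]


@dataclass(frozen=True)
class EdgeTimes:
    """Leading/trailing threshold-crossing times for one trace peak."""

    t_lead: float
    t_trail: float
    threshold_level: float  # absolute reading at which crossings were taken
    peak_value: float

    def __post_init__(self) -> None:
        if not self.t_lead < self.t_trail:
            raise EdgeOrderingError(
                f"t_lead ({self.t_lead}) must precede t_trail ({self.t_trail})"
            )


def detect_edges(
    trace: DosimeterTrace,
    threshold_fraction: float = 0.10,
    *,
    interpolate: bool = True,
    median_filter: bool = False,
) -> EdgeTimes:
    """Find the threshold crossings of the single peak in ``trace``.

    Parameters
    ----------
    threshold_fraction:
        Fraction of the trace maximum defining the threshold.
    interpolate:
        Refine each crossing by linear interpolation between the
        straddling samples (default).  With ``False`` the leading edge is
        the first sample at/above threshold and the trailing edge the
        last, i.e. crossings aligned to the sampling grid.
    median_filter:
        Apply a 3-sample median pre-filter for spike rejection.

    Tie-breaking: if consecutive samples equal the threshold exactly, the
    earliest is the leading crossing and the latest the trailing one.

    Raises
    ------
    NoSignalError
        All-zero or flat trace.
    AmbiguousPeakError
        More than one disjoint above-threshold run; the exception lists
        the runs as (start_time, stop_time) pairs.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    y = np.asarray(trace.readings, dtype=float)
    if median_filter:
        y = medfilt(y, kernel_size=3)
    peak = float(y.max())
    if peak <= 0 or np.isclose(peak, y.min()):
        raise NoSignalError(f"trace '{trace.label}' carries no usable peak")
    thr = threshold_fraction * peak

    above = y >= thr
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    starts += [int(i) + 1 for i in edges if not above[i]]
    stops = [int(i) for i in edges if above[i]]
    if above[-1]:
        stops.append(y.size - 1)
    runs = list(zip(starts, stops))
    t = trace.times
    if len(runs) != 1:
        raise AmbiguousPeakError(
            f"trace '{trace.label}' has {len(runs)} disjoint above-threshold runs",
            [(float(t[i]), float(t[j])) for i, j in runs],
        )
    i, j = runs[0]

    dt = trace.sample_period
    if not interpolate or i == 0:
        t_lead = float(t[i])
    else:
        y0, y1 = y[i - 1], y[i]
        t_lead = float(t[i - 1] + dt * (thr - y0) / (y1 - y0))
    if not interpolate or j == y.size - 1:
        t_trail = float(t[j])
    else:
        y0, y1 = y[j], y[j + 1]
        t_trail = float(t[j] + dt * (thr - y0) / (y1 - y0))
    return EdgeTimes(
        t_lead=t_lead, t_trail=t_trail, threshold_level=thr, peak_value=peak
    )


def beam_on_duration(edges: EdgeTimes) -> float:
    """Time spent above threshold, s (for a bore trace: the beam-on time)."""
    return edges.t_trail - edges.t_lead


def table_speed_from_traces(
    a: EdgeTimes,
    b: EdgeTimes,
    separation: float,
    edge_mode: str = "lead",
) -> float:
    """Table speed from the transit delay between two table dosimeters.

    ``a`` must be the dosimeter the beam reaches first.  In ``lead`` mode
    the speed is separation over the leading-edge delay; in
    ``lead_and_trail`` mode the leading- and trailing-edge delays are
    averaged first, which halves independent single-edge timing noise.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if edge_mode not in ("lead", "lead_and_trail"):
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    dt_lead = b.t_lead - a.t_lead
    if dt_lead <= 0:
        raise EdgeOrderingError(
            "trace b must reach the beam after trace a (non-positive lead delay)"
        )
    if edge_mode == "lead":
        return separation / dt_lead
    dt_trail = b.t_trail - a.t_trail
    if dt_trail <= 0:
        raise EdgeOrderingError("non-positive trailing-edge delay")
    return separation / ((dt_lead + dt_trail) / 2.0)
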