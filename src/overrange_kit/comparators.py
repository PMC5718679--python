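"""Literature comparators: dose-slope extrapolation and console readings.

The dose-slope method scans a varying number of rotations n and fits
DLP(n) by ordinary least squares; the intercept at n = 0 is the DLP due
solely to over-ranging, which divided by CTDIvol gives a length.  The
console-reading method takes the scanner's displayed over-range, which
film measurements show to be too large by one half of the beam
collimation; subtracting W/2 gives the "adjusted console reading".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GroupingError, InsufficientDataError
from .overranging import OverrangeResult

__all__ = [
    "RotationSeries",
    "dose_slope_overrange",
    "adjusted_console_overrange",
    "method_comparison",
]


@dataclass
class RotationSeries:
    """(number of rotations, DLP) pairs acquired at fixed protocol."""

    n_rotations: np.ndarray
    dlp: np.ndarray  # mGy.cm
    ctdi_vol: float  # mGy
    collimation: float  # mm
    pitch: float

    def __post_init__(self) -> None:
        self.n_rotations = np.asarray(self.n_rotations, dtype=float)
        self.dlp = np.asarray(self.dlp, dtype=float)
        if self.n_rotations.shape != self.dlp.shape or self.n_rotations.ndim != 1:
            raise InsufficientDataError("n_rotations and dlp must be matching 1-D")
        if self.ctdi_vol <= 0:
            raise ValueError("ctdi_vol must be positive")
        order = np.argsort(self.n_rotations)
        if np.any(np.diff(self.dlp[order]) <= 0):
            raise InsufficientDataError(
                "dlp must be strictly increasing in n_rotations"
            )


def dose_slope_overrange(series: RotationSeries) -> OverrangeResult:
    """Over-ranging length by linear extrapolation of DLP to zero rotations.

    Fits ``dlp = a + b n`` by unweighted OLS; the intercept ``a`` is the
    over-ranging DLP and ``a / ctdi_vol`` (converted cm to mm) the length.
    The conversion assumes DLP = CTDIvol x length exactly across the
    over-ranged region, the method's inherent first-approximation bias.
    A negative intercept yields a degenerate-flagged result, not an error.
    """
    if np.unique(series.n_rotations).size < 3:
        raise InsufficientDataError(
            "dose-slope fit needs at least 3 distinct rotation counts"
        )
    fit = stats.linregress(series.n_rotations, series.dlp)
    intercept_dlp = float(fit.intercept)
    length_mm = intercept_dlp / series.ctdi_vol * 10.0
    unc_mm = float(fit.intercept_stderr) / series.ctdi_vol * 10.0
    return OverrangeResult(
        length=length_mm,
        total_exposed_length=math.nan,
        voi_length=math.nan,
        table_speed=math.nan,
        beam_on_duration=math.nan,
        uncertainty=unc_mm,
        method="dose_slope",
        includes_penumbra=True,  # DLP integrates the actual exposure
        degenerate=length_mm <= 0,
        pitch=series.pitch,
        diagnostics={
            "slope_mgycm_per_rotation": float(fit.slope),
            "intercept_mgycm": intercept_dlp,
            "r_squared": float(fit.rvalue) ** 2,
            "intercept_stderr_mgycm": float(fit.intercept_stderr),
            "n_points": int(series.n_rotations.size),
        },
    )


def adjusted_console_overrange(console_overrange: float, collimation: float) -> float:
    """Console over-range corrected down by half the beam collimation, mm.

    The scanner console adds a full collimation width to the table
    displacement, but film shows the exposure extends only half a
    collimation beyond the displayed over-range; the corrected value is
    ``console_overrange - collimation / 2``.  An over-corrected
    (non-positive) result is returned with a warning rather than raised.
    """
    if console_overrange <= 0:
        raise ValueError("console_overrange must be positive")
    if collimation < 0:
        raise ValueError("collimation must be non-negative")
    adjusted = console_overrange - collimation / 2.0
    if adjusted <= 0:
        warnings.warn(
            f"adjusted console reading {adjusted:.2f} mm is non-positive "
            "(over-correction)",
            UserWarning,
            stacklevel=2,
        )
    return adjusted


def method_comparison(
    results: list[OverrangeResult], reference: OverrangeResult
) -> pd.DataFrame:
    """Relative differences of each method against a reference estimate.

    Returns a table with one row per result: method, length, and
    100 x (method - reference) / reference.  All results (and the
    reference) must belong to the same pitch group when pitch metadata is
    present.
    """
    if not results:
        raise ValueError("results list must be non-empty")
    pitches = {
        r.pitch for r in [*results, reference] if r.pitch is not None
    }
    if len(pitches) > 1:
        raise GroupingError(
            f"results mix pitches {sorted(pitches)}; compare one pitch at a time"
        )
    rows = [
        {
            "method": r.method,
            "length_mm": r.length,
            "reference_mm": reference.length,
            "rel_diff_pct": 100.0 * (r.length - reference.length) / reference.length,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["method", "length_mm", "reference_mm", "rel_diff_pct"])
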