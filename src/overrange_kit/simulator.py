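"""Dosimeter-trace simulator with a known ground-truth over-ranging length.

The simulator stands in for the scanner plus fiber-optic dosimetry
hardware: it produces the three dose-rate time series (one stationary
"bore" dosimeter, two translating "table" dosimeters) that the estimators
consume, and returns alongside them the ground truth used to generate
them, so every estimator can be tested by parameter recovery.

Geometry conventions (patient coordinates, mm):

* the VOI spans ``[0, voi_length]``;
* the exposed region spans ``[-L/2, voi_length + L/2]`` where ``L`` is the
  ground-truth over-ranging length (the over-range is split evenly
  between the two ends — only the total is observable);
* the beam's longitudinal profile is a trapezoid whose full width at the
  10% level equals the nominal collimation ``W`` (flat core
  ``W - 1.8 p``, linear penumbrae of width ``p`` each side);
* the beam centre therefore travels ``D = voi_length + L - W`` during the
  beam-on time ``T``, so ``v T + W - voi_length = L`` identically for
  ramp-free scans.

Edge-time convention: the beam-on envelope ramps are placed so that the
10%-of-maximum crossing of the bore trace falls exactly at the beam-on
and beam-off instants; likewise a table-trace 10% crossing marks the
instant the dosimeter sits ``W/2`` from the beam centre.  This mirrors
the measurement convention (all durations are read at the 10% level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidProtocolError, SimulationGeometryError
from .scan_model import (
    DosimeterLayout,
    OverrangeModel,
    ScanProtocol,
    default_layout,
    ground_truth_overrange,
    nominal_table_speed,
)

__all__ = [
    "DosimeterTrace",
    "SimulationSpec",
    "SimulationTruth",
    "simulate_scan",
    "simulate_cr_strip",
    "render_exposure_band",
    "trapezoid_trace",
    "plateau_trace",
    "CRStripInfo",
]


@dataclass
class DosimeterTrace:
    """A uniformly sampled dose-rate time series for one point dosimeter.

    ``readings`` are non-negative dose-rate samples in arbitrary but
    consistent units; ``t0`` is the time of the first sample.
    """

    readings: np.ndarray
    sample_period: float = 0.010
    t0: float = 0.0
    label: str = "bore"

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 1 or self.readings.size < 2:
            raise ValueError("readings must be a 1-D array with >= 2 samples")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if np.any(self.readings < 0):
            raise ValueError("readings must be non-negative")

    @property
    def times(self) -> np.ndarray:
        """Sample times, s."""
        return self.t0 + np.arange(self.readings.size) * self.sample_period


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth embedded in a simulated scan (never fed to estimators)."""

    overrange_length: float  # mm
    table_speed: float  # mm/s, steady-state
    beam_on_duration: float  # s
    translation: float  # mm travelled during beam-on
    total_exposed_length: float  # mm, translation + one collimation width
    t_beam_on: float  # s
    t_beam_off: float  # s


@dataclass
class SimulationSpec:
    """Everything needed to simulate one helical scan.

    ``noise_sd`` is the relative (multiplicative Gaussian) noise per
    sample; ``gantry_ripple`` the relative amplitude of the
    rotation-frequency intensity modulation (free-in-air response varies
    by less than 5% over a revolution, hence the 0.05 cap);
    ``ramp_time`` the duration of the linear table acceleration at scan
    start (deceleration happens after beam-off and is not modelled).
    ``detector_size_mm`` > 0 averages the beam profile over the finite
    scintillator extent (boxcar convolution).
    """

    protocol: ScanProtocol
    layout: DosimeterLayout | None = None
    model: OverrangeModel | None = None
    noise_sd: float = 0.01
    ramp_time: float = 0.0
    gantry_ripple: float = 0.0
    seed: int = 0
    sample_period: float = 0.010
    penumbra_fraction: float = 0.10
    bore_edge_time: float = 0.05
    pre_roll: float = 0.5
    post_roll: float = 0.5
    detector_size_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidProtocolError("noise_sd must be >= 0")
        if self.ramp_time < 0:
            raise InvalidProtocolError("ramp_time must be >= 0")
        if not 0.0 <= self.gantry_ripple <= 0.05:
            raise InvalidProtocolError("gantry_ripple must lie in [0, 0.05]")
        if self.sample_period <= 0:
            raise InvalidProtocolError("sample_period must be positive")
        if not 0.0 < self.penumbra_fraction < 1.0 / 1.8:
            raise InvalidProtocolError(
                "penumbra_fraction must lie in (0, 1/1.8) to keep a flat core"
            )


def _beam_profile(
    u: np.ndarray | float,
    collimation: float,
    penumbra_fraction: float,
    detector_size_mm: float = 0.0,
) -> np.ndarray:
    """Relative beam intensity at longitudinal offset ``u`` from centre.

    Trapezoid with full width ``collimation`` at the 10% level; optional
    boxcar average over the finite detector extent.
    """
    p = penumbra_fraction * collimation
    flat_half = (collimation - 1.8 * p) / 2.0
    u = np.asarray(u, dtype=float)

    def trap(x: np.ndarray) -> np.ndarray:
        return np.clip((flat_half + p - np.abs(x)) / p, 0.0, 1.0)

    if detector_size_mm <= 0:
        return trap(u)
    offsets = np.linspace(
        -detector_size_mm / 2.0, detector_size_mm / 2.0, 9
    )
    return np.mean([trap(u + o) for o in offsets], axis=0)


def _envelope(t: np.ndarray, t_on: float, t_off: float, tau: float) -> np.ndarray:
    """Beam-on envelope: linear edges with 10% crossings at t_on / t_off."""
    knots = np.array(
        [t_on - 0.1 * tau, t_on + 0.9 * tau, t_off - 0.9 * tau, t_off + 0.1 * tau]
    )
    return np.interp(t, knots, [0.0, 1.0, 1.0, 0.0])


def _displacement(
    t: np.ndarray | float, t_on: float, speed: float, ramp_time: float
) -> np.ndarray:
    """Table displacement since beam-on, with a leading linear speed ramp."""
    dt = np.asarray(t, dtype=float) - t_on
    if ramp_time <= 0:
        return speed * np.clip(dt, 0.0, None)
    s = np.where(
        dt <= 0,
        0.0,
        np.where(
            dt < ramp_time,
            speed * dt**2 / (2.0 * ramp_time),
            speed * dt - speed * ramp_time / 2.0,
        ),
    )
    return s


def simulate_scan(
    spec: SimulationSpec,
) -> tuple[DosimeterTrace, DosimeterTrace, DosimeterTrace, SimulationTruth]:
    """Simulate one helical scan; return (bore, table_1, table_2, truth).

    The bore trace is a plateau whose 10%-level duration equals the
    beam-on time; each table trace is a trapezoidal peak whose 10%-level
    full width equals (collimation + detector size) / table speed.  The
    table translation is chosen so that the exposed length equals
    ``voi_length + truth.overrange_length``.
    """
    prot = spec.protocol
    v = nominal_table_speed(prot)
    if v <= 0:
        raise SimulationGeometryError(
            "table speed must be positive to simulate a helical scan"
        )
    model = spec.model if spec.model is not None else OverrangeModel.for_collimation(
        prot.collimation
    )
    L = ground_truth_overrange(model, prot)
    W = prot.collimation
    p = spec.penumbra_fraction * W
    flat_half = (W - 1.8 * p) / 2.0
    base_half = flat_half + p  # beam extent to the zero-intensity point
    D = prot.voi_length + L - W
    if D <= 0:
        raise SimulationGeometryError(
            f"voi_length + over-range ({prot.voi_length + L:.1f} mm) must "
            f"exceed the collimation ({W} mm)"
        )
    r = spec.ramp_time
    T = D / v + r / 2.0  # ramp start loses v*r/2 of travel
    tau = spec.bore_edge_time
    if T <= 2.0 * tau:
        raise SimulationGeometryError("beam-on time too short for the edge ramps")
    t_on = spec.pre_roll
    t_off = t_on + T

    layout = spec.layout if spec.layout is not None else default_layout(prot)
    center_start = -L / 2.0 + W / 2.0

    # Each table dosimeter must complete its transit (to the beam base,
    # including detector extent) strictly inside the beam-on window and
    # after the acceleration ramp, so its trapezoid is clean.
    eff_half = base_half + spec.detector_size_mm / 2.0
    guard = max(r, 0.9 * tau)
    s_guard_lo = float(_displacement(t_on + guard, t_on, v, r))
    s_guard_hi = D - v * 0.9 * tau
    for x in layout.table_positions:
        s_entry = x - center_start - eff_half
        s_exit = x - center_start + eff_half
        if s_exit <= 0 or s_entry >= D:
            raise SimulationGeometryError(
                f"table dosimeter at {x:.1f} mm stays outside the beam for "
                "the entire scan"
            )
        if s_entry < s_guard_lo or s_exit > s_guard_hi:
            raise SimulationGeometryError(
                f"table dosimeter at {x:.1f} mm does not transit fully "
                "inside the steady-speed beam-on window"
            )

    dt = spec.sample_period
    n = int(np.floor((t_off + spec.post_roll) / dt)) + 1
    t = np.arange(n) * dt
    env = _envelope(t, t_on, t_off, tau)
    z_c = center_start + _displacement(t, t_on, v, r)

    rng = np.random.default_rng(spec.seed)

    def finalize(base: np.ndarray, label: str) -> DosimeterTrace:
        out = base.copy()
        if spec.gantry_ripple > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            out = out * (
                1.0
                + spec.gantry_ripple
                * np.sin(2.0 * np.pi * t / prot.rotation_time + phase)
            )
        if spec.noise_sd > 0:
            out = out * (1.0 + rng.normal(0.0, spec.noise_sd, size=n))
        return DosimeterTrace(
            readings=np.clip(out, 0.0, None),
            sample_period=dt,
            t0=0.0,
            label=label,
        )

    bore = finalize(env, "bore")
    tables = []
    for i, x in enumerate(layout.table_positions, start=1):
        prof = _beam_profile(
            x - z_c, W, spec.penumbra_fraction, spec.detector_size_mm
        )
        tables.append(finalize(env * prof, f"table_{i}"))

    truth = SimulationTruth(
        overrange_length=L,
        table_speed=v,
        beam_on_duration=T,
        translation=D,
        total_exposed_length=D + W,
        t_beam_on=t_on,
        t_beam_off=t_off,
    )
    return bore, tables[0], tables[1], truth


# ---------------------------------------------------------------------------
# Synthetic single traces (worked-example construction, tests, CLI demos)
# ---------------------------------------------------------------------------

def trapezoid_trace(
    lead_time: float,
    speed: float,
    collimation: float,
    *,
    penumbra_fraction: float = 0.10,
    sample_period: float = 0.010,
    duration: float | None = None,
    label: str = "table_1",
) -> DosimeterTrace:
    """A single beam-transit trapezoid whose leading 10% crossing is exact.

    Builds the trace a table dosimeter would record while crossing a beam
    of the given collimation at the given speed, with the rising
    10%-of-maximum crossing placed exactly at ``lead_time``.
    """
    if speed <= 0 or collimation <= 0:
        raise ValueError("speed and collimation must be positive")
    center_time = lead_time + (collimation / 2.0) / speed
    transit = collimation * 1.2 / speed
    if duration is None:
        duration = center_time + transit + 1.0
    n = int(np.floor(duration / sample_period)) + 1
    t = np.arange(n) * sample_period
    u = (t - center_time) * speed
    y = _beam_profile(u, collimation, penumbra_fraction)
    return DosimeterTrace(y, sample_period=sample_period, t0=0.0, label=label)


def plateau_trace(
    t_on: float,
    t_off: float,
    *,
    edge_time: float = 0.05,
    sample_period: float = 0.010,
    post_roll: float = 0.5,
    label: str = "bore",
) -> DosimeterTrace:
    """A bore-style plateau whose 10% crossings fall at t_on and t_off."""
    if not t_off > t_on:
        raise ValueError("t_off must exceed t_on")
    n = int(np.floor((t_off + post_roll) / sample_period)) + 1
    t = np.arange(n) * sample_period
    y = _envelope(t, t_on, t_off, edge_time)
    return DosimeterTrace(y, sample_period=sample_period, t0=0.0, label=label)


# ---------------------------------------------------------------------------
# Synthetic CR film strip
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRStripInfo:
    """Ground truth accompanying a synthetic CR strip image."""

    mm_per_pixel: float
    marker_columns: tuple[float, float]  # drawn centre columns, px
    marker_separation_mm: float
    third_marker_column: float
    band_length_mm: float  # exposed band length at the 10% level
    translation_mm: float
    z_origin_mm: float  # patient coordinate of column 0's left edge


def render_exposure_band(
    translation: float,
    collimation: float,
    mm_per_pixel: float,
    *,
    penumbra_fraction: float = 0.10,
    height_px: int = 64,
    margin_mm: float = 20.0,
    band_row_fraction: float = 0.6,
    image_width_px: int | None = None,
) -> np.ndarray:
    """Render the longitudinal exposure band of a helical scan.

    The band is the convolution of the table translation with the beam
    profile: a trapezoid whose extent at the 10% level equals
    ``translation + collimation`` (a stationary table exposes exactly one
    beam width).  Returns a float image in [0, 1], band along axis 1.
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    if translation < 0 or collimation <= 0:
        raise ValueError("translation must be >= 0 and collimation positive")
    p = penumbra_fraction * collimation
    flat = translation + collimation - 1.8 * p
    base_len = flat + 2.0 * p
    width_mm = base_len + 2.0 * margin_mm
    need_px = int(np.ceil(width_mm / mm_per_pixel))
    if image_width_px is None:
        image_width_px = need_px
    elif image_width_px < need_px:
        raise SimulationGeometryError(
            f"exposed band needs {need_px} px but image is {image_width_px} px wide"
        )
    z = (np.arange(image_width_px) + 0.5) * mm_per_pixel
    center = margin_mm + base_len / 2.0
    profile = np.clip((flat / 2.0 + p - np.abs(z - center)) / p, 0.0, 1.0)
    img = np.zeros((height_px, image_width_px))
    r0 = int(height_px * (1.0 - band_row_fraction) / 2.0)
    r1 = r0 + int(height_px * band_row_fraction)
    img[r0:r1, :] = profile
    return img


def simulate_cr_strip(
    spec: SimulationSpec,
    mm_per_pixel: float,
    *,
    height_px: int = 64,
    margin_mm: float = 20.0,
    image_width_px: int | None = None,
) -> tuple[np.ndarray, CRStripInfo]:
    """Synthetic CR strip for the scan in ``spec``, with fiducial markers.

    The exposed band's physical length at the 10% level equals the table
    translation plus one full collimation width.  Three fiducial markers
    are drawn: one at each VOI boundary (the calibration pair, known
    centre-to-centre separation = VOI length) plus a second marker 10 mm
    inside the VOI start to make the bore-side end identifiable, as on a
    physical strip.
    """
    prot = spec.protocol
    model = spec.model if spec.model is not None else OverrangeModel.for_collimation(
        prot.collimation
    )
    L = ground_truth_overrange(model, prot)
    W = prot.collimation
    D = prot.voi_length + L - W
    if D < 0:
        raise SimulationGeometryError("VOI too short for this collimation")
    img = render_exposure_band(
        D,
        W,
        mm_per_pixel,
        penumbra_fraction=spec.penumbra_fraction,
        height_px=height_px,
        margin_mm=margin_mm,
        image_width_px=image_width_px,
    )
    p = spec.penumbra_fraction * W
    # patient coordinate of the left image edge: the band base starts at
    # margin_mm in image coords and at -(L/2 + 0.1 p) in patient coords
    z_origin = -(L / 2.0 + 0.1 * p) - margin_mm

    def col_of(z_mm: float) -> float:
        return (z_mm - z_origin) / mm_per_pixel - 0.5

    marker_cols = (col_of(0.0), col_of(prot.voi_length))
    third_col = col_of(10.0)
    h = 3  # marker rows; kept small so the column profile stays band-dominated
    for c in (*marker_cols, third_col):
        ci = int(round(c))
        img[2 : 2 + h, max(ci - 2, 0) : ci + 3] = 1.2
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        img = np.clip(img * (1.0 + rng.normal(0, spec.noise_sd, img.shape)), 0, None)
    info = CRStripInfo(
        mm_per_pixel=mm_per_pixel,
        marker_columns=(
            float(round(marker_cols[0])),
            float(round(marker_cols[1])),
        ),
        marker_separation_mm=prot.voi_length,
        third_marker_column=float(round(third_col)),
        band_length_mm=D + W,
        translation_mm=D,
        z_origin_mm=z_origin,
    )
    return img, info
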