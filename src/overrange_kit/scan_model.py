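"""Shared domain types and the deterministic kinematics of a helical CT scan.

In helical (spiral) CT the patient table translates at constant speed while
the gantry rotates, so the X-ray focus traces a helix around the patient.
Reconstruction of the first and last slices of the clinical volume of
interest (VOI) requires projection data from at least half a rotation
beyond each VOI boundary; the extra irradiated length is called
*over-ranging* (also over-scanning).  Its magnitude depends on pitch, beam
collimation and the reconstruction slice thickness, but not on rotation
time or on the VOI length itself.

All lengths in this package are millimetres and all times seconds; the
dose-length product (DLP) alone is reported in the clinical unit mGy·cm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InvalidProtocolError

#: pitch menu of the modelled 16-slice scanner: 0.50 .. 1.50 in steps of 0.05
PITCH_RANGE = (0.5, 1.5)
PITCH_STEP = 0.05
#: total beam collimations (N·T) offered by the modelled scanner, mm
STRICT_COLLIMATIONS = (12.0, 24.0)
#: gantry rotation times offered, s per rotation
STRICT_ROTATION_TIMES = (0.5, 0.75, 1.0, 1.5)
#: reconstruction slice-width menu, mm
STRICT_SLICE_THICKNESSES = (0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
#: smallest reconstruction slice thickness selectable per collimation, mm
MIN_SLICE_THICKNESS = {12.0: 0.75, 24.0: 2.0}


class SeparationWarning(UserWarning):
    """Table-dosimeter separation outside the nominal 20-30 cm band."""


@dataclass(frozen=True)
class ScanProtocol:
    """Operator-selectable acquisition parameters plus the console CTDIvol.

    Parameters
    ----------
    pitch:
        Table travel per rotation divided by total beam collimation
        (dimensionless).
    rotation_time:
        Seconds per gantry rotation.
    collimation:
        Total beam collimation width N·T along the patient axis, mm.
    slice_thickness:
        Reconstruction slice width, mm.
    voi_length:
        Operator-selected scan (VOI) length, mm.
    ctdi_vol:
        Volume CT dose index for the protocol, mGy.  Used only to convert
        lengths into DLP; never derived from the traces.
    kvp, mas:
        Tube voltage / current-time product; informational only.

    Construction is *permissive*: any physically meaningful value is
    accepted (``pitch == 0`` is allowed as a degenerate stationary scan).
    :meth:`validate_strict` additionally checks the values against the
    menus of the modelled scanner.
    """

    pitch: float = 1.0
    rotation_time: float = 0.5
    collimation: float = 24.0
    slice_thickness: float = 3.0
    voi_length: float = 251.0
    ctdi_vol: float = 13.0
    kvp: float = 120.0
    mas: float = 140.0

    def __post_init__(self) -> None:
        if self.pitch < 0:
            raise InvalidProtocolError(f"pitch must be >= 0, got {self.pitch}")
        if self.rotation_time <= 0:
            raise InvalidProtocolError(
                f"rotation_time must be positive, got {self.rotation_time}"
            )
        if self.collimation <= 0:
            raise InvalidProtocolError(
                f"collimation must be positive, got {self.collimation}"
            )
        if self.slice_thickness <= 0:
            raise InvalidProtocolError(
                f"slice_thickness must be positive, got {self.slice_thickness}"
            )
        if self.voi_length <= 0:
            raise InvalidProtocolError(
                f"voi_length must be positive, got {self.voi_length}"
            )
        if self.ctdi_vol < 0:
            raise InvalidProtocolError(
                f"ctdi_vol must be non-negative, got {self.ctdi_vol}"
            )

    def validate_strict(self) -> None:
        """Check the protocol against the modelled scanner's menus.

        Raises :class:`~overrange_kit.errors.InvalidProtocolError` if the
        pitch is off the 0.50..1.50 (step 0.05) grid, or collimation,
        rotation time or slice thickness is not on the scanner menu, or
        the slice thickness is below the minimum for the collimation.
        """
        lo, hi = PITCH_RANGE
        steps = (self.pitch - lo) / PITCH_STEP
        if not (lo - 1e-9 <= self.pitch <= hi + 1e-9) or abs(
            steps - round(steps)
        ) > 1e-6:
            raise InvalidProtocolError(
                f"pitch {self.pitch} not on the {lo}..{hi} grid (step {PITCH_STEP})"
            )
        if not any(abs(self.collimation - c) < 1e-9 for c in STRICT_COLLIMATIONS):
            raise InvalidProtocolError(
                f"collimation {self.collimation} mm not in {STRICT_COLLIMATIONS}"
            )
        if not any(
            abs(self.rotation_time - r) < 1e-9 for r in STRICT_ROTATION_TIMES
        ):
            raise InvalidProtocolError(
                f"rotation_time {self.rotation_time} s not in {STRICT_ROTATION_TIMES}"
            )
        if not any(
            abs(self.slice_thickness - s) < 1e-9 for s in STRICT_SLICE_THICKNESSES
        ):
            raise InvalidProtocolError(
                f"slice_thickness {self.slice_thickness} mm not on the menu"
            )
        min_st = MIN_SLICE_THICKNESS[float(self.collimation)]
        if self.slice_thickness < min_st - 1e-9:
            raise InvalidProtocolError(
                f"slice_thickness {self.slice_thickness} mm below the "
                f"{min_st} mm minimum for {self.collimation} mm collimation"
            )


@dataclass(frozen=True)
class DosimeterLayout:
    """Longitudinal positions of the three point dosimeters, mm.

    ``table_positions`` are table (patient) coordinates of the two moving
    dosimeters that straddle or sit inside the VOI; ``bore_position`` is
    the stationary in-bore dosimeter, which by construction stays inside
    the fan beam for the whole scan and therefore only times beam-on.
    """

    table_positions: tuple[float, float]
    bore_position: float = 0.0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise InvalidProtocolError(
                "table dosimeters must sit at distinct positions"
            )
        if not 200.0 <= self.separation <= 300.0:
            warnings.warn(
                f"table-dosimeter separation {self.separation:.1f} mm outside "
                "the nominal 200-300 mm band",
                SeparationWarning,
                stacklevel=2,
            )

    @property
    def separation(self) -> float:
        """Distance between the two table dosimeters, mm."""
        return abs(self.table_positions[1] - self.table_positions[0])


def default_layout(protocol: ScanProtocol, margin: float = 15.0) -> DosimeterLayout:
    """Table dosimeters inset ``margin`` mm inside each VOI boundary.

    The inset keeps both beam transits strictly inside the beam-on window
    (at scan start the beam penumbra already overlaps the VOI boundary).
    """
    voi = protocol.voi_length
    if voi <= 2 * margin:
        raise InvalidProtocolError(
            f"voi_length {voi} mm too short for a {margin} mm dosimeter inset"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        return DosimeterLayout(
            table_positions=(margin, voi - margin), bore_position=voi / 2.0
        )


# Reference value of the default pitch law at pitch 1.0 (constant slice
# regime), used to transfer the relative pitch dependence between
# collimations: 33.75 + 20.1 * 1.0.
_PITCH_LAW_REF = 53.85
_SCALE_12MM = 11.1 / _PITCH_LAW_REF


@dataclass(frozen=True)
class OverrangeModel:
    """Ground-truth over-ranging law used by the simulator.

    The over-ranging length is modelled as the product of a pitch law and
    a reconstruction-slice-thickness factor::

        L(pitch, st) = (pitch_intercept + pitch_slope * pitch) * f(st)

    where ``f`` is 1 in the thin-slice regime (``st <= regime_boundary``,
    the cone-beam-corrected reconstruction) and, above the boundary where
    the scanner switches to z-filtering, jumps by ``jump_fraction`` and
    grows linearly::

        f(st) = [constant_region_value * (1 + jump_fraction)
                 + linear_region_slope * (st - regime_boundary)]
                / constant_region_value

    The two laws are combined multiplicatively around the reference
    configuration (pitch 1.0, thin-slice regime) because the joint
    dependence has not been measured; this is a simulator convention.
    By construction the length is independent of rotation time and of the
    VOI length.
    """

    pitch_intercept: float = 33.75
    pitch_slope: float = 20.1
    regime_boundary: float = 4.0
    constant_region_value: float = 25.5
    linear_region_slope: float = (52.5 - 25.5 * 1.77) / 6.0
    jump_fraction: float = 0.77

    @classmethod
    def default_24mm(cls) -> "OverrangeModel":
        """Law for 24 mm total collimation.

        Pitch law anchored at 43.8 mm (pitch 0.5) and 63.9 mm (pitch 1.5);
        z-filtering regime starts above 4 mm slices with a 77% jump,
        reaching 52.5/25.5 times the thin-slice value at 10 mm slices.
        """
        return cls()

    @classmethod
    def default_12mm(cls) -> "OverrangeModel":
        """Law for 12 mm total collimation.

        Thin-slice plateau 11.1 mm (0.75-2 mm slices) with an 88% jump
        into the z-filtering regime, reaching 29.7 mm at 10 mm slices.
        The relative pitch dependence of the 24 mm law is reused, rescaled
        so the plateau at pitch 1.0 equals 11.1 mm.
        """
        return cls(
            pitch_intercept=33.75 * _SCALE_12MM,
            pitch_slope=20.1 * _SCALE_12MM,
            regime_boundary=2.0,
            constant_region_value=11.1,
            linear_region_slope=(29.7 - 11.1 * 1.88) / 8.0,
            jump_fraction=0.88,
        )

    @classmethod
    def for_collimation(cls, collimation: float) -> "OverrangeModel":
        """Default law for a given total collimation (12 mm or 24 mm).

        Unknown collimations fall back to the 24 mm parameters.
        """
        if abs(collimation - 12.0) < 1e-9:
            return cls.default_12mm()
        return cls.default_24mm()


def nominal_table_speed(protocol: ScanProtocol) -> float:
    """Table speed implied by the protocol, mm/s.

    The defining helical relation: speed = pitch x collimation / rotation
    time.  A pitch of zero degenerates to a stationary table.
    """
    if protocol.rotation_time <= 0:  # unreachable via the dataclass, kept for raw use
        raise InvalidProtocolError("rotation_time must be positive")
    return protocol.pitch * protocol.collimation / protocol.rotation_time


def ground_truth_overrange(model: OverrangeModel, protocol: ScanProtocol) -> float:
    """Evaluate the ground-truth over-ranging length, mm.

    Raises :class:`~overrange_kit.errors.InvalidProtocolError` if the
    slice thickness is below the scanner minimum for the collimation, or
    if the model parameters yield a non-positive length.
    """
    min_st = MIN_SLICE_THICKNESS.get(float(protocol.collimation))
    if min_st is not None and protocol.slice_thickness < min_st - 1e-9:
        raise InvalidProtocolError(
            f"slice_thickness {protocol.slice_thickness} mm below the "
            f"{min_st} mm minimum for {protocol.collimation} mm collimation"
        )
    pitch_term = model.pitch_intercept + model.pitch_slope * protocol.pitch
    st = protocol.slice_thickness
    if st <= model.regime_boundary + 1e-12:
        factor = 1.0
    else:
        factor = (
            model.constant_region_value * (1.0 + model.jump_fraction)
            + model.linear_region_slope * (st - model.regime_boundary)
        ) / model.constant_region_value
    length = pitch_term * factor
    if length <= 0:
        raise InvalidProtocolError(
            f"over-ranging model yields non-positive length ({length:.3f} mm)"
        )
    return length
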