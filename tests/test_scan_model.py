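"""Kinematics, protocol validation and the ground-truth over-ranging law."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from overrange_kit import (
    DosimeterLayout,
    OverrangeModel,
    ScanProtocol,
    ground_truth_overrange,
    nominal_table_speed,
)
from overrange_kit.errors import InvalidProtocolError
from overrange_kit.scan_model import SeparationWarning


@pytest.mark.parametrize(
    "pitch, collimation, rotation, expected",
    [
        (1.0, 24.0, 0.5, 48.0),
        (0.0, 24.0, 0.5, 0.0),
        (1.5, 24.0, 0.5, 72.0),
        (0.5, 12.0, 1.5, 4.0),
    ],
)
def test_nominal_table_speed(pitch, collimation, rotation, expected):
    prot = ScanProtocol(pitch=pitch, collimation=collimation, rotation_time=rotation)
    assert nominal_table_speed(prot) == pytest.approx(expected)


def test_nominal_speed_matches_bench_measurement():
    # the measured pitch-1.0, 24 mm, 0.5 s bench value was 48.4 mm/s
    speed = nominal_table_speed(ScanProtocol(pitch=1.0, collimation=24.0, rotation_time=0.5))
    assert abs(speed - 48.4) / 48.4 < 0.01


@given(
    pitch=st.floats(0.0, 1.5),
    collimation=st.sampled_from([12.0, 24.0]),
    rotation=st.sampled_from([0.5, 0.75, 1.0, 1.5]),
)
def test_speed_linear_in_pitch_and_inverse_in_rotation(pitch, collimation, rotation):
    base = nominal_table_speed(
        ScanProtocol(pitch=pitch, collimation=collimation, rotation_time=rotation)
    )
    doubled_rot = nominal_table_speed(
        ScanProtocol(pitch=pitch, collimation=collimation, rotation_time=2 * rotation)
    )
    assert doubled_rot == pytest.approx(base / 2.0)
    if pitch <= 0.75:
        doubled_pitch = nominal_table_speed(
            ScanProtocol(pitch=2 * pitch, collimation=collimation, rotation_time=rotation)
        )
        assert doubled_pitch == pytest.approx(2.0 * base)


class TestGroundTruthOverrange:
    def test_pitch_law_endpoints_and_midpoint(self):
        # default 24 mm law anchored at 43.8 mm (pitch 0.5), 63.9 mm (pitch 1.5)
        model = OverrangeModel.default_24mm()
        for pitch, expected in [(0.5, 43.8), (1.0, 53.85), (1.5, 63.9)]:
            prot = ScanProtocol(pitch=pitch, slice_thickness=3.0)
            assert ground_truth_overrange(model, prot) == pytest.approx(expected)

    def test_zero_pitch_slope_removes_pitch_dependence(self):
        model = OverrangeModel(pitch_intercept=50.0, pitch_slope=0.0)
        vals = {
            ground_truth_overrange(model, ScanProtocol(pitch=p, slice_thickness=3.0))
            for p in (0.5, 1.0, 1.5)
        }
        assert vals == {50.0}

    def test_12mm_constant_region_plateau(self):
        # thin-slice plateau: 1 mm and 2 mm reconstructions give the same
        # 11.1 mm over-range at pitch 1.0
        model = OverrangeModel.default_12mm()
        vals = [
            ground_truth_overrange(
                model,
                ScanProtocol(pitch=1.0, collimation=12.0, slice_thickness=st_),
            )
            for st_ in (0.75, 1.0, 2.0)
        ]
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])
        assert vals[0] == pytest.approx(11.1)

    def test_jump_between_regimes(self):
        model = OverrangeModel.default_12mm()
        below = ground_truth_overrange(
            model, ScanProtocol(pitch=1.0, collimation=12.0, slice_thickness=2.0)
        )
        above = ground_truth_overrange(
            model, ScanProtocol(pitch=1.0, collimation=12.0, slice_thickness=3.0)
        )
        assert above / below > 1.88  # jump plus one mm of linear growth

    @given(
        st_lo=st.sampled_from([2.0, 3.0, 4.0, 5.0, 6.0, 8.0]),
        st_hi=st.sampled_from([3.0, 4.0, 5.0, 6.0, 8.0, 10.0]),
        pitch=st.sampled_from([0.5, 1.0, 1.5]),
    )
    def test_monotone_in_slice_thickness(self, st_lo, st_hi, pitch):
        if st_lo > st_hi:
            st_lo, st_hi = st_hi, st_lo
        model = OverrangeModel.default_24mm()
        lo = ground_truth_overrange(
            model, ScanProtocol(pitch=pitch, slice_thickness=st_lo)
        )
        hi = ground_truth_overrange(
            model, ScanProtocol(pitch=pitch, slice_thickness=st_hi)
        )
        assert hi >= lo - 1e-12

    @given(
        rotation=st.sampled_from([0.5, 0.75, 1.0, 1.5]),
        voi=st.floats(100.0, 400.0),
    )
    def test_invariant_to_rotation_time_and_voi(self, rotation, voi):
        model = OverrangeModel.default_24mm()
        ref = ground_truth_overrange(model, ScanProtocol())
        other = ground_truth_overrange(
            model, ScanProtocol(rotation_time=rotation, voi_length=voi)
        )
        assert other == pytest.approx(ref)

    def test_slice_below_scanner_minimum_raises(self):
        model = OverrangeModel.default_24mm()
        with pytest.raises(InvalidProtocolError):
            ground_truth_overrange(
                model, ScanProtocol(collimation=24.0, slice_thickness=1.0)
            )

    def test_positive_for_all_menu_protocols(self):
        from overrange_kit.scan_model import (
            MIN_SLICE_THICKNESS,
            STRICT_SLICE_THICKNESSES,
        )

        for collim in (12.0, 24.0):
            model = OverrangeModel.for_collimation(collim)
            for pitch in [0.5 + 0.05 * k for k in range(21)]:
                for st_ in STRICT_SLICE_THICKNESSES:
                    if st_ < MIN_SLICE_THICKNESS[collim]:
                        continue
                    prot = ScanProtocol(
                        pitch=pitch, collimation=collim, slice_thickness=st_
                    )
                    assert ground_truth_overrange(model, prot) > 0


class TestProtocolValidation:
    def test_permissive_accepts_off_menu_values(self):
        ScanProtocol(pitch=1.01, collimation=38.4, slice_thickness=7.3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pitch": -0.1},
            {"rotation_time": 0.0},
            {"collimation": -24.0},
            {"voi_length": 0.0},
            {"ctdi_vol": -1.0},
        ],
    )
    def test_permissive_rejects_unphysical(self, kwargs):
        with pytest.raises(InvalidProtocolError):
            ScanProtocol(**kwargs)

    def test_strict_accepts_menu_protocol(self):
        ScanProtocol(pitch=1.05, collimation=24.0, slice_thickness=5.0).validate_strict()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pitch": 1.02},
            {"pitch": 1.55},
            {"collimation": 18.0},
            {"rotation_time": 0.6},
            {"collimation": 24.0, "slice_thickness": 1.0},
        ],
    )
    def test_strict_rejects_off_menu(self, kwargs):
        with pytest.raises(InvalidProtocolError):
            ScanProtocol(**kwargs).validate_strict()


class TestDosimeterLayout:
    def test_separation_is_absolute_distance(self):
        layout = DosimeterLayout(table_positions=(300.0, 50.0))
        assert layout.separation == 250.0

    def test_coincident_positions_rejected(self):
        with pytest.raises(InvalidProtocolError):
            DosimeterLayout(table_positions=(100.0, 100.0))

    def test_warns_outside_nominal_band(self):
        with pytest.warns(SeparationWarning):
            DosimeterLayout(table_positions=(0.0, 97.0))
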