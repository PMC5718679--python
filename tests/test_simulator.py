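"""Trace simulator: kinematics, trapezoid geometry, noise, CR strips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import random_spec

from overrange_kit import (
    DosimeterLayout,
    ScanProtocol,
    SimulationSpec,
    beam_on_duration,
    default_layout,
    detect_edges,
    render_exposure_band,
    simulate_cr_strip,
    simulate_scan,
)
from overrange_kit.errors import InvalidProtocolError, SimulationGeometryError


def noise_free_spec(**prot_kwargs) -> SimulationSpec:
    prot = ScanProtocol(**prot_kwargs)
    return SimulationSpec(protocol=prot, layout=default_layout(prot), noise_sd=0.0)


class TestSimulateScan:
    def test_kinematic_identity_pitch_one(self):
        """Pitch 1, 24 mm, 0.5 s: speed 48 mm/s; leading edges sep/48 apart."""
        spec = noise_free_spec(pitch=1.0, collimation=24.0, rotation_time=0.5)
        bore, t1, t2, truth = simulate_scan(spec)
        assert truth.table_speed == pytest.approx(48.0)
        e1, e2 = detect_edges(t1), detect_edges(t2)
        sep = spec.layout.separation
        # each crossing carries a sub-sample interpolation residual
        assert e2.t_lead - e1.t_lead == pytest.approx(sep / 48.0, abs=2e-3)

    def test_arbitrary_length_run_two_second_edge_delay(self):
        """Dosimeters 97.0 mm apart at 48.5 mm/s: leading edges 2.00 s apart."""
        prot = ScanProtocol(pitch=48.5 * 0.5 / 24.0, collimation=24.0, rotation_time=0.5)
        with pytest.warns(Warning):  # 97 mm is below the nominal spacing band
            layout = DosimeterLayout(table_positions=(77.0, 174.0), bore_position=125.0)
        spec = SimulationSpec(protocol=prot, layout=layout, noise_sd=0.0)
        bore, t1, t2, truth = simulate_scan(spec)
        assert truth.table_speed == pytest.approx(48.5)
        e1, e2 = detect_edges(t1), detect_edges(t2)
        assert e2.t_lead - e1.t_lead == pytest.approx(2.00, abs=1e-4)

    def test_truth_identity_over_random_grid(self, rng):
        """T*v + W - VOI equals the over-range for every noise-free spec."""
        for _ in range(100):
            spec = random_spec(rng)
            _, _, _, truth = simulate_scan(spec)
            lhs = (
                truth.beam_on_duration * truth.table_speed
                + spec.protocol.collimation
                - spec.protocol.voi_length
            )
            assert lhs == pytest.approx(truth.overrange_length, abs=1e-9)
            assert truth.overrange_length > 0

    def test_bore_plateau_width_is_beam_on_time(self):
        spec = noise_free_spec()
        bore, _, _, truth = simulate_scan(spec)
        dur = beam_on_duration(detect_edges(bore))
        assert dur == pytest.approx(truth.beam_on_duration, abs=spec.sample_period)

    def test_table_peak_width_is_collimation_over_speed(self):
        spec = noise_free_spec(pitch=1.0, collimation=24.0)
        _, t1, _, truth = simulate_scan(spec)
        width = beam_on_duration(detect_edges(t1))
        assert width == pytest.approx(
            spec.protocol.collimation / truth.table_speed, abs=spec.sample_period
        )

    def test_finite_detector_broadens_table_peak(self):
        prot = ScanProtocol()
        base = SimulationSpec(protocol=prot, noise_sd=0.0)
        wide = SimulationSpec(protocol=prot, noise_sd=0.0, detector_size_mm=0.5)
        _, t1a, _, truth = simulate_scan(base)
        _, t1b, _, _ = simulate_scan(wide)
        wa = beam_on_duration(detect_edges(t1a))
        wb = beam_on_duration(detect_edges(t1b))
        assert wb > wa
        assert wb == pytest.approx(
            (prot.collimation + 0.5) / truth.table_speed, abs=2 * base.sample_period
        )

    @given(ripple=st.floats(0.0, 0.05))
    def test_ripple_shifts_crossings_under_one_sample(self, ripple):
        prot = ScanProtocol()
        layout = default_layout(prot)
        clean = SimulationSpec(protocol=prot, layout=layout, noise_sd=0.0)
        rippled = SimulationSpec(
            protocol=prot, layout=layout, noise_sd=0.0, gantry_ripple=ripple, seed=7
        )
        _, c1, _, _ = simulate_scan(clean)
        _, r1, _, _ = simulate_scan(rippled)
        ec, er = detect_edges(c1), detect_edges(r1)
        assert abs(er.t_lead - ec.t_lead) <= clean.sample_period
        assert abs(er.t_trail - ec.t_trail) <= clean.sample_period

    def test_same_seed_reproducible_different_seed_not(self):
        prot = ScanProtocol()
        a = simulate_scan(SimulationSpec(protocol=prot, seed=42))[0]
        b = simulate_scan(SimulationSpec(protocol=prot, seed=42))[0]
        c = simulate_scan(SimulationSpec(protocol=prot, seed=43))[0]
        np.testing.assert_array_equal(a.readings, b.readings)
        assert not np.array_equal(a.readings, c.readings)

    def test_dosimeter_outside_scan_raises(self):
        prot = ScanProtocol()
        layout = DosimeterLayout(table_positions=(1000.0, 1250.0))
        with pytest.raises(SimulationGeometryError):
            simulate_scan(SimulationSpec(protocol=prot, layout=layout))

    def test_dosimeter_inside_startup_beam_raises(self):
        # at pitch 0.5 the half over-range is smaller than the beam
        # half-width, so a dosimeter at the VOI edge sits inside the beam
        # penumbra at turn-on
        prot = ScanProtocol(pitch=0.5)
        layout = DosimeterLayout(table_positions=(0.0, 236.0))
        with pytest.raises(SimulationGeometryError):
            simulate_scan(SimulationSpec(protocol=prot, layout=layout))

    def test_ripple_bounds_enforced(self):
        with pytest.raises(InvalidProtocolError):
            SimulationSpec(protocol=ScanProtocol(), gantry_ripple=0.06)


class TestCRStrip:
    def test_band_length_is_translation_plus_collimation(self):
        spec = noise_free_spec()
        img, info = simulate_cr_strip(spec, mm_per_pixel=0.4)
        assert info.band_length_mm == pytest.approx(info.translation_mm + 24.0)
        assert img.ndim == 2 and img.max() > 0

    def test_stationary_table_exposes_one_beam_width(self):
        from overrange_kit import DosimeterTrace

        img = render_exposure_band(0.0, 24.0, mm_per_pixel=0.2)
        profile = img.mean(axis=0)
        trace = DosimeterTrace(profile, sample_period=1.0)
        e = detect_edges(trace, 0.10)
        assert (e.t_trail - e.t_lead) * 0.2 == pytest.approx(24.0, abs=0.4)

    def test_marker_pair_encodes_voi_length(self):
        spec = noise_free_spec()
        _, info = simulate_cr_strip(spec, mm_per_pixel=0.4)
        px_sep = abs(info.marker_columns[1] - info.marker_columns[0])
        assert px_sep * 0.4 == pytest.approx(spec.protocol.voi_length, abs=0.4)

    def test_band_exceeding_image_raises(self):
        spec = noise_free_spec()
        with pytest.raises(SimulationGeometryError):
            simulate_cr_strip(spec, mm_per_pixel=0.4, image_width_px=100)
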