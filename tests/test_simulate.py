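"""Simulator: restitution closed form, capture scheduling, rendering, fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicemap import conditioning, mapping, scenarios
from slicemap.simulate import (
    ArtifactParams,
    ConductionSpec,
    Grid,
    Rect,
    RegionSpec,
    SimProtocol,
    WaveformParams,
    build_activation_schedule,
    read_ground_truth,
    render_movie,
    restitution_function,
    steady_state_duration,
    write_fixture,
)

WF = WaveformParams(apd_max_ms=380, restitution_amplitude_ms=140,
                    restitution_tau_ms=120)


class TestRestitutionFunction:
    @pytest.mark.parametrize("di, expected", [
        (1e9, 380.0),                       # asymptote
        (0.0, 240.0),                       # exp(0) = 1
        (120.0, 380.0 - 140.0 / math.e),    # one time constant
    ])
    def test_closed_form(self, di, expected):
        assert restitution_function(di, WF) == pytest.approx(expected, abs=1e-6)

    def test_negative_di_rejected(self):
        with pytest.raises(ValueError):
            restitution_function(-1.0, WF)

    @given(st.floats(min_value=0, max_value=600),
           st.floats(min_value=0.1, max_value=1000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, di, delta):
        d1 = restitution_function(di, WF)
        d2 = restitution_function(di + delta, WF)
        assert d1 < d2 <= WF.apd_max_ms

    def test_invalid_waveform_rejected(self):
        with pytest.raises(ValueError):
            WaveformParams(apd_max_ms=100, restitution_amplitude_ms=100)

    def test_steady_state_is_fixed_point(self):
        for pcl in (2000, 600, 300):
            d = steady_state_duration(pcl, WF)
            assert restitution_function(max(pcl - d, 0), WF) == pytest.approx(d, abs=1e-6)


def single_pixel_schedule(erp_ms, pcl_ms, n_pulses=14):
    region = RegionSpec("r", Rect(0, 0, 1, 1), erp_ms=erp_ms, waveform=WF)
    protocol = SimProtocol(mode="point", point_site=(0, 0),
                           cycle_lengths_ms=[pcl_ms], pulses_per_step=n_pulses)
    return build_activation_schedule(protocol, [region],
                                     Grid(shape=(1, 1), pixel_size_mm=0.1), 0.5)


class TestCaptureScheduling:
    @pytest.mark.parametrize("erp, pcl, expected_period", [
        (900, 600, 2),     # observed 2:1 at 600 ms
        (900, 400, 3),     # observed 3:1 at 400 ms
        (900, 1000, 1),    # 1:1 at 1 Hz
    ])
    def test_san_capture_ratios(self, erp, pcl, expected_period):
        truth = single_pixel_schedule(erp, pcl)
        acts = truth.activation_times(0, 0)
        # steady-state spacing = expected_period * PCL
        assert np.allclose(np.diff(acts), expected_period * pcl)

    def test_capture_period_matches_floor_rule(self):
        """Brute-force: k = floor(ERP/PCL) + 1 for the strict-inequality rule."""
        for erp in range(200, 1201, 250):
            for pcl in range(200, 2001, 300):
                truth = single_pixel_schedule(erp, pcl, n_pulses=12)
                acts = truth.activation_times(0, 0)
                k = erp // pcl + 1
                assert np.allclose(np.diff(acts), k * pcl), (erp, pcl)

    def test_spontaneous_firing_at_intrinsic_cycle(self):
        region = RegionSpec("san", Rect(0, 0, 1, 1), erp_ms=400, waveform=WF,
                            intrinsic_cycle_ms=1000)
        protocol = SimProtocol(mode="none", total_duration_ms=10_000)
        truth = build_activation_schedule(protocol, [region],
                                          Grid(shape=(1, 1)), 0.5)
        acts = truth.activation_times(0, 0)
        assert acts.size == 10
        assert np.allclose(np.diff(acts), 1000.0)

    def test_phase_reset_by_paced_beat(self):
        """An earlier paced capture resets the pacemaker clock."""
        region = RegionSpec("san", Rect(0, 0, 1, 1), erp_ms=300, waveform=WF,
                            intrinsic_cycle_ms=1000)
        protocol = SimProtocol(mode="point", point_site=(0, 0),
                               cycle_lengths_ms=[600.0], pulses_per_step=4,
                               total_duration_ms=4000)
        truth = build_activation_schedule(protocol, [region], Grid(shape=(1, 1)), 0.5)
        acts = truth.activation_times(0, 0)
        # pacemaker due at t=0 fires first; the 20 ms stimulus falls inside
        # its ERP, later stimuli capture; after pacing stops the next
        # spontaneous beat comes one intrinsic cycle after the last capture
        assert np.allclose(acts, [0, 620, 1220, 1820, 2820, 3820], atol=1e-6)

    def test_point_site_outside_grid_rejected(self):
        region = RegionSpec("r", Rect(0, 0, 4, 4), erp_ms=300, waveform=WF)
        protocol = SimProtocol(mode="point", point_site=(9, 9),
                               cycle_lengths_ms=[1000.0], pulses_per_step=1)
        with pytest.raises(ValueError, match="outside grid"):
            build_activation_schedule(protocol, [region], Grid(shape=(4, 4)), 0.5)


class TestActivationGeometry:
    def test_plane_wave_is_affine_in_propagation_coordinate(self):
        _, truth = scenarios.simulate_plane_wave(0.5, shape=(10, 12), fps=1000)
        arr = truth.events[0].arrival_ms
        # left-edge stimulus: t = t0 + x / v, identical along rows
        assert np.allclose(arr, arr[0][None, :])
        x_mm = np.arange(12) * truth.grid.pixel_size_mm
        slope = np.polyfit(x_mm, arr[0], 1)[0]
        assert slope == pytest.approx(1 / 0.5, rel=1e-9)

    def test_point_source_times_proportional_to_distance(self):
        _, truth = scenarios.simulate_point_source(
            ConductionSpec(0.4), shape=(15, 15), source_px=(7, 7))
        arr = truth.events[0].arrival_ms
        rows, cols = np.mgrid[0:15, 0:15]
        dist_mm = np.hypot(rows - 7, cols - 7) * truth.grid.pixel_size_mm
        assert np.allclose(arr - arr[7, 7], dist_mm / 0.4)

    def test_anisotropic_ellipse(self):
        cv = ConductionSpec(0.6, 0.3, fiber_angle_rad=0.0)
        _, truth = scenarios.simulate_point_source(cv, shape=(21, 21),
                                                   source_px=(10, 10))
        arr = truth.events[0].arrival_ms
        px = truth.grid.pixel_size_mm
        # along fibers (cols): fast; across (rows): slow
        assert arr[10, 15] - arr[10, 10] == pytest.approx(5 * px / 0.6)
        assert arr[15, 10] - arr[10, 10] == pytest.approx(5 * px / 0.3)


class TestRendering:
    def test_upstroke_crossing_matches_schedule(self, plane_wave_20):
        stack, truth = plane_wave_20
        frame_ms = 1000.0 / stack.fps_hz
        tr = conditioning.normalize(conditioning.extract_trace(stack, (10, 5)))
        windows = mapping.segment_beats(tr, stack.stim_times_ms)
        acts = [mapping.activation_time(tr, w) for w in windows]
        truth_acts = truth.activation_times(10, 5)
        assert len(acts) == truth_acts.size
        assert np.max(np.abs(np.asarray(acts) - truth_acts)) < frame_ms

    def test_polarity_flip_negates_about_baseline(self):
        kw = dict(shape=(6, 6), fps=500, pcl_ms=800, n_pulses=2)
        pos, _ = scenarios.simulate_plane_wave(0.5, **kw)
        neg, _ = scenarios.simulate_plane_wave(
            0.5, artifacts=ArtifactParams(polarity=-1), **kw)
        dia = scenarios.ventricular_waveform().diastolic_level
        assert np.allclose(neg.frames, 2 * dia - pos.frames)

    def test_seeded_noise_is_reproducible(self):
        kw = dict(shape=(6, 6), fps=500, pcl_ms=800, n_pulses=1)
        art = ArtifactParams(noise_sd=0.1, seed=42)
        a, _ = scenarios.simulate_plane_wave(0.5, artifacts=art, **kw)
        b, _ = scenarios.simulate_plane_wave(0.5, artifacts=art, **kw)
        assert np.array_equal(a.frames, b.frames)
        c, _ = scenarios.simulate_plane_wave(
            0.5, artifacts=ArtifactParams(noise_sd=0.1, seed=43), **kw)
        assert not np.array_equal(a.frames, c.frames)

    def test_too_short_movie_rejected(self):
        region = RegionSpec("r", Rect(0, 0, 4, 4), erp_ms=300, waveform=WF)
        protocol = SimProtocol(mode="field", cycle_lengths_ms=[500.0],
                               pulses_per_step=2, total_duration_ms=300.0)
        truth = build_activation_schedule(protocol, [region], Grid(shape=(4, 4)), 0.5)
        with pytest.raises(ValueError, match="shorter"):
            render_movie(truth, fps=500)

    def test_calcium_is_delayed_and_slower(self):
        region = RegionSpec("r", Rect(0, 0, 4, 4), erp_ms=300,
                            waveform=WaveformParams(ca_delay_ms=20))
        protocol = SimProtocol(mode="field", cycle_lengths_ms=[1000.0],
                               pulses_per_step=1)
        truth = build_activation_schedule(protocol, [region], Grid(shape=(4, 4)), 0.5)
        vm = render_movie(truth, fps=1000, modality="Vm")
        ca = render_movie(truth, fps=1000, modality="Ca")
        win = mapping.BeatWindow(0, vm.duration_ms)
        t_vm = mapping.activation_time(conditioning.extract_trace(vm, (2, 2)), win)
        t_ca = mapping.activation_time(conditioning.extract_trace(ca, (2, 2)), win)
        assert t_ca - t_vm == pytest.approx(20.0, abs=1.0)
        r_vm = mapping.upstroke_metrics(conditioning.extract_trace(vm, (2, 2)), win)
        r_ca = mapping.upstroke_metrics(conditioning.extract_trace(ca, (2, 2)), win)
        assert r_ca["rise_time_10_90_ms"] > 2 * r_vm["rise_time_10_90_ms"]


class TestFixtureIO:
    def test_round_trip(self, tmp_path):
        stack, truth = scenarios.simulate_plane_wave(0.5, shape=(6, 6), fps=500,
                                                     pcl_ms=800, n_pulses=1)
        stack.frames = np.round(stack.frames)   # integral camera counts
        paths = write_fixture(stack, truth, tmp_path)
        back = conditioning.read_stack(paths["tiff"], paths["sidecar"])
        assert np.array_equal(back.frames, stack.frames)
        assert back.fps_hz == stack.fps_hz
        assert back.stim_times_ms == stack.stim_times_ms
        truth2 = read_ground_truth(paths["truth"])
        assert truth2.label_names == truth.label_names
        np.testing.assert_allclose(truth2.events[0].arrival_ms,
                                   truth.events[0].arrival_ms)
        np.testing.assert_array_equal(truth2.region_labels, truth.region_labels)

    def test_overflow_rejected(self, tmp_path):
        stack, truth = scenarios.simulate_plane_wave(0.5, shape=(6, 6), fps=500,
                                                     pcl_ms=800, n_pulses=1)
        stack.frames = stack.frames * 100       # exceeds 16-bit range
        with pytest.raises(ValueError, match="16-bit"):
            write_fixture(stack, truth, tmp_path)
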