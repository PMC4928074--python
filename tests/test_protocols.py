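"""Capture ratio, ERP estimation, restitution curves, automaticity, regions."""

import warnings

import numpy as np
import pytest

from slicemap import conditioning, scenarios, simulate
from slicemap.conditioning import TissueMask
from slicemap.mapping import DurationMap
from slicemap.protocols import (
    CaptureResult,
    build_restitution,
    capture_ratio,
    classify_regions,
    detect_automaticity,
    estimate_erp,
    region_capture,
)


def paced_acts(pcl, n_stim, period, start=0.0, latency=5.0):
    """Activations following every ``period``-th stimulus."""
    stims = start + pcl * np.arange(n_stim)
    return list(stims[::period] + latency), list(stims)


class TestCaptureRatio:
    @pytest.mark.parametrize("pcl, period", [(1000, 1), (600, 2), (400, 3)])
    def test_periodic_locking(self, pcl, period):
        acts, stims = paced_acts(pcl, 12, period)
        res = capture_ratio(acts, stims)
        assert res.ratio == period

    def test_irregular_pattern_is_none(self):
        stims = list(np.arange(10) * 500.0)
        acts = [s + 5 for s in (stims[2], stims[3], stims[5], stims[8])]
        assert capture_ratio(acts, stims).ratio is None

    def test_no_response_is_none(self):
        res = capture_ratio([], np.arange(8) * 500.0)
        assert res.ratio is None and res.responses == 0

    def test_no_stimuli_rejected(self):
        with pytest.raises(ValueError, match="no stimuli"):
            capture_ratio([100.0], [])

    def test_transient_discarded(self):
        """A 1:1 transient before 2:1 locking must not break the estimate."""
        stims = list(np.arange(12) * 600.0)
        acts = [stims[0] + 5, stims[1] + 5] + [s + 5 for s in stims[2::2]]
        assert capture_ratio(acts, stims, n_discard=2).ratio == 2

    def test_full_pipeline_matches_floor_rule(self):
        """Render-then-analyze equals floor(ERP/PCL)+1 on a small slice."""
        for erp, pcl in [(700, 500), (900, 250), (450, 500)]:
            stack, truth = scenarios.simulate_san_atrial(
                pcl, 4 * (erp // pcl + 1), shape=(16, 16), fps=500,
                san_erp_ms=erp)
            res, _ = region_capture(stack, truth.region_mask("san"))
            assert res.ratio == erp // pcl + 1, (erp, pcl)


class TestEstimateErp:
    def test_definitional_midpoint(self):
        results = [CaptureResult(400, 8, 8, 1), CaptureResult(350, 8, 8, 1),
                   CaptureResult(300, 8, 4, 2)]
        est = estimate_erp(results, step_ms=50)
        assert est.erp_ms == 325.0
        assert est.first_lost_pcl_ms == 300.0
        assert est.last_captured_pcl_ms == 350.0

    @pytest.mark.parametrize("true_erp", [275, 430, 520])
    def test_recovery_within_half_step(self, true_erp):
        """Scheduler-level S1-S1 scan brackets the ERP within 25 ms."""
        results = []
        for pcl in range(700, 199, -50):
            region = simulate.RegionSpec(
                "r", simulate.Rect(0, 0, 1, 1), erp_ms=true_erp)
            protocol = simulate.SimProtocol(
                mode="point", point_site=(0, 0), cycle_lengths_ms=[float(pcl)],
                pulses_per_step=8)
            truth = simulate.build_activation_schedule(
                protocol, [region], simulate.Grid(shape=(1, 1)), 0.5)
            acts = truth.activation_times(0, 0)
            results.append(capture_ratio(acts, truth.stim_times_ms))
        est = estimate_erp(results, step_ms=50)
        assert abs(est.erp_ms - true_erp) <= 25.0

    def test_all_captured_rejected(self):
        results = [CaptureResult(p, 8, 8, 1) for p in (500, 400, 300)]
        with pytest.raises(ValueError, match="outside tested range"):
            estimate_erp(results, 100)

    def test_all_lost_rejected(self):
        results = [CaptureResult(p, 8, 4, 2) for p in (500, 400)]
        with pytest.raises(ValueError, match="outside tested range"):
            estimate_erp(results, 100)


@pytest.fixture(scope="module")
def restitution_series():
    wf = scenarios.ventricular_waveform()
    series = scenarios.simulate_restitution_series(
        [2000, 1000, 600, 400, 300], shape=(10, 10), fps=500, waveform=wf)
    return wf, series


class TestRestitution:
    def test_curve_matches_steady_state_function(self, restitution_series):
        wf, series = restitution_series
        mask = TissueMask(np.ones((10, 10), bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = build_restitution([(p, s) for p, s, _ in series], mask,
                                      use_last=3)
        frame_ms = 2.0
        assert len(curve.points) == 5
        for p in curve.points:
            dss = simulate.steady_state_duration(p["pcl_ms"], wf)
            expected = simulate.restitution_function(
                max(p["pcl_ms"] - dss, 0.0), wf)
            assert p["mean_duration_ms"] == pytest.approx(expected, abs=frame_ms)

    def test_monotone_in_pcl(self, restitution_series):
        _, series = restitution_series
        mask = TissueMask(np.ones((10, 10), bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = build_restitution([(p, s) for p, s, _ in series], mask,
                                      use_last=3)
        durs = [p["mean_duration_ms"] for p in curve.points]  # PCL descending
        assert durs[0] > durs[-1]
        assert all(a >= b - 0.5 for a, b in zip(durs[:-1], durs[1:]))

    def test_flat_restitution_constant(self):
        wf = scenarios.ventricular_waveform(restitution_amplitude_ms=0.0)
        series = scenarios.simulate_restitution_series(
            [1500, 500], shape=(6, 6), fps=500, waveform=wf)
        mask = TissueMask(np.ones((6, 6), bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = build_restitution([(p, s) for p, s, _ in series], mask,
                                      use_last=2)
        d = [p["mean_duration_ms"] for p in curve.points]
        assert abs(d[0] - d[1]) < 2.0

    def test_lost_capture_excluded(self):
        """A cycle length below the tissue ERP drops out with a warning."""
        wf = scenarios.ventricular_waveform()
        series = scenarios.simulate_restitution_series([1000], shape=(6, 6),
                                                       fps=500, waveform=wf)
        stack, truth = scenarios.simulate_san_atrial(
            300, 10, shape=(6, 6), fps=500, san_erp_ms=900, atrial_erp_ms=500)
        mask = TissueMask(np.ones((6, 6), bool))
        with pytest.warns(UserWarning, match="lost 1:1 capture"):
            curve = build_restitution(
                [(1000, series[0][1]), (300, stack)], mask, use_last=2)
        assert [p["pcl_ms"] for p in curve.points] == [1000.0]


class TestAutomaticity:
    def test_unpaced_pacemaker_rate(self):
        acts = list(np.arange(10) * 1000.0)
        out = detect_automaticity(acts, [])
        assert out["spontaneous"] and out["rate_hz"] == pytest.approx(1.0)

    def test_fully_paced_not_spontaneous(self):
        stims = list(np.arange(8) * 800.0)
        acts = [s + 10 for s in stims]
        out = detect_automaticity(acts, stims)
        assert not out["spontaneous"]

    def test_mixed_paced_and_competing_pacemaker(self):
        stims = [0.0, 2000.0, 4000.0]
        acts = [5.0, 1000.0, 2005.0, 3000.0, 4005.0]
        out = detect_automaticity(acts, stims)
        assert out["spontaneous"] and out["n_spontaneous"] == 2

    def test_rendered_san_slice(self):
        stack, truth = scenarios.simulate_san_atrial(
            0, 0, shape=(12, 12), fps=500, intrinsic_cycle_ms=1000,
            total_duration_ms=9500)
        from slicemap.conditioning import extract_trace, lowpass, normalize
        from slicemap.mapping import activation_time, segment_beats
        tr = normalize(lowpass(extract_trace(stack, truth.region_mask("san"))))
        acts = [activation_time(tr, w) for w in segment_beats(tr, [])]
        out = detect_automaticity(acts, [])
        assert out["spontaneous"]
        assert out["rate_hz"] == pytest.approx(1.0, abs=0.02)


class TestClassifyRegions:
    def test_separated_gaussian_clusters_exact(self, rng):
        shape = (20, 20)
        truth_labels = np.zeros(shape, dtype=int)
        truth_labels[5:15, 10:18] = 1
        dur = np.where(truth_labels == 1, 420.0, 240.0) + rng.normal(0, 5, shape)
        rise = np.where(truth_labels == 1, 80.0, 6.0) + rng.normal(0, 1, shape)
        labels = classify_regions(DurationMap(dur), rise,
                                  TissueMask(np.ones(shape, bool)))
        assert np.array_equal(labels, truth_labels)

    def test_homogeneous_single_label(self, rng):
        shape = (15, 15)
        dur = 300.0 + rng.normal(0, 3, shape)
        rise = 6.0 + rng.normal(0, 0.5, shape)
        with pytest.warns(UserWarning, match="unimodal"):
            labels = classify_regions(DurationMap(dur), rise,
                                      TissueMask(np.ones(shape, bool)))
        assert set(np.unique(labels)) == {0}

    def test_too_few_pixels_rejected(self, rng):
        shape = (5, 5)
        with pytest.raises(ValueError, match="minimum"):
            classify_regions(DurationMap(rng.normal(size=shape)),
                             rng.normal(size=shape),
                             TissueMask(np.ones(shape, bool)))
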