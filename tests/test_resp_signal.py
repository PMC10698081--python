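"""Respiratory surrogate: ROI median, moving median, phase labels, gating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respcine import phantom, resp_signal
from respcine.errors import DegenerateSignalError, InsufficientDataError
from respcine.resp_signal import EXPIRATION, INSPIRATION, RoiSpec
from respcine.series import FrameSeries


def _series_from_frames(frames):
    frames = np.asarray(frames, dtype=np.float32)
    n = frames.shape[0]
    return FrameSeries(
        images=frames,
        acq_time_ms=np.arange(n) * 33.0,
        trigger_time_ms=np.zeros(n),
        slice_index=0,
    )


def brute_force_moving_median(x, hw):
    return np.array(
        [np.median(x[max(0, i - hw): i + hw + 1]) for i in range(len(x))]
    )


def brute_force_labels(smoothed, invert=False):
    out = []
    for i in range(1, len(smoothed)):
        d = smoothed[i] - smoothed[i - 1]
        insp = d <= 0 if not invert else d >= 0
        out.append(INSPIRATION if insp else EXPIRATION)
    return np.array([out[0]] + out)


class TestExtractRoiSignal:
    def test_uniform_frame(self):
        series = _series_from_frames(np.full((3, 10, 10), 100.0))
        roi = RoiSpec(0, rect=(0, 10, 0, 10))
        assert np.allclose(resp_signal.extract_roi_signal(series, roi), 100.0)

    def test_three_pixel_median(self):
        frame = np.zeros((1, 1, 3), dtype=np.float32)
        frame[0, 0] = [0.0, 50.0, 200.0]
        series = _series_from_frames(frame)
        roi = RoiSpec(0, rect=(0, 1, 0, 3))
        assert resp_signal.extract_roi_signal(series, roi)[0] == 50.0

    def test_roi_outside_bounds(self):
        series = _series_from_frames(np.zeros((2, 10, 10)))
        with pytest.raises(ValueError):
            resp_signal.extract_roi_signal(series, RoiSpec(0, rect=(0, 20, 0, 5)))

    def test_polygon_roi(self):
        series = _series_from_frames(np.full((2, 20, 20), 7.0))
        roi = RoiSpec(0, polygon=((2, 2), (2, 15), (15, 15), (15, 2)))
        assert np.allclose(resp_signal.extract_roi_signal(series, roi), 7.0)

    def test_monotone_trace_during_inspiration(self, mini_subject_noiseless):
        """During one inspiration the ROI trace falls as the diaphragm descends."""
        sub = mini_subject_noiseless
        roi = RoiSpec(0, rect=phantom.default_roi(sub.config))
        raw = resp_signal.extract_roi_signal(sub.series[0], roi)
        f = sub.truth.frames
        insp = (f["resp_phase"] == "inspiration").to_numpy()
        # first contiguous inspiration block away from the trace edge
        start = 30
        while not insp[start]:
            start += 1
        end = start
        while insp[end]:
            end += 1
        seg = raw[start:end]
        assert seg[0] > seg[-1]


class TestMovingMedian:
    def test_constant(self):
        x = np.full(50, 3.0)
        assert np.allclose(resp_signal.smooth_moving_median(x), 3.0)

    def test_linear_ramp_interior(self):
        x = np.arange(100.0)
        sm = resp_signal.smooth_moving_median(x, 10)
        assert np.allclose(sm[10:-10], x[10:-10])

    def test_spike_removed(self):
        x = np.arange(100.0)
        x[50] += 1000.0
        sm = resp_signal.smooth_moving_median(x, 10)
        assert np.allclose(sm, brute_force_moving_median(x, 10))
        assert abs(sm[50] - 50.0) <= 1.0

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(20):
            n = int(rng.integers(25, 400))
            hw = int(rng.integers(1, min(10, (n - 1) // 2)))
            x = rng.normal(size=n) * rng.uniform(0.1, 100)
            assert np.allclose(
                resp_signal.smooth_moving_median(x, hw),
                brute_force_moving_median(x, hw),
            )

    def test_preserves_monotonicity(self, rng):
        x = np.cumsum(rng.uniform(0, 1, size=120))
        sm = resp_signal.smooth_moving_median(x, 10)
        assert np.all(np.diff(sm) >= 0)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            resp_signal.smooth_moving_median(np.arange(15.0), 10)


class TestLabelPhases:
    def test_decreasing_is_inspiration(self):
        labels = resp_signal.label_phases(np.arange(20.0)[::-1])
        assert set(labels) == {INSPIRATION}

    def test_increasing_is_expiration(self):
        labels = resp_signal.label_phases(np.arange(20.0))
        assert set(labels) == {EXPIRATION}

    def test_triangle_wave_blocks(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        labels = resp_signal.label_phases(x)
        assert np.array_equal(labels, brute_force_labels(x))
        assert set(labels[1:10]) == {EXPIRATION}
        assert set(labels[11:]) == {INSPIRATION}

    def test_zero_derivative_ties_are_inspiration(self):
        labels = resp_signal.label_phases(np.zeros(10))
        assert set(labels) == {INSPIRATION}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    def test_partition_property(self, values):
        labels = resp_signal.label_phases(np.array(values))
        assert labels.shape == (len(values),)
        assert set(labels) <= {INSPIRATION, EXPIRATION}


class TestRescaleAndGate:
    def test_full_span_all_valid(self):
        # square-ish wave: >5% of samples sit at each extreme, so the
        # percentile range equals the full range and nothing is gated
        x = np.tile(np.repeat([0.0, 1.0], 10), 10)
        phase = resp_signal.label_phases(x)
        trace = resp_signal.rescale_and_gate(x, phase)
        assert trace.valid.all()
        assert np.nanmin(trace.normalized) == pytest.approx(0.0)
        assert np.nanmax(trace.normalized) == pytest.approx(1.0)

    def test_deep_sigh_gated_out(self):
        t = np.linspace(0, 8 * 2 * np.pi, 800)
        depth = np.ones_like(t)
        sigh = (t > 2 * 2 * np.pi) & (t < 3 * 2 * np.pi)
        depth[sigh] = 3.0
        x = 1.0 - depth * (1 - np.cos(t)) / 2  # intensity falls in inspiration
        phase = resp_signal.label_phases(x)
        trace = resp_signal.rescale_and_gate(x, phase)
        assert not trace.valid[sigh & (x < np.percentile(x, 5))].any()
        assert trace.valid.sum() > 0.7 * len(x)

    def test_degenerate_flat_signal(self):
        x = np.full(100, 2.0)
        with pytest.raises(DegenerateSignalError):
            resp_signal.rescale_and_gate(x, resp_signal.label_phases(x))

    def test_phantom_default_duration_has_five_cycles(self, mini_subject):
        roi = RoiSpec(0, rect=phantom.default_roi(mini_subject.config))
        trace = resp_signal.build_resp_trace(mini_subject.series[0], roi)
        assert trace.n_cycles >= 5
        assert not trace.low_cycle_warning

    def test_normalized_tracks_truth_depth(self, mini_subject_noiseless):
        from scipy.stats import spearmanr

        sub = mini_subject_noiseless
        roi = RoiSpec(0, rect=phantom.default_roi(sub.config))
        trace = resp_signal.build_resp_trace(sub.series[0], roi)
        tv = sub.truth.frames["tidal_volume_ml"].to_numpy()
        rho = spearmanr(trace.normalized[trace.valid], tv[trace.valid]).statistic
        assert rho > 0.99
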