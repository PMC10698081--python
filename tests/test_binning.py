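"""Binning: phase/class assignment, phase correlation, bin resolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import fourier_shift, gaussian_filter

from respcine import binning, phantom, resp_signal
from respcine.errors import DegenerateSignalError, MetadataError
from respcine.resp_signal import EXPIRATION, INSPIRATION, RoiSpec


class TestCardiacPhaseIndex:
    def test_trigger_zero_is_phase_one(self):
        assert binning.cardiac_phase_index(0.0, 700.0) == 1

    def test_last_bin(self):
        assert binning.cardiac_phase_index(699.0, 700.0) == 25

    def test_out_of_range(self):
        with pytest.raises(MetadataError):
            binning.cardiac_phase_index(700.0, 700.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 0.999), st.floats(0, 0.999))
    def test_monotone_in_trigger_time(self, a, b):
        rr = 700.0
        lo, hi = sorted((a * rr, b * rr))
        assert binning.cardiac_phase_index(lo, rr) <= binning.cardiac_phase_index(hi, rr)


class TestRespiratoryClassIndex:
    def test_shallow_inspiration(self):
        assert binning.respiratory_class_index(0.0, INSPIRATION) == 1

    def test_top_band_closed_expiration(self):
        assert binning.respiratory_class_index(1.0, EXPIRATION) == 8

    def test_uniform_values_spread_evenly(self, rng):
        values = rng.uniform(0, 1, 1000)
        bands = [binning.respiratory_class_index(v, INSPIRATION) for v in values]
        counts = np.bincount(bands, minlength=5)[1:5]
        assert counts.sum() == 1000
        assert np.all(np.abs(counts - 250) < 60)

    def test_gated_out_frame_rejected(self):
        with pytest.raises(ValueError):
            binning.respiratory_class_index(float("nan"), INSPIRATION)


def _smooth_random_image(rng, n=64):
    return gaussian_filter(rng.normal(size=(n, n)), 3)


class TestSubpixelShift:
    def test_identical_images(self, rng):
        img = _smooth_random_image(rng)
        assert binning.subpixel_shift(img, img) == (0.0, 0.0)

    def test_integer_circular_shift(self, rng):
        img = _smooth_random_image(rng)
        shifted = np.roll(img, (3, -2), axis=(0, 1))
        dy, dx = binning.subpixel_shift(img, shifted)
        assert dy == pytest.approx(3.0, abs=0.05)
        assert dx == pytest.approx(-2.0, abs=0.05)

    def test_half_pixel_shift(self, rng):
        img = _smooth_random_image(rng, n=96)
        shifted = np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(img), (0.5, 0.0))))
        dy, dx = binning.subpixel_shift(img, shifted)
        assert dy == pytest.approx(0.5, abs=0.1)
        assert dx == pytest.approx(0.0, abs=0.1)

    def test_all_zero_image(self):
        with pytest.raises(DegenerateSignalError):
            binning.subpixel_shift(np.zeros((8, 8)), np.ones((8, 8)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            binning.subpixel_shift(np.ones((8, 8)), np.ones((9, 9)))


def brute_force_representative(images, depths, class_median, acq_times):
    """Literal reimplementation: all pairwise shifts, mean/SD exclusion,
    SI-distance argmin with earliest-time tie-break."""
    k = len(images)
    if k == 1:
        return 0, []
    mean_shift = []
    for i in range(k):
        mags = []
        for j in range(k):
            if i == j:
                continue
            dy, dx = binning.subpixel_shift(images[i], images[j], 20)
            mags.append(math.hypot(dy, dx))
        mean_shift.append(sum(mags) / len(mags))
    mu = np.mean(mean_shift)
    sd = np.std(mean_shift)
    keep = [i for i in range(k) if abs(mean_shift[i] - mu) <= sd]
    excluded = [i for i in range(k) if i not in keep]
    if k <= 2 or not keep:
        keep, excluded = list(range(k)), []
    best = min(keep, key=lambda i: (abs(depths[i] - class_median), acq_times[i]))
    return best, excluded


class TestSelectBinRepresentative:
    def test_single_candidate(self):
        chosen, excluded = binning.select_bin_representative([7], [0.3], 0.5)
        assert chosen == 7 and excluded == []

    def test_identical_frames_pick_nearest_depth(self, rng):
        img = _smooth_random_image(rng)
        images = [img] * 5
        depths = [0.1, 0.35, 0.52, 0.7, 0.9]
        chosen, excluded = binning.select_bin_representative(
            list(range(5)), depths, 0.5, acq_times=list(range(5)), images=images
        )
        assert chosen == 2
        assert excluded == []

    def test_shifted_outlier_excluded(self, rng):
        img = _smooth_random_image(rng)
        images = [img] * 4 + [np.roll(img, 8, axis=0)]
        chosen, excluded = binning.select_bin_representative(
            list(range(5)), [0.5] * 5, 0.5, acq_times=list(range(5)), images=images
        )
        assert excluded == [4]
        assert chosen == 0  # depth tie broken by earliest acquisition

    def test_matches_brute_force(self, rng):
        for trial in range(8):
            k = int(rng.integers(1, 7))
            base = _smooth_random_image(rng, 48)
            images = [
                np.roll(base, (int(rng.integers(-6, 7)), int(rng.integers(-6, 7))), (0, 1))
                for _ in range(k)
            ]
            depths = rng.uniform(0, 1, k).tolist()
            times = rng.permutation(k).astype(float).tolist()
            median = float(rng.uniform(0, 1))
            got = binning.select_bin_representative(
                list(range(k)), depths, median, acq_times=times, images=images
            )
            assert got == brute_force_representative(images, depths, median, times)


def brute_force_assignment(trigger, rr, normalized, phase, valid):
    members = {}
    for i in range(len(trigger)):
        if not valid[i]:
            continue
        p = int(trigger[i] // (rr / 25)) + 1
        band = min(int(normalized[i] * 4) + 1, 4)
        c = band if phase[i] == INSPIRATION else band + 4
        members.setdefault((p, c), []).append(i)
    return members


class TestAssembleBinGrid:
    def test_partition_conserves_valid_frames(self, mini_subject):
        roi = RoiSpec(0, rect=phantom.default_roi(mini_subject.config))
        trace = resp_signal.build_resp_trace(mini_subject.series[0], roi)
        grid = binning.assemble_bin_grid(
            mini_subject.series[0], trace, filter_images=False
        )
        total_candidates = sum(
            e.n_candidates for e in grid.entries.values() if e.status == binning.FILLED
        )
        assert total_candidates == int(trace.valid.sum())

    def test_assignment_matches_brute_force(self, mini_subject):
        s = mini_subject.series[0]
        roi = RoiSpec(0, rect=phantom.default_roi(mini_subject.config))
        trace = resp_signal.build_resp_trace(s, roi)
        grid = binning.assemble_bin_grid(s, trace, filter_images=False)
        expected = brute_force_assignment(
            s.trigger_time_ms, s.rr_interval_ms, trace.normalized, trace.phase, trace.valid
        )
        for (p, c), idx in expected.items():
            assert grid.entry(p, c).candidate_frames == idx
        n_filled = sum(1 for e in grid.entries.values() if e.status == binning.FILLED)
        assert n_filled == len(expected)

    def test_default_duration_fill_rate(self, mini_subject):
        """A full-length slice fills at least 85% of its 200 bins honestly."""
        roi = RoiSpec(0, rect=phantom.default_roi(mini_subject.config))
        trace = resp_signal.build_resp_trace(mini_subject.series[0], roi)
        grid = binning.assemble_bin_grid(
            mini_subject.series[0], trace, filter_images=False
        )
        assert grid.count(binning.FILLED) >= 0.85 * grid.total_bins

    def test_inspiration_only_borrows_all_expiration(self, mini_subject):
        s = mini_subject.series[0]
        roi = RoiSpec(0, rect=phantom.default_roi(mini_subject.config))
        trace = resp_signal.build_resp_trace(s, roi)
        trace.valid &= trace.phase == INSPIRATION
        grid = binning.assemble_bin_grid(s, trace, filter_images=False)
        for p in range(1, 26):
            for c in range(5, 9):
                assert grid.entry(p, c).status == binning.BORROWED

    def test_borrow_prefers_same_respiratory_phase(self):
        # class 2 empty: nearest same-side neighbors (1, 3, 4) come before
        # any expiration class
        order = binning._neighbor_order(2, 4)
        assert order[:3] == [1, 3, 4]
        assert all(c > 4 for c in order[3:])


class TestBinFillStats:
    def test_study_bin_total(self):
        assert binning.total_bin_count([11, 11, 11, 11, 12, 12]) == 13600
        assert binning.total_bin_count([10, 11, 11, 12, 12, 12]) == 13600

    def test_reported_percentages(self):
        assert binning.fill_percentage(12305, 13600) == 90.5
        assert binning.fill_percentage(12197, 13600) == 89.7

    def test_zero_slices(self):
        assert binning.total_bin_count([]) == 0
        assert binning.fill_percentage(0, 0) == 0.0
        stats = binning.bin_fill_stats([])
        assert stats["total_bins"] == 0 and stats["filled"] == 0
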