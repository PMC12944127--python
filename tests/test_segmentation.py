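"""Hybrid segmentation: scores, fusion, boundary detection, refinement."""

import numpy as np
import pytest

from remsacc import (
    REMInterval,
    SegmentationParams,
    Segment,
    amplitude_score,
    derivative_series,
    detect_boundaries,
    fuse_scores,
    mad_threshold,
    morphology_score,
    refine_segments,
    segment_interval,
)
from remsacc.segmentation import morphology_raw
from remsacc.synth import SynthConfig, synth_rem_recording


class TestDerivative:
    def test_constant_gives_zeros(self):
        np.testing.assert_allclose(derivative_series(np.full(10, 2.5)), 0.0)

    def test_hand_difference(self):
        np.testing.assert_allclose(derivative_series(np.array([0.0, 1.0, 3.0, 2.0])), [0, 1, 2, 1])

    def test_homogeneous_in_scale(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        np.testing.assert_allclose(derivative_series(-3.0 * x), 3.0 * derivative_series(x))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            derivative_series(np.array([1.0]))


class TestMADThreshold:
    def test_hand_median_computation(self):
        # median 3, deviations [2,1,0,1,97] -> MAD 1
        assert mad_threshold(np.array([1.0, 2, 3, 4, 100]), k_mad=3.0) == pytest.approx(3.0)

    def test_zero_series_floored(self):
        assert mad_threshold(np.zeros(50), k_mad=3.0) == pytest.approx(3e-12)

    def test_zero_mad_floored(self):
        # median 1, MAD 0 -> floor applies
        assert mad_threshold(np.array([1.0, 1, 1, 1, 5]), k_mad=2.0) == pytest.approx(2e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.exponential(size=301)
        med = np.median(d)
        expected = 2.5 * np.median(np.abs(d - med))
        assert mad_threshold(d, 2.5) == pytest.approx(expected, abs=1e-12)


class TestAmplitudeScore:
    def test_all_subthreshold_zero(self):
        np.testing.assert_allclose(amplitude_score(np.array([1.0, 2, 3]), t_amp=5.0), 0.0)

    def test_hand_minmax(self):
        out = amplitude_score(np.array([0.0, 5.0, 10.0]), t_amp=4.0)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_one_hot(self):
        out = amplitude_score(np.array([0.0, 0.0, 9.0, 0.0]), t_amp=1.0)
        np.testing.assert_allclose(out, [0, 0, 1, 0])

    def test_binary_mode(self):
        out = amplitude_score(np.array([0.0, 5.0, 10.0]), t_amp=4.0, mode="binary")
        np.testing.assert_allclose(out, [0.0, 1.0, 1.0])

    def test_mask_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(size=500)
        counts = [(d > mad_threshold(d, k)).sum() for k in (0.5, 1.0, 2.0, 3.0, 5.0)]
        assert counts == sorted(counts, reverse=True)


class TestMorphologyScore:
    def test_embedded_scaled_kernel_peak(self, kernel, fs):
        x = np.zeros(400)
        q = 137
        x[q : q + kernel.L] = 2.5 * kernel.h
        raw = morphology_raw(x, kernel, shift_window_s=0.05, fs=fs)
        assert raw.max() == pytest.approx(2.5, abs=1e-9)
        assert abs(int(np.argmax(raw)) - q) <= int(0.05 * fs)
        # without shifts the peak sits exactly at the embedding offset
        raw0 = morphology_raw(x, kernel, shift_window_s=0.0, fs=fs)
        assert int(np.argmax(raw0)) == q

    def test_zero_signal_zero_score(self, kernel, fs):
        np.testing.assert_allclose(morphology_score(np.zeros(300), kernel, 0.05, fs), 0.0)

    def test_polarity_invariant(self, kernel, fs):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        a = morphology_score(x, kernel, 0.05, fs)
        b = morphology_score(-x, kernel, 0.05, fs)
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, kernel, fs, seed):
        """Raw score equals a brute-force max over shifted dot products."""
        rng = np.random.default_rng(seed)
        n = 500
        x = rng.normal(size=n)
        W = int(0.05 * fs)
        L = kernel.L
        expected = np.zeros(n)
        for t in range(n):
            best = 0.0
            for tau in range(-W, W + 1):
                s = t + tau
                if 0 <= s <= n - L:
                    best = max(best, abs(float(np.dot(x[s : s + L], kernel.h))))
            expected[t] = best
        got = morphology_raw(x, kernel, 0.05, fs)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_signal_shorter_than_kernel_rejected(self, kernel, fs):
        with pytest.raises(ValueError):
            morphology_raw(np.zeros(kernel.L - 1), kernel, 0.05, fs)


class TestFusion:
    def test_limits_and_arithmetic(self):
        a = np.array([0.2, 0.8])
        m = np.array([0.6, 0.4])
        np.testing.assert_allclose(fuse_scores(a, m, 1.0), a)
        np.testing.assert_allclose(fuse_scores(a, m, 0.0), m)
        np.testing.assert_allclose(fuse_scores(a, m, 0.5), [0.4, 0.6])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores(np.zeros(3), np.zeros(4), 0.5)


class TestBoundaries:
    def test_single_spike_run(self):
        s = np.zeros(100)
        s[40:45] = 1.0
        (seg,) = detect_boundaries(s, 3.0)
        assert (seg.start, seg.end) == (40, 45)

    def test_constant_trace_empty(self):
        assert detect_boundaries(np.full(50, 0.3), 3.0) == []

    def test_two_runs_in_order(self):
        s = np.zeros(200)
        s[20:25] = 1.0
        s[150:160] = 1.0
        segs = detect_boundaries(s, 3.0)
        assert [(g.start, g.end) for g in segs] == [(20, 25), (150, 160)]

    def test_threshold_is_mean_plus_k_sd(self):
        rng = np.random.default_rng(3)
        s = rng.random(1000)
        theta = s.mean() + 2.0 * s.std()
        segs = detect_boundaries(s, 2.0)
        covered = np.zeros(1000, bool)
        for g in segs:
            covered[g.start : g.end] = True
        np.testing.assert_array_equal(covered, s > theta)


class TestRefinement:
    def test_merge_when_gap_below_threshold(self):
        params = SegmentationParams(gap_s=5.0, min_dur_s=0.0, refine_radius_s=0.0)
        segs = [Segment(0, 10), Segment(13, 20)]
        out = refine_segments(segs, np.zeros(30), params, fs=1.0)
        assert [(s.start, s.end) for s in out] == [(0, 20)]

    def test_drop_short_segment(self):
        params = SegmentationParams(gap_s=0.0, min_dur_s=5.0, refine_radius_s=0.0)
        assert refine_segments([Segment(0, 2)], np.zeros(30), params, fs=1.0) == []

    def test_boundary_snaps_to_derivative_peak(self):
        x = np.zeros(30)
        x[12] = 5.0  # |dx/dt| peaks at samples 12 and 13
        params = SegmentationParams(gap_s=0.0, min_dur_s=0.0, refine_radius_s=4.0)
        (out,) = refine_segments([Segment(10, 20)], x, params, fs=1.0)
        assert out.start == 12

    def test_drop_first_order_available(self):
        params = SegmentationParams(gap_s=5.0, min_dur_s=4.0, refine_radius_s=0.0,
                                    refine_order="drop_first")
        segs = [Segment(0, 2), Segment(4, 10)]
        out = refine_segments(segs, np.zeros(30), params, fs=1.0)
        # the 2-sample fragment dies before it can merge
        assert [(s.start, s.end) for s in out] == [(4, 10)]

    def test_outputs_sorted_disjoint(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        params = SegmentationParams()
        segs = [Segment(a, a + rng.integers(3, 40)) for a in range(0, 1900, 60)]
        out = refine_segments(segs, x, params, fs=250.0)
        for a, b in zip(out, out[1:]):
            assert a.end <= b.start
        assert all(s.start < s.end for s in out)


class TestEndToEnd:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_single_clean_saccade_found(self, kernel, fs, alpha):
        """A noiseless recording with one saccade yields exactly one event."""
        cfg = SynthConfig(fs=fs, noise_sd=0.0, drift_amp=0.0, seed=5)
        x, events = synth_rem_recording(cfg, [(5.0, "saccade")], duration_s=12.0)
        from remsacc.preprocess import preprocess_interval

        pre = preprocess_interval(x, fs, REMInterval(0, x.size, fs))
        params = SegmentationParams(alpha=alpha)
        segs, trace = segment_interval(pre.x, fs, kernel, params)
        ev = events[0]
        hits = [
            s for s in segs
            if min(ev.offset_s * fs, s.end) - max(ev.onset_s * fs, s.start) > 0
        ]
        assert len(hits) == 1
        assert trace.s_fused.shape == pre.x.shape
        assert trace.s_amp.min() >= 0 and trace.s_amp.max() <= 1
        assert trace.s_morph.min() >= 0 and trace.s_morph.max() <= 1
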