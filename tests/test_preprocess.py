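"""Spike removal, smoothing, segmentation, QC and Fourier resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cmjkit as ck
from cmjkit.preprocess import UnusableSeriesError
from cmjkit.series import SampledSeries


def series(values, rate=100.0):
    return SampledSeries(np.asarray(values, dtype=float), rate)


class TestRemoveSpikes:
    def test_smooth_ramp_unchanged(self):
        s = series(np.linspace(0, 10, 200))
        out = ck.remove_spikes_zscore(s)
        assert np.array_equal(out.values, s.values)

    def test_constant_unchanged(self):
        s = series(np.full(50, 3.0))
        assert np.array_equal(ck.remove_spikes_zscore(s).values, s.values)

    def test_inserted_spike_recovered(self):
        rng = np.random.default_rng(0)
        base = np.sin(np.linspace(0, 4 * np.pi, 300)) + rng.normal(0, 0.05, 300)
        sd = np.std(base)
        spiked = base.copy()
        spiked[137] += 50 * sd
        out = ck.remove_spikes_zscore(series(spiked))
        assert np.max(np.abs(out.values - base)) < sd

    def test_genuine_motion_untouched(self, clean_recording):
        """A noise-free jump trace has no spikes: removal is the identity,
        even though the flight-phase differences are large."""
        toe = clean_recording.omc.toe
        assert np.array_equal(ck.remove_spikes_zscore(toe).values, toe.values)

    def test_pervasively_spiky_series_is_unusable(self):
        # a cascade of ever-smaller spikes: each pass can only unmask a few,
        # so the budget runs out and the series is declared unusable
        x = np.zeros(200)
        idx = np.arange(2, 198, 4)
        x[idx] = 10.0 ** (8 - 0.25 * np.arange(idx.size)) * (-1.0) ** np.arange(idx.size)
        with pytest.raises(UnusableSeriesError):
            ck.remove_spikes_zscore(series(x))

    def test_too_short(self):
        with pytest.raises(ValueError):
            ck.remove_spikes_zscore(series([1, 2, 3]))


class TestSavgol:
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_quadratic_reproduced_exactly(self, a, b, c):
        t = np.linspace(0, 2, 60)
        s = series(a * t**2 + b * t + c)
        assert np.allclose(ck.smooth_savgol(s).values, s.values, atol=1e-8)

    def test_constant_unchanged(self):
        s = series(np.full(30, 7.5))
        assert np.allclose(ck.smooth_savgol(s).values, 7.5, atol=1e-12)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 5, 500)
        quad = 3 * t**2 - t
        s = series(quad + rng.normal(0, 1.0, t.size))
        resid = ck.smooth_savgol(s).values - quad
        assert np.std(resid) < 0.5

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ck.smooth_savgol(series(np.zeros(20)))


class TestSegmentation:
    def test_three_reps_found_near_truth(self):
        spec = ck.JumpSpec(true_height=25.0, n_reps=3, marker_noise_sd=0.5, seed=9)
        motion = ck.simulate_motion(spec)
        omc = ck.render_omc(motion, spec)
        hip = ck.denoise(omc.hip)
        segs = ck.segment_repetitions(hip)
        assert len(segs) == 3
        for seg, t_apex in zip(segs, motion.apex_times()):
            assert abs(seg.peak_index / 100.0 - t_apex) <= 2 / 100.0

    def test_flat_series_empty(self):
        assert ck.segment_repetitions(series(np.zeros(1000))) == []

    def test_close_peaks_keep_more_prominent(self):
        t = np.arange(0, 10, 0.01)
        x = np.exp(-((t - 4.0) / 0.3) ** 2) + 0.8 * np.exp(-((t - 5.0) / 0.3) ** 2)
        segs = ck.segment_repetitions(series(x), window_t=1.5)
        assert len(segs) == 1
        assert abs(segs[0].peak_index - 400) < 5

    def test_edge_segment_flagged_clipped(self):
        t = np.arange(0, 3, 0.01)
        x = np.exp(-((t - 0.5) / 0.3) ** 2)
        segs = ck.segment_repetitions(series(x), window_t=1.5)
        assert segs and "clipped_window" in segs[0].qc_flags

    def test_count_stable_across_seeds_and_noise(self):
        """Segment count equals the simulated rep count for pixel noise
        up to 2 px across seeds 1..20 (MMC path at 30 fps)."""
        for seed in range(1, 21):
            spec = ck.JumpSpec(true_height=20.0, n_reps=3, pixel_noise_sd=2.0,
                               seed=seed)
            mmc = ck.render_mmc(ck.simulate_motion(spec), spec)
            hip_up = mmc.hip.with_values(-mmc.hip.values)
            hip = ck.smooth_savgol(
                ck.resample_to_length(ck.remove_spikes_zscore(hip_up),
                                      len(hip_up) * 10 // 3))
            assert len(ck.segment_repetitions(hip)) == 3


class TestQcFlags:
    def test_clean_rep_unflagged(self, clean_recording):
        hip = ck.denoise(clean_recording.omc.hip)
        seg = ck.segment_repetitions(hip)[0]
        assert ck.flag_uncharacteristic(seg, hip) == set()

    def test_uncharacteristic_fixture_flagged(self):
        spec = ck.JumpSpec(true_height=20.0, failure_mode="uncharacteristic", seed=3)
        mmc = ck.render_mmc(ck.simulate_motion(spec), spec)
        hip = ck.denoise(mmc.hip.with_values(-mmc.hip.values))
        segs = ck.segment_repetitions(hip)
        assert segs
        flags = set()
        for seg in segs:
            flags |= ck.flag_uncharacteristic(seg, hip)
        assert "uncharacteristic" in flags

    def test_low_confidence_flagged(self, clean_recording):
        hip = ck.denoise(clean_recording.omc.hip)
        seg = ck.segment_repetitions(hip)[0]
        conf = SampledSeries(np.full(len(hip), 0.1), hip.rate)
        assert "low_confidence" in ck.flag_uncharacteristic(seg, hip, conf)


class TestResampling:
    def test_identity_at_same_length(self):
        s = series(np.random.default_rng(2).normal(size=90), rate=30)
        out = ck.resample_to_length(s, 90)
        assert np.allclose(out.values, s.values)

    def test_sinusoid_upsampled_matches_analytic(self):
        # 6 whole periods in the window: band-limited and periodic, so
        # Fourier interpolation is exact
        n, target = 90, 300
        k = 6
        t30 = np.arange(n) / n
        s = series(np.sin(2 * np.pi * k * t30), rate=30)
        out = ck.resample_to_length(s, target)
        t100 = np.arange(target) / target
        assert np.max(np.abs(out.values - np.sin(2 * np.pi * k * t100))) < 1e-6

    def test_constant_stays_constant(self):
        out = ck.resample_to_length(series(np.full(60, 4.2), rate=30), 200)
        assert np.allclose(out.values, 4.2)

    def test_mean_preserved(self):
        s = series(np.random.default_rng(3).normal(size=120), rate=30)
        out = ck.resample_to_length(s, 400)
        assert out.values.mean() == pytest.approx(s.values.mean(), abs=1e-9)

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError):
            ck.resample_to_length(series(np.zeros(100)), 50)

    def test_round_trip_band_limited(self):
        """Upsampling by 3 then reading every 3rd sample returns the
        original for band-limited periodic input."""
        n = 120
        t = np.arange(n) / n
        x = np.sin(2 * np.pi * 3 * t) + 0.5 * np.cos(2 * np.pi * 7 * t)
        out = ck.resample_to_length(series(x, rate=30), 3 * n)
        assert np.max(np.abs(out.values[::3] - x)) < 1e-6
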