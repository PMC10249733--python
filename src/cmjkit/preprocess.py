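"""Denoising, repetition segmentation, QC flagging and resampling of
kinematic time series (marker trajectories and pose keypoints).

The denoising order is fixed: spike removal first (z-scores of the first
differences, linear interpolation across flagged frames), then a
second-order Savitzky-Golay filter with a 21-sample window — wide enough
to suppress high-frequency noise while preserving the main maxima and
minima that segmentation and the height measurement rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, resample, savgol_filter

from .series import SampledSeries

SAVGOL_WINDOW = 21
SAVGOL_ORDER = 2


class UnusableSeriesError(ValueError):
    """Raised when a series is too corrupted to denoise."""


@dataclass
class JumpSegment:
    """One repetition window centred on a hip apex.

    Indices refer to samples of the series the segment was cut from;
    ``qc_flags`` accumulates quality-control findings
    (``spiky``, ``low_confidence``, ``uncharacteristic``, ``clipped_window``).
    """

    peak_index: int
    start_index: int
    end_index: int
    rep_id: int
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.start_index <= self.peak_index <= self.end_index:
            raise ValueError("segment must contain its peak")

    @property
    def usable(self) -> bool:
        return not ({"uncharacteristic", "low_confidence"} & self.qc_flags)


def remove_spikes_zscore(series: SampledSeries, z_thresh: float = 3.0,
                         max_passes: int = 10) -> SampledSeries:
    """Remove isolated spikes by z-scoring the first differences.

    A spike is a single displaced frame: its incoming and outgoing first
    differences are both z-score outliers (|z| above ``z_thresh``) of
    opposite sign. Genuine motion produces sustained same-sign differences
    and passes through untouched. Flagged frames are replaced by linear
    interpolation from the flanking inlier frames; passes repeat until no
    frame is flagged (large spikes inflate the difference s.d. and can mask
    smaller ones on the first pass). A series that still shows spikes after
    ``max_passes``, or where more than half the frames had to be replaced,
    is declared unusable.
    """
    x = series.values.copy()
    if x.size < 5:
        raise ValueError("series too short for spike removal")
    flagged_total = np.zeros(x.size, dtype=bool)
    for _ in range(max_passes):
        d = np.diff(x)
        sd = float(np.std(d))
        if sd == 0:
            return series.with_values(x)
        z = (d - np.mean(d)) / sd
        out = np.abs(z) > z_thresh
        bad = np.zeros(x.size, dtype=bool)
        bad[1:-1] = out[:-1] & out[1:] & (np.sign(d[:-1]) != np.sign(d[1:]))
        if not bad.any():
            return series.with_values(x)
        flagged_total |= bad
        if flagged_total.mean() > 0.5:
            raise UnusableSeriesError(
                "more than half the frames flagged as spikes; series unusable")
        good = np.flatnonzero(~bad)
        x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    raise UnusableSeriesError(
        f"spikes persist after {max_passes} removal passes; series unusable")


def smooth_savgol(series: SampledSeries, window: int = SAVGOL_WINDOW,
                  order: int = SAVGOL_ORDER) -> SampledSeries:
    """Savitzky-Golay smoothing (default order 2, window 21 samples).

    Polynomials up to the filter order pass through unchanged, so the
    filter preserves the local parabolic shape of an apex. Edges are
    handled by polynomial fits on the truncated windows.
    """
    if len(series) < window:
        raise ValueError(f"series length {len(series)} < window {window}")
    return series.with_values(savgol_filter(series.values, window, order, mode="interp"))


def denoise(series: SampledSeries, z_thresh: float = 3.0,
            window: int = SAVGOL_WINDOW, order: int = SAVGOL_ORDER) -> SampledSeries:
    """Spike removal followed by Savitzky-Golay smoothing (fixed order)."""
    return smooth_savgol(remove_spikes_zscore(series, z_thresh), window, order)


def segment_repetitions(hip: SampledSeries, window_t: float = 1.5,
                        prominence_fraction: float = 0.5) -> list[JumpSegment]:
    """Cut one window per jump repetition around each dominant hip peak.

    Peaks are maxima of the (denoised, up-positive) hip trace with
    prominence at least ``prominence_fraction`` of the apex elevation
    (global max minus global median, i.e. the rise above quiet stance) and
    separated by at least ``2 * window_t``. The apex elevation is the right
    scale here: the full range is dominated by the countermovement dip, and
    the final repetition's prominence is bounded by its shallow landing dip
    rather than by the jump itself. Each segment spans ``window_t`` seconds
    to either side of its peak; segments truncated by the series bounds
    carry the ``clipped_window`` flag.
    """
    if window_t <= 0:
        raise ValueError("window_t must be positive")
    x = hip.values
    rng_ = float(np.max(x) - np.median(x)) if x.size else 0.0
    if rng_ == 0:
        return []
    distance = max(1, int(round(2 * window_t * hip.rate)))
    peaks, _ = find_peaks(x, prominence=prominence_fraction * rng_, distance=distance)
    half = int(round(window_t * hip.rate))
    segments = []
    for rep, p in enumerate(peaks):
        a, b = p - half, p + half
        flags = set()
        if a < 0 or b > x.size:
            flags.add("clipped_window")
        segments.append(JumpSegment(peak_index=int(p), start_index=max(a, 0),
                                    end_index=min(b, x.size), rep_id=rep,
                                    qc_flags=flags))
    return segments


def flag_uncharacteristic(segment: JumpSegment, hip: SampledSeries,
                          confidence: SampledSeries | None = None,
                          peak_fraction: float = 0.7,
                          confidence_threshold: float = 0.3) -> set:
    """QC a segment against the single-dominant-peak jump template.

    ``uncharacteristic`` is set when two or more local maxima inside the
    window exceed ``peak_fraction`` of the segment range — the signature of
    pose-estimation failure rather than a jump. ``low_confidence`` is set
    when the median keypoint confidence over the window falls below
    ``confidence_threshold``. Flags are added to ``segment.qc_flags`` and
    also returned.
    """
    x = hip.values[segment.start_index:segment.end_index]
    flags: set = set()
    rng_ = float(np.ptp(x))
    if rng_ > 0:
        level = float(np.min(x)) + peak_fraction * rng_
        peaks, _ = find_peaks(x, height=level, prominence=0.15 * rng_)
        if peaks.size >= 2:
            flags.add("uncharacteristic")
    if confidence is not None:
        c = confidence.values[segment.start_index:segment.end_index]
        if c.size and float(np.median(c)) < confidence_threshold:
            flags.add("low_confidence")
    segment.qc_flags |= flags
    return flags


def resample_to_length(series: SampledSeries, target_len: int) -> SampledSeries:
    """Fourier-domain upsampling to exactly ``target_len`` samples.

    Used to put the 30 fps keypoint series on the 100 Hz marker time base
    after segmentation. Only upsampling is supported; the mean of the
    series is preserved to floating tolerance.
    """
    n = len(series)
    if target_len < n:
        raise ValueError("resample_to_length only upsamples (target >= source)")
    if target_len == n:
        return series.with_values(series.values.copy())
    new_rate = series.rate * target_len / n
    return SampledSeries(resample(series.values, target_len), new_rate,
                         t0=series.t0, name=series.name)


def resample_to_rate(series: SampledSeries, target_rate: float) -> SampledSeries:
    """Fourier upsampling onto a faster uniform rate (e.g. 30 fps -> 100 Hz).

    The sample count scales by ``target_rate / rate`` so the covered span is
    preserved; the resulting rate is within one part in the series length of
    the requested one.
    """
    if target_rate < series.rate:
        raise ValueError("resample_to_rate only upsamples")
    if target_rate == series.rate:
        return series.with_values(series.values.copy())
    target_len = int(round(len(series) * target_rate / series.rate))
    return resample_to_length(series, target_len)
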