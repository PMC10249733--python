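"""Pixel-to-metric rescaling of markerless keypoint series.

Two routes:

* **Reverse minmax (RMM)** — normalise the pixel series to [0, 1] and map it
  onto the min/max range of a reference millimetre series captured
  simultaneously by marker-based equipment. Because it needs that reference,
  RMM is an evaluation-only method.
* **Pixel-to-metric (PTM)** — use gravity as the physical reference. At the
  hip apex of a jump the body is in free fall with zero vertical velocity,
  so after T seconds it has dropped 500 T^2 g millimetres. Equating that to
  the observed pixel drop |d0 - dT| gives the conversion factor
  R = 500 T^2 g / |d0 - dT| mm per pixel, needing no calibration object.

All inputs here are up-positive: image-row pixel series (y growing
downward) must be sign-converted once, upstream, before rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .preprocess import JumpSegment
from .series import SampledSeries

G = 9.81  # m/s^2


class NotEstimableError(ValueError):
    """Raised when the free-fall evidence is too weak to fit a scale."""


@dataclass
class ScaleEstimate:
    """A pixel-to-millimetre conversion factor with its free-fall evidence."""

    R: float                 # mm per px
    free_fall_T: float       # s
    pixel_drop: float        # |d0 - dT| in px
    source: Literal["fitted", "cohort_mean_fallback"] = "fitted"

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("scale R must be positive")

    def to_dict(self) -> dict:
        return {"R_mm_per_px": self.R, "free_fall_T_s": self.free_fall_T,
                "pixel_drop_px": self.pixel_drop, "source": self.source}


def minmax(values: np.ndarray) -> np.ndarray:
    """Normalise to [0, 1]; degenerate (constant) input raises."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        raise ValueError("constant series: minmax range is degenerate")
    return (values - lo) / (hi - lo)


def rescale_rmm(q_px: SampledSeries, p_mm: SampledSeries) -> SampledSeries:
    """Reverse-minmax rescaling of a pixel series onto a mm reference.

    Both series must be up-positive and of equal length (resample first).
    The output's min and max equal the reference's exactly. Evaluation-only:
    it presumes the reference capture exists.
    """
    if len(q_px) == 0 or len(p_mm) == 0:
        raise ValueError("empty series")
    if len(q_px) != len(p_mm):
        raise ValueError(f"length mismatch {len(q_px)} != {len(p_mm)}; "
                         "resample the pixel series first")
    q_star = minmax(q_px.values)  # raises on degenerate pixel range
    p = p_mm.values
    lo, hi = float(np.min(p)), float(np.max(p))
    if hi == lo:
        raise ValueError("constant reference series: cannot set a mm range")
    return p_mm.with_values(q_star * (hi - lo) + lo, name=q_px.name + "_mm")


def estimate_ptm_scale(hip_px: SampledSeries, segment: JumpSegment,
                       alpha: float = 0.5, baseline_window: float = 0.33,
                       min_pixel_drop: float = 2.0) -> ScaleEstimate:
    """Fit the gravity-calibrated scale R from the free fall around one apex.

    The apex is the maximum of the (up-positive, denoised) hip series inside
    the segment. The free-fall evidence window comprises the contiguous
    samples around the apex that stay within ``alpha`` of the apex-to-baseline
    pixel displacement — by construction inside the flight phase, where the
    hip follows a parabola. A quadratic fit over that window locates the apex
    at sub-frame precision (d0 at the vertex); T is the time from the vertex
    to the last window sample and |d0 - dT| the fitted drop over it, giving
    R = 500 T^2 g / |d0 - dT|.

    Raises :class:`NotEstimableError` when there is no usable apex or the
    pixel drop is below ``min_pixel_drop`` (resolution floor).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    x = hip_px.values[segment.start_index:segment.end_index]
    if x.size < 5 or float(np.ptp(x)) == 0:
        raise NotEstimableError("flat or empty hip segment: no apex")
    k0 = int(np.argmax(x))
    n_base = max(1, int(round(baseline_window * hip_px.rate)))
    baseline = float(np.median(x[:n_base]))
    drop_total = x[k0] - baseline
    if drop_total <= 0:
        raise NotEstimableError("apex does not rise above baseline")
    floor_level = x[k0] - alpha * drop_total

    lo = k0
    while lo > 0 and x[lo - 1] >= floor_level:
        lo -= 1
    hi = k0
    while hi < x.size - 1 and x[hi + 1] >= floor_level:
        hi += 1
    idx = np.arange(lo, hi + 1)
    if idx.size < 3:
        raise NotEstimableError("fewer than 3 samples in the free-fall window")

    t = idx / hip_px.rate
    a, b, c = np.polyfit(t, x[idx], 2)
    if a >= 0:
        raise NotEstimableError("no downward curvature at the apex")
    t_vertex = -b / (2 * a)
    d0 = np.polyval([a, b, c], t_vertex)
    t_end = t[-1]
    T = t_end - t_vertex
    if T <= 0:
        raise NotEstimableError("apex vertex beyond the evidence window")
    dT = np.polyval([a, b, c], t_end)
    pixel_drop = abs(d0 - dT)
    if pixel_drop < min_pixel_drop:
        raise NotEstimableError(
            f"pixel drop {pixel_drop:.2f} px below the {min_pixel_drop} px floor")
    return ScaleEstimate(R=500.0 * T**2 * G / pixel_drop,
                         free_fall_T=float(T), pixel_drop=float(pixel_drop))


def apply_scale(q_px: SampledSeries, scale: ScaleEstimate) -> SampledSeries:
    """Convert an up-positive pixel series to millimetres: q_mm = R * q_px."""
    return q_px.with_values(scale.R * q_px.values, name=q_px.name + "_mm")


def cohort_mean_fallback(estimates: list[ScaleEstimate]) -> ScaleEstimate:
    """Mean R over the fitted estimates, used when a repetition's own scale
    is not estimable (e.g. a pose-estimation failure case)."""
    fitted = [e for e in estimates if e.source == "fitted"]
    if not fitted:
        raise ValueError("no fitted scale estimates to fall back on")
    return ScaleEstimate(R=float(np.mean([e.R for e in fitted])),
                         free_fall_T=float(np.mean([e.free_fall_T for e in fitted])),
                         pixel_drop=float(np.mean([e.pixel_drop for e in fitted])),
                         source="cohort_mean_fallback")
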