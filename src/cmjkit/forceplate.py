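"""Flight detection in vertical ground-reaction-force traces and the
flight-time jump height (the first ground truth).

A jump repetition appears on the plate as an interval of (nearly) zero
force. Candidate flight intervals are the maximal runs below 5% of the
quiet-stance force; their boundaries are then refined against the noise
band of the unloaded plate, which locates toe-off and landing more
precisely than the raw threshold crossing. Height follows from the flight
time Tf by ballistics: the centre of mass rises for Tf/2 under gravity,
so h = 100 g Tf^2 / 8 centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import SampledSeries

G = 9.81  # m/s^2


@dataclass
class FlightInterval:
    """One airborne interval: sample indices of toe-off and landing."""

    toe_off_index: int
    landing_index: int
    flight_time_Tf: float
    rep_id: int

    def __post_init__(self) -> None:
        if self.landing_index <= self.toe_off_index:
            raise ValueError("landing must come after toe-off")


def height_from_flight_time(tf: float) -> float:
    """Jump height in cm from flight time in s: h = 100 g Tf^2 / 8."""
    if tf < 0:
        raise ValueError("flight time must be non-negative")
    return 100.0 * G * tf**2 / 8.0


def detect_flight_intervals(force: SampledSeries,
                            stance_window: float = 0.5,
                            threshold_fraction: float = 0.05,
                            min_flight: float = 0.08,
                            noise_band_k: float = 5.0,
                            refine_window: float = 0.05) -> list[FlightInterval]:
    """Find airborne intervals in a vertical force trace.

    Parameters
    ----------
    force : SampledSeries
        Vertical ground-reaction force in newtons, rate >= 100 Hz.
    stance_window : float
        Leading quiet-stance duration (s) whose mean force defines the
        unloading threshold.
    threshold_fraction : float
        Candidate flight samples are those below this fraction of the
        stance mean (default 5%).
    min_flight : float
        Runs shorter than this (s) are discarded as chatter; 80 ms is
        shorter than any plausible human countermovement-jump flight.
    noise_band_k : float
        Half-width of the unloaded-plate noise band in standard deviations,
        estimated from the central 50% of each candidate run.
    refine_window : float
        How far (s) a refined boundary may move outward past the raw
        threshold crossing.

    Returns
    -------
    list of FlightInterval
        One entry per repetition, in temporal order. An empty list means
        no unloading was found (e.g. a constant bodyweight trace).
    """
    if force.rate < 100:
        raise ValueError("force rate must be >= 100 Hz for flight timing")
    f = force.values
    n_st = int(round(stance_window * force.rate))
    if n_st < 2 or n_st > f.size:
        raise ValueError("stance window does not fit the trace; cannot "
                         "estimate the stance baseline")
    baseline = float(np.mean(f[:n_st]))
    if baseline <= 0:
        raise ValueError("non-positive stance baseline; check trace units")
    thresh = threshold_fraction * baseline

    below = f < thresh
    d = np.diff(below.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if below[0]:
        starts = [0] + starts
    if below[-1]:
        stops = stops + [f.size]

    min_run = int(round(min_flight * force.rate))
    max_shift = int(round(refine_window * force.rate))
    intervals: list[FlightInterval] = []
    rep = 0
    for a, b in zip(starts, stops):
        if b - a < min_run:
            continue
        a_ref, b_ref = _refine_run(f, a, b, noise_band_k, max_shift)
        tf = (b_ref - a_ref) / force.rate
        if tf < min_flight:
            continue
        intervals.append(FlightInterval(toe_off_index=a_ref, landing_index=b_ref,
                                        flight_time_Tf=tf, rep_id=rep))
        rep += 1
    return intervals


def _refine_run(f: np.ndarray, a: int, b: int, k: float,
                max_shift: int) -> tuple[int, int]:
    """Snap run boundaries to the first/last sample inside the unloaded-plate
    noise band (mean +/- k sd of the run interior)."""
    q = (b - a) // 4
    interior = f[a + q:b - q] if b - a >= 8 else f[a:b]
    mu = float(np.mean(interior))
    sd = float(np.std(interior))
    half = k * max(sd, 1e-9)
    lo, hi = mu - half, mu + half

    inside = lambda i: lo <= f[i] <= hi  # noqa: E731

    a_ref = a
    while a_ref > max(0, a - max_shift) and inside(a_ref - 1):
        a_ref -= 1
    while a_ref < b - 1 and not inside(a_ref):
        a_ref += 1
    b_ref = b
    while b_ref < min(f.size, b + max_shift) and inside(b_ref):
        b_ref += 1
    while b_ref > a_ref + 1 and not inside(b_ref - 1):
        b_ref -= 1
    return a_ref, b_ref


def heights_from_force(force: SampledSeries, **kwargs) -> list[tuple[FlightInterval, float]]:
    """Convenience: detect flights and convert each to a height in cm."""
    return [(iv, height_from_flight_time(iv.flight_time_Tf))
            for iv in detect_flight_intervals(force, **kwargs)]
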