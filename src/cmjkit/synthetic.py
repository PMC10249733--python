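"""Synthetic countermovement-jump recordings.

One ground-truth vertical motion is generated from ballistic and quasi-static
mechanics, then rendered as the three capture modalities used in practice:

* a 1000 Hz vertical ground-reaction-force trace (force plate),
* 100 Hz hip and fifth-metatarsal trajectories in millimetres (optical
  motion capture, OMC),
* a 30 fps hip/toe keypoint trace in pixels with per-frame confidence
  (markerless motion capture, MMC), following the image convention that
  pixel y grows downward.

The flight phase is exact free fall, so the flight time, the toe apex and
the force-plate zero interval are mutually consistent: a jump of height
``h`` cm has flight time ``sqrt(8 h / (100 g))`` seconds. That internal
consistency is what makes parameter-recovery tests of the downstream
pipeline meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .series import SampledSeries

G = 9.81  # m/s^2

#: master simulation grid; divisible into 1000 Hz, 100 Hz and 30 fps exactly
GRID_RATE = 3000

FORCE_RATE = 1000
OMC_RATE = 100
MMC_RATE = 30

#: image height in px; pixel row = IMAGE_ORIGIN_PX - height_mm / R
IMAGE_ORIGIN_PX = 720.0

PHASES = ("stance", "countermovement", "propulsion", "flight", "landing")


def flight_time_for_height(height_cm: float) -> float:
    """Flight time in s implied by a jump height in cm (inverse of h = 100 g Tf^2 / 8)."""
    if height_cm < 0:
        raise ValueError("height must be non-negative")
    return float(np.sqrt(8.0 * height_cm / (100.0 * G)))


@dataclass
class JumpSpec:
    """Parameters of one simulated participant-task capture.

    Heights and the countermovement depth are in centimetres; noise standard
    deviations are in the native units of each modality (N, mm, px).
    ``true_height = 0`` is the no-lift-off limit: the motion then contains
    no flight or landing phase.
    """

    true_height: float = 20.0          # cm
    body_mass: float = 75.0            # kg
    n_reps: int = 3
    task: Literal["bilateral", "unilateral"] = "bilateral"
    countermovement_depth: float = 30.0  # cm
    stance_duration: float = 1.0       # s of quiet stance before each rep
    rest_between_reps: float = 1.0     # s
    scale_R_true: float = 3.43         # mm per px
    pixel_noise_sd: float = 1.0        # px
    marker_noise_sd: float = 0.5       # mm
    force_noise_sd: float = 2.0        # N
    spike_prob: float = 0.0            # per MMC frame
    failure_mode: Literal["none", "limb_swap", "uncharacteristic"] = "none"
    rep_height_jitter_sd: float = 0.0  # cm; rep-to-rep variation around true_height
    seed: int = 0

    # secondary shape parameters (not usually varied)
    countermovement_duration: float = 0.45  # s
    propulsion_duration: float = 0.30       # s
    landing_duration: float = 0.40          # s
    hip_baseline_m: float = 0.95
    com_baseline_m: float = 1.00
    toe_baseline_m: float = 0.03

    def validate(self) -> None:
        if self.true_height < 0:
            raise ValueError("true_height must be >= 0 cm")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.countermovement_depth < 0:
            raise ValueError("countermovement_depth must be >= 0")
        if self.scale_R_true <= 0:
            raise ValueError("scale_R_true must be positive")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError("spike_prob must be in [0, 1]")
        for name in ("pixel_noise_sd", "marker_noise_sd", "force_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def flight_time(self) -> float:
        return flight_time_for_height(self.true_height)


@dataclass
class GroundTruthMotion:
    """Noise-free motion on the master grid, with per-sample phase labels."""

    time_grid: np.ndarray       # s
    com_height: np.ndarray      # m
    toe_height: np.ndarray      # m
    hip_height: np.ndarray      # m
    vertical_force: np.ndarray  # N, exactly 0 during flight
    phase_labels: np.ndarray    # str per sample, one of PHASES
    spec: JumpSpec
    rep_heights_cm: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def rate(self) -> float:
        return GRID_RATE

    def apex_times(self) -> np.ndarray:
        """Times of the hip apex of each repetition (empty if no flight)."""
        apexes = []
        in_flight = self.phase_labels == "flight"
        edges = np.flatnonzero(np.diff(in_flight.astype(int)))
        starts = edges[::2] + 1
        stops = edges[1::2] + 1
        for a, b in zip(starts, stops):
            k = a + int(np.argmax(self.hip_height[a:b]))
            apexes.append(self.time_grid[k])
        return np.asarray(apexes)


def _hermite(p0, v0, p1, v1, T, s):
    """Cubic Hermite interpolant on s in [0, 1] over a phase of duration T."""
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    h11 = s**3 - s**2
    return h00 * p0 + h10 * T * v0 + h01 * p1 + h11 * T * v1


def _hermite_accel(p0, v0, p1, v1, T, s):
    return ((12 * s - 6) * (p0 - p1) + T * v0 * (6 * s - 4)
            + T * v1 * (6 * s - 2)) / T**2


def simulate_motion(spec: JumpSpec) -> GroundTruthMotion:
    """Build the piecewise ground-truth motion for ``spec``.

    Each repetition is quiet stance, a raised-cosine countermovement dip of
    the configured depth, a cubic propulsion segment ending at the ballistic
    take-off velocity, exact free-fall flight whose apex exceeds the stance
    baseline by ``true_height``, a cubic landing absorption, and rest. The
    force trace is ``m (g + a_com)`` in the grounded phases, exactly zero in
    flight, and a brief impulse peak absorbing the landing momentum.
    """
    spec.validate()
    depth = spec.countermovement_depth / 100.0
    m = spec.body_mass

    # per-rep apex heights (m); jitter lets repetitions vary as real ones do
    heights = np.full(spec.n_reps, spec.true_height / 100.0)
    if spec.rep_height_jitter_sd > 0:
        jit = _rng(spec, 0).normal(0.0, spec.rep_height_jitter_sd / 100.0, spec.n_reps)
        heights = np.clip(heights + jit, 0.0, None)
    if spec.true_height > 0:
        # the nominal height is hit exactly by at least one repetition
        heights[0] = spec.true_height / 100.0

    # flat phase plan across all repetitions: (name, duration, takeoff speed)
    plan: list[tuple[str, float, float]] = []
    for h_m in heights:
        tf = float(np.sqrt(2.0 * h_m / G) * 2.0) if h_m > 0 else 0.0
        v0 = G * tf / 2.0
        plan.append(("stance", spec.stance_duration, v0))
        if depth > 0 or h_m > 0:
            plan.append(("countermovement", spec.countermovement_duration, v0))
            plan.append(("propulsion", spec.propulsion_duration, v0))
        if h_m > 0:
            plan.append(("flight", tf, v0))
            plan.append(("landing", spec.landing_duration, v0))
        plan.append(("stance", spec.rest_between_reps, v0))

    total = sum(d for _, d, _ in plan)
    n = int(round(total * GRID_RATE))
    t = np.arange(n) / GRID_RATE

    z = np.zeros(n)       # COM displacement from stance baseline, m
    toe = np.zeros(n)     # toe displacement, m
    force = np.full(n, m * G)
    labels = np.full(n, "stance", dtype="<U15")

    tcm, tp, tl = (spec.countermovement_duration, spec.propulsion_duration,
                   spec.landing_duration)
    pulse_tau = 0.04  # landing impulse time constant, s

    start = 0.0
    for name, dur, v0 in plan:
        if dur <= 0:
            start += dur
            continue
        i0 = int(np.ceil(start * GRID_RATE - 1e-9))
        i1 = min(int(np.ceil((start + dur) * GRID_RATE - 1e-9)), n)
        tau = t[i0:i1] - start
        s = tau / dur
        if name == "countermovement":
            z[i0:i1] = -(depth / 2.0) * (1 - np.cos(np.pi * s))
            a = -(depth / 2.0) * (np.pi / tcm) ** 2 * np.cos(np.pi * s)
            force[i0:i1] = m * (G + a)
        elif name == "propulsion":
            z[i0:i1] = _hermite(-depth, 0.0, 0.0, v0, tp, s)
            a = _hermite_accel(-depth, 0.0, 0.0, v0, tp, s)
            force[i0:i1] = m * (G + a)
        elif name == "flight":
            z[i0:i1] = v0 * tau - 0.5 * G * tau**2
            toe[i0:i1] = z[i0:i1]
            force[i0:i1] = 0.0
        elif name == "landing":
            z[i0:i1] = _hermite(0.0, -v0, 0.0, 0.0, tl, s)
            force[i0:i1] = m * G + (m * v0 / (np.e * pulse_tau)) * \
                (tau / pulse_tau) * np.exp(1 - tau / pulse_tau)
        if name != "stance":
            labels[i0:i1] = name
        start += dur

    np.clip(force, 0.0, None, out=force)
    return GroundTruthMotion(
        time_grid=t,
        com_height=spec.com_baseline_m + z,
        toe_height=spec.toe_baseline_m + toe,
        hip_height=spec.hip_baseline_m + z,
        vertical_force=force,
        phase_labels=labels,
        spec=spec,
        rep_heights_cm=heights * 100.0,
    )


def _subsample(x: np.ndarray, step: int) -> np.ndarray:
    return x[::step].copy()


def _rng(spec: JumpSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, stream])


def render_force_plate(motion: GroundTruthMotion, spec: JumpSpec) -> SampledSeries:
    """1000 Hz force trace with additive Gaussian sensor noise (also on the
    unloaded flight segment, as on a real plate)."""
    step = GRID_RATE // FORCE_RATE
    f = _subsample(motion.vertical_force, step)
    if spec.force_noise_sd > 0:
        f = f + _rng(spec, 1).normal(0.0, spec.force_noise_sd, f.size)
    return SampledSeries(f, FORCE_RATE, name="force_N")


@dataclass
class OmcRecording:
    """Marker-based capture: vertical hip and fifth-metatarsal traces, mm, up-positive."""
    hip: SampledSeries
    toe: SampledSeries


@dataclass
class MmcRecording:
    """Keypoint capture: vertical hip and toe traces in image pixels
    (y grows downward) plus per-frame confidence in [0, 1]."""
    hip: SampledSeries
    toe: SampledSeries
    confidence: SampledSeries


def render_omc(motion: GroundTruthMotion, spec: JumpSpec,
               dropout: bool = False, dropout_duration: float = 0.08) -> OmcRecording:
    """100 Hz OMC rendering in millimetres.

    ``dropout=True`` zeroes one brief run of samples per trace, mimicking
    marker occlusion by hands or clothing (coordinates drop to zero).
    """
    step = GRID_RATE // OMC_RATE
    hip = _subsample(motion.hip_height, step) * 1000.0
    toe = _subsample(motion.toe_height, step) * 1000.0
    rng = _rng(spec, 2)
    if spec.marker_noise_sd > 0:
        hip = hip + rng.normal(0.0, spec.marker_noise_sd, hip.size)
        toe = toe + rng.normal(0.0, spec.marker_noise_sd, toe.size)
    if dropout:
        k = max(1, int(round(dropout_duration * OMC_RATE)))
        for arr in (hip, toe):
            start = int(rng.integers(0, max(1, arr.size - k)))
            arr[start:start + k] = 0.0
    return OmcRecording(hip=SampledSeries(hip, OMC_RATE, name="hip_mm"),
                        toe=SampledSeries(toe, OMC_RATE, name="toe_mm"))


def _uncharacteristic_px(n: int, rate: float, base: float, amp: float,
                         rng: np.random.Generator) -> np.ndarray:
    """A non-jump oscillation with several comparable local maxima, standing in
    for pose-estimation failure on unilateral side views."""
    t = np.arange(n) / rate
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    x = 0.6 * np.sin(2 * np.pi * 0.8 * t + ph1) + 0.45 * np.sin(2 * np.pi * 1.9 * t + ph2)
    return base - amp * x


def render_mmc(motion: GroundTruthMotion, spec: JumpSpec) -> MmcRecording:
    """30 fps keypoint rendering in image pixels.

    pixel = IMAGE_ORIGIN_PX - height_mm / R: the image y axis points down.
    Isolated spike frames (probability ``spike_prob`` per frame) are displaced
    by at least 20 noise standard deviations and get low confidence, mimicking
    left/right limb swaps in pose estimation. ``failure_mode="uncharacteristic"``
    replaces the hip trajectory with a non-jump oscillation;
    ``failure_mode="limb_swap"`` exchanges hip and toe on spike frames.
    """
    step = GRID_RATE // MMC_RATE
    hip_px = IMAGE_ORIGIN_PX - _subsample(motion.hip_height, step) * 1000.0 / spec.scale_R_true
    toe_px = IMAGE_ORIGIN_PX - _subsample(motion.toe_height, step) * 1000.0 / spec.scale_R_true
    n = hip_px.size
    rng = _rng(spec, 3)

    if spec.failure_mode == "uncharacteristic":
        amp = max(spec.true_height, 10.0) * 10.0 / spec.scale_R_true / 2.0
        hip_px = _uncharacteristic_px(n, MMC_RATE, float(np.median(hip_px)), amp, rng)
        toe_px = _uncharacteristic_px(n, MMC_RATE, float(np.median(toe_px)), amp * 0.8, rng)

    conf = np.clip(0.88 + 0.05 * rng.standard_normal(n), 0.0, 1.0)
    if spec.pixel_noise_sd > 0:
        hip_px = hip_px + rng.normal(0.0, spec.pixel_noise_sd, n)
        toe_px = toe_px + rng.normal(0.0, spec.pixel_noise_sd, n)

    if spec.spike_prob > 0:
        spikes = rng.random(n) < spec.spike_prob
        # keep spikes isolated: drop a spike immediately following another
        idx = np.flatnonzero(spikes)
        keep = np.ones(idx.size, dtype=bool)
        keep[1:] = np.diff(idx) > 1
        idx = idx[keep]
        scale = max(spec.pixel_noise_sd, 1.0)
        if spec.failure_mode == "limb_swap":
            hip_px[idx], toe_px[idx] = toe_px[idx].copy(), hip_px[idx].copy()
        else:
            signs = rng.choice([-1.0, 1.0], idx.size)
            mags = (20.0 + rng.exponential(5.0, idx.size)) * scale
            hip_px[idx] += signs * mags
            toe_px[idx] += signs * mags * rng.uniform(0.5, 1.0, idx.size)
        conf[idx] = np.minimum(conf[idx], rng.uniform(0.05, 0.25, idx.size))

    return MmcRecording(hip=SampledSeries(hip_px, MMC_RATE, name="hip_px"),
                        toe=SampledSeries(toe_px, MMC_RATE, name="toe_px"),
                        confidence=SampledSeries(conf, MMC_RATE, name="confidence"))


@dataclass
class JumpRecording:
    """One participant-task capture across the three synchronized modalities."""
    participant: str
    spec: JumpSpec
    motion: GroundTruthMotion
    force: SampledSeries
    omc: OmcRecording
    mmc: MmcRecording


def simulate_recording(spec: JumpSpec, participant: str = "P01",
                       dropout: bool = False) -> JumpRecording:
    """Simulate one capture and render all three modalities."""
    motion = simulate_motion(spec)
    return JumpRecording(
        participant=participant,
        spec=spec,
        motion=motion,
        force=render_force_plate(motion, spec),
        omc=render_omc(motion, spec, dropout=dropout),
        mmc=render_mmc(motion, spec),
    )


def simulate_cohort(n_participants: int = 16, n_reps: int = 3,
                    task: Literal["bilateral", "unilateral"] = "bilateral",
                    seed: int = 0, height_mean: float | None = None,
                    height_sd: float | None = None,
                    **overrides) -> list[JumpRecording]:
    """Simulate a cohort of participants with realistic height spread.

    Jump-height population defaults match typical healthy-adult values:
    bilateral 21.3 +/- 8.8 cm, unilateral 11.5 +/- 4.2 cm, clipped to a
    plausible range. ``overrides`` are forwarded to every :class:`JumpSpec`.
    """
    rng = np.random.default_rng(seed)
    if height_mean is None:
        height_mean = 21.3 if task == "bilateral" else 11.5
    if height_sd is None:
        height_sd = 8.8 if task == "bilateral" else 4.2
    lo, hi = (8.0, 55.0) if task == "bilateral" else (4.0, 30.0)
    recordings = []
    for i in range(n_participants):
        h = float(np.clip(rng.normal(height_mean, height_sd), lo, hi))
        mass = float(np.clip(rng.normal(75.0, 10.0), 50.0, 110.0))
        spec = JumpSpec(true_height=h, body_mass=mass, n_reps=n_reps, task=task,
                        seed=int(rng.integers(0, 2**31 - 1)), **overrides)
        recordings.append(simulate_recording(spec, participant=f"P{i + 1:02d}"))
    return recordings
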