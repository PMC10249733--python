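# Methods

This note documents the models, algorithms and numerical choices behind
`cmjkit`, and what the synthetic validation does and does not show about
real recordings.

## The measurement problem

A countermovement jump (CMJ) is a maximal vertical jump preceded by a rapid
dip of the centre of mass (COM). Three instruments can measure its height:

* a force plate, via the flight time $T_f$ during which vertical ground
  reaction force is zero: by symmetry of ballistic flight the COM rises for
  $T_f/2$, so $h = \frac{1}{2} g (T_f/2)^2 = 100\,g\,T_f^2/8$ cm;
* marker-based optical motion capture (OMC), via the maximum vertical
  displacement of the fifth-metatarsal marker in millimetres;
* markerless motion capture (MMC), via the same toe displacement read from
  pose-estimation keypoints — but in pixels, with per-frame confidence,
  occasional single-frame spikes (limb swaps), and no metric scale.

The package's job is to make the third estimate metric and trustworthy, and
to quantify how far it is from the first two.

## Synthetic ground truth

`synthetic.simulate_motion` builds one vertical motion on a 3000 Hz master
grid (divisible exactly into 1000 Hz, 100 Hz and 30 fps) from a phase plan:

| phase | duration | kinematics | force |
|---|---|---|---|
| stance | 1.0 s | constant | $mg$ |
| countermovement | 0.45 s | raised-cosine dip of depth $D$ | $m(g+\ddot z)$ |
| propulsion | 0.30 s | cubic Hermite from $(-D, 0)$ to $(0, v_0)$ | $m(g+\ddot z)$ |
| flight | $T_f$ | $v_0\tau - \tfrac12 g\tau^2$, $v_0 = gT_f/2$ | exactly 0 |
| landing | 0.40 s | cubic Hermite back to baseline | $mg$ + impulse pulse |
| rest | 1.0 s | constant | $mg$ |

The raised cosine and Hermite segments are twice differentiable inside each
phase, so the Savitzky–Golay tests see no spurious overshoot. Flight is
exact free fall: the toe apex, the force-plate zero interval and $T_f$ are
mutually consistent by construction, which is what makes cross-modality
agreement on synthetic data a meaningful end-to-end check. The landing
force is a parametric overdamped pulse absorbing the landing momentum
rather than the second derivative of the landing kinematics; only the
zero-force interval matters to any measured quantity. Per-repetition
heights can be jittered (`rep_height_jitter_sd`) for test–retest studies.

Renderers subsample the master grid and add modality noise:

* force plate, 1000 Hz: additive Gaussian noise (default sd 2 N), also on
  the unloaded segment;
* OMC, 100 Hz, mm, up-positive: Gaussian marker noise (default sd 0.5 mm),
  optional zero-valued dropout runs mimicking occlusion;
* MMC, 30 fps: `pixel = 720 − mm / R`, i.e. image y grows downward, so the
  pipeline must handle the sign inversion explicitly; Gaussian pixel noise
  (default sd 1 px), isolated spike frames displaced by ≥ 20 noise sd with
  lowered confidence, and two failure modes — `limb_swap` (hip/toe exchanged
  on spike frames) and `uncharacteristic` (a multi-peaked oscillation
  replacing the jump, as pose estimation produces on difficult views).

Cohort defaults follow healthy-adult populations: bilateral jump heights
21.3 ± 8.8 cm, unilateral 11.5 ± 4.2 cm, body mass 75 ± 10 kg, camera scale
3.43 mm/px. Noise is white Gaussian plus sparse spikes; the spectral
content of real pose-estimation noise is not well characterised, so this is
an explicit modelling assumption. No horizontal drift toward or away from
the camera is simulated, and no photorealistic video or pose-estimation
emulation is attempted — passing tests show the post-processing chain
recovers known parameters under these noise models, not that any particular
pose estimator is accurate.

## Pipeline stages and numerical choices

**Flight detection.** Candidate flight regions are maximal runs below 5% of
the quiet-stance mean force (leading 0.5 s window; the mean rather than the
peak is used, configurable). Boundaries are refined to the first/last
sample inside the unloaded-plate noise band, mean ± 5 sd estimated from the
central 50% of the run, moving at most 50 ms past the raw crossing. Runs
shorter than 80 ms — below any plausible human CMJ flight — are discarded
as chatter. With 2 N noise on a 700 N bodyweight this locates $T_f$ to
about a millisecond (≈ 0.05 cm at $T_f = 0.4$ s).

**Spike removal.** First differences are z-scored globally; a frame is a
spike when both its incoming and outgoing differences exceed the threshold
(default 3.0) *with opposite signs*. The sign condition matters: genuine
motion (flight) produces sustained same-sign difference outliers on traces
that are otherwise flat, and a plain magnitude rule would interpolate the
jump away. Flagged frames are linearly interpolated; passes repeat until
clean (large spikes inflate the sd and mask smaller ones). A series still
spiky after 10 passes, or with more than half its frames flagged, raises
`UnusableSeriesError`.

**Smoothing.** Savitzky–Golay, order 2, window 21 samples, edge windows
fitted on truncated polynomials. Order 2 passes parabolas — hence flight
apexes — through unchanged whenever the window sits inside the flight
phase. For this to hold at every modality the filter must have the same
*time* support everywhere: the pipeline therefore Fourier-upsamples the
30 fps keypoint series onto the 100 Hz analysis rate (after spike removal,
before smoothing), where the 21-sample window spans 0.21 s. Applied
directly at 30 fps the same window spans 0.7 s — wider than a whole flight —
and flattens the apex by several centimetres.

**Segmentation.** Peaks of the denoised, up-positive hip trace with
prominence ≥ 0.5 × (global max − global median) and separation ≥ 2·window
(window 1.5 s to either side of the peak, both tasks). The max−median
scale, rather than the full range, is deliberate: the range is dominated by
the countermovement dip, and the final repetition's prominence is bounded
by its shallow landing dip rather than by the jump amplitude, which made
small jumps lose their last repetition. Edge-clipped windows are flagged.

**QC.** A segment is `uncharacteristic` when ≥ 2 local maxima exceed 70% of
the segment range (prominence ≥ 15% of range) — the signature of
pose-estimation failure rather than a jump — and `low_confidence` when the
median keypoint confidence falls below 0.3. Flagged repetitions are
measured and reported with their flags but excluded from summary means
(marked `F`) and from agreement statistics, and every exclusion traces to a
QC log line.

**Reverse minmax.** Exact by construction: the rescaled series' min/max
equal the reference's. It is invariant to any positive affine map of the
pixel input and is exposed as evaluation-only, since it presupposes the OMC
reference it is judged against.

**Pixel-to-metric.** The free-fall evidence window comprises the contiguous
samples around the segment apex within α = 0.5 of the apex-to-baseline
pixel displacement (baseline: median of the segment's leading 0.33 s). At
α = 0.5 the window stays inside the flight phase on both sides of the apex,
where the hip is a single parabola. A quadratic fit over the window locates
the apex at sub-frame precision — essential at 30 fps, where the apex frame
can miss the true apex by 17 ms and a two-point reading of the drop would
be biased by ~20% — and supplies $d_0$ at the vertex, $d_T$ at the window
end, $T$ between them, and $\mathcal{R} = 500\,T^2 g/|d_0-d_T|$. Drops
below 2 px are declared not estimable; such repetitions (and QC-flagged
ones) fall back to the cohort-mean scale, averaged per participant before
pooling, and their results carry a `fallback_scale` flag. Noise-free the
scale is recovered within ~1%; at 1 px noise, within a few percent
(median).

**Height.** Baseline = median toe height over the leading 0.5 s of the
segment (quiet stance, before the countermovement); height = (in-segment
maximum − baseline)/10 cm, reported to 2 decimals in the summary table.
Zero-valued samples in the baseline window (marker occlusion) raise rather
than silently shifting the reference.

**Agreement.** ICC(2,1) is computed from the two-way ANOVA mean squares,
$(MS_R - MS_E)/(MS_R + (k-1)MS_E + \frac{k}{n}(MS_C - MS_E))$, with listwise
deletion; the test suite checks it against pingouin's independent
implementation to 1e-10. Test–retest reliability applies the same estimator
with repetitions as raters. Bland–Altman uses the sample sd (n−1) and
orientation candidate − truth. All repetitions from all participants are
pooled as individual measurements; this ignores within-participant
clustering, a known caveat of the pooled design that the package reproduces
deliberately.

## Problem sizes

The validation suite and the acceptance script use cohorts of 16
participants × 3 repetitions (48 jumps), 20-seed replications for
stochastic claims, and a 10–45 cm height grid — comfortably spanning the
physiological range while keeping a full run under a minute.

## Known limitations

* The generator's keypoint noise is white; real pose-estimation error is
  temporally correlated with lighting and background, so real-world scale
  errors will be somewhat larger than the synthetic ones.
* PTM assumes a stationary camera and no movement toward or away from it
  during a task; such movement changes the mm/px scale mid-trial and is not
  modelled.
* Unilateral captures in side view are exactly where pose estimation fails
  most; the `uncharacteristic` QC rule catches gross failures but subtle
  ones pass through.
* The flight-time height assumes equal take-off and landing COM height; the
  toe-displacement height assumes the metatarsal keypoint tracks the shoe
  tip consistently. Both are standard, both are approximations.
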