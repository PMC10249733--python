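"""End-to-end orchestration: denoise, segment, rescale, measure, compare.

A session is a collection of participant-task recordings, each with any
subset of the three modalities. Per recording the pipeline

1. measures force-plate heights from flight times,
2. denoises and segments the marker (OMC) series and measures toe heights,
3. denoises, segments and QC-flags the keypoint (MMC) series, fits the
   gravity-calibrated scale per repetition, and measures toe heights via
   both reverse-minmax (needs OMC) and pixel-to-metric rescaling.

Repetitions whose own scale is not estimable (or that failed QC) fall back
to the cohort-mean scale, pooled per participant first. Flagged repetitions
are reported but excluded from the agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forceplate, preprocess, rescale
from .agreement import AgreementReport, bland_altman
from .height import JumpHeightResult, summarize_per_participant, toe_displacement_height
from .io import SessionConfig
from .preprocess import JumpSegment
from .series import SampledSeries
from .synthetic import JumpRecording, MmcRecording, OmcRecording

#: agreement pairs reported when both methods are present (candidate, truth)
AGREEMENT_PAIRS = [
    ("MMC_RMM", "OMC"), ("MMC_PTM", "OMC"),
    ("MMC_RMM", "FP"), ("MMC_PTM", "FP"),
    ("FP", "TRUTH"), ("OMC", "TRUTH"), ("MMC_PTM", "TRUTH"), ("MMC_RMM", "TRUTH"),
]


class PipelineError(RuntimeError):
    """Raised when a session yields no usable repetitions at all."""


@dataclass
class SessionRecording:
    """One participant-task capture; any modality may be absent."""

    participant: str
    task: str = "bilateral"
    force: SampledSeries | None = None
    omc: OmcRecording | None = None
    mmc: MmcRecording | None = None
    true_heights_cm: np.ndarray | None = None  # synthetic ground truth, per rep

    @classmethod
    def from_simulation(cls, rec: JumpRecording) -> "SessionRecording":
        return cls(participant=rec.participant, task=rec.spec.task,
                   force=rec.force, omc=rec.omc, mmc=rec.mmc,
                   true_heights_cm=rec.motion.rep_heights_cm)


@dataclass
class SessionReport:
    """Everything a session produces: per-rep heights, the summary table,
    agreement statistics, scale estimates and the QC log."""

    heights: list[JumpHeightResult]
    table: pd.DataFrame
    agreement: dict[str, AgreementReport]
    scales: list[dict]
    qc_log: list[str]

    def heights_frame(self) -> pd.DataFrame:
        rows = [{"participant": r.participant, "task": r.task, "rep_id": r.rep_id,
                 "method": r.method, "height_cm": r.height_cm,
                 "usable": r.usable, "qc_flags": ",".join(sorted(r.qc_flags))}
                for r in self.heights]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "agreement": {k: v.to_dict() for k, v in self.agreement.items()},
            "scales": self.scales,
            "qc_log": self.qc_log,
            "n_heights": len(self.heights),
        }


def _up_positive(series: SampledSeries) -> SampledSeries:
    """Image rows grow downward; flip once so everything downstream is
    up-positive. The offset is irrelevant: all measures use displacements."""
    return series.with_values(-series.values)


@dataclass
class _PendingPTM:
    toe_up: SampledSeries
    segment: JumpSegment
    participant: str
    task: str


def _matched(*segment_lists):
    """Zip per-modality segment lists by repetition order."""
    return zip(*segment_lists)


def _process_force(rec: SessionRecording, cfg: SessionConfig,
                   results: list, log: list) -> None:
    try:
        intervals = forceplate.detect_flight_intervals(
            rec.force, stance_window=cfg.stance_window, min_flight=cfg.min_flight)
    except ValueError as e:
        log.append(f"{rec.participant}/{rec.task}/FP: {e}")
        return
    for iv in intervals:
        results.append(JumpHeightResult(
            rep_id=iv.rep_id, method="FP",
            height_cm=forceplate.height_from_flight_time(iv.flight_time_Tf),
            participant=rec.participant, task=rec.task))


def _segment_windows(hip: SampledSeries, cfg: SessionConfig) -> list[JumpSegment]:
    return preprocess.segment_repetitions(
        hip, window_t=cfg.window_t, prominence_fraction=cfg.prominence_fraction)


def _relative_segment(seg: JumpSegment, values: np.ndarray) -> JumpSegment:
    """A segment covering one extracted window, peak at the window argmax."""
    return JumpSegment(peak_index=int(np.argmax(values)), start_index=0,
                       end_index=len(values), rep_id=seg.rep_id,
                       qc_flags=set(seg.qc_flags))


def process_recording(rec: SessionRecording, cfg: SessionConfig,
                      results: list, scales: list, pending: list,
                      log: list) -> None:
    """Process one recording, appending height results and scale estimates.

    PTM heights that need the cohort-mean fallback scale are deferred to
    ``pending`` and resolved at session level.
    """
    if rec.true_heights_cm is not None:
        for i, h in enumerate(np.atleast_1d(rec.true_heights_cm)):
            results.append(JumpHeightResult(rep_id=i, method="TRUTH",
                                            height_cm=float(h),
                                            participant=rec.participant,
                                            task=rec.task))
    if rec.force is not None:
        _process_force(rec, cfg, results, log)

    omc_segments: list[JumpSegment] = []
    omc_toe = None
    if rec.omc is not None:
        try:
            omc_hip = preprocess.denoise(rec.omc.hip, cfg.z_thresh, cfg.savgol_window)
            omc_toe = preprocess.denoise(rec.omc.toe, cfg.z_thresh, cfg.savgol_window)
            omc_segments = _segment_windows(omc_hip, cfg)
        except ValueError as e:
            log.append(f"{rec.participant}/{rec.task}/OMC: {e}")
        for seg in omc_segments:
            try:
                r = toe_displacement_height(omc_toe, seg, cfg.baseline_window, "OMC")
                r.participant, r.task = rec.participant, rec.task
                results.append(r)
            except ValueError as e:
                log.append(f"{rec.participant}/{rec.task}/OMC rep {seg.rep_id}: {e}")

    if rec.mmc is None:
        return
    # Keypoint series: spike removal at the native frame rate, Fourier
    # upsampling onto the common analysis rate, then Savitzky-Golay. Smoothing
    # after upsampling keeps the filter's time support (0.21 s at 100 Hz)
    # identical across modalities; 21 frames at 30 fps would span 0.7 s and
    # flatten the flight apex.
    analysis_rate = rec.omc.hip.rate if rec.omc is not None else 100.0
    try:
        mmc_hip = preprocess.remove_spikes_zscore(_up_positive(rec.mmc.hip),
                                                  cfg.z_thresh)
        mmc_toe = preprocess.remove_spikes_zscore(_up_positive(rec.mmc.toe),
                                                  cfg.z_thresh)
        if analysis_rate > rec.mmc.hip.rate:
            mmc_hip = preprocess.resample_to_rate(mmc_hip, analysis_rate)
            mmc_toe = preprocess.resample_to_rate(mmc_toe, analysis_rate)
        mmc_hip = preprocess.smooth_savgol(mmc_hip, cfg.savgol_window)
        mmc_toe = preprocess.smooth_savgol(mmc_toe, cfg.savgol_window)
    except ValueError as e:
        log.append(f"{rec.participant}/{rec.task}/MMC: {e}")
        return
    confidence = SampledSeries(
        np.interp(mmc_hip.times, rec.mmc.confidence.times,
                  rec.mmc.confidence.values),
        mmc_hip.rate, name="confidence")
    mmc_segments = _segment_windows(mmc_hip, cfg)
    for seg in mmc_segments:
        flags = preprocess.flag_uncharacteristic(
            seg, mmc_hip, confidence,
            confidence_threshold=cfg.confidence_threshold)
        if flags:
            log.append(f"{rec.participant}/{rec.task}/MMC rep {seg.rep_id}: "
                       f"flagged {sorted(flags)}")

    # pixel-to-metric: per-repetition scale where estimable
    for seg in mmc_segments:
        scale = None
        if seg.usable:
            try:
                scale = rescale.estimate_ptm_scale(mmc_hip, seg, alpha=cfg.alpha)
                scales.append({"participant": rec.participant, "task": rec.task,
                               "rep_id": seg.rep_id, **scale.to_dict()})
            except rescale.NotEstimableError as e:
                log.append(f"{rec.participant}/{rec.task}/PTM rep {seg.rep_id}: {e}")
        if scale is None:
            pending.append(_PendingPTM(mmc_toe, seg, rec.participant, rec.task))
            continue
        try:
            toe_mm = rescale.apply_scale(mmc_toe, scale)
            r = toe_displacement_height(toe_mm, seg, cfg.baseline_window, "MMC_PTM")
            r.participant, r.task = rec.participant, rec.task
            results.append(r)
        except ValueError as e:
            log.append(f"{rec.participant}/{rec.task}/PTM rep {seg.rep_id}: {e}")

    # reverse minmax: evaluation-only, needs the OMC reference
    if omc_toe is not None and omc_segments:
        for oseg, mseg in _matched(omc_segments, mmc_segments):
            try:
                p = omc_toe.slice(oseg.start_index, oseg.end_index)
                q = mmc_toe.slice(mseg.start_index, mseg.end_index)
                if len(q) > len(p):  # both on the analysis rate; trim the tail
                    q = q.slice(0, len(p))
                q_up = preprocess.resample_to_length(q, len(p))
                q_mm = rescale.rescale_rmm(q_up, p)
                seg_rel = _relative_segment(oseg, q_mm.values)
                seg_rel.qc_flags |= mseg.qc_flags
                r = toe_displacement_height(q_mm, seg_rel, cfg.baseline_window,
                                            "MMC_RMM")
                r.participant, r.task = rec.participant, rec.task
                results.append(r)
            except ValueError as e:
                log.append(f"{rec.participant}/{rec.task}/RMM rep "
                           f"{oseg.rep_id}: {e}")


def _fallback_scale(scales: list[dict]) -> rescale.ScaleEstimate | None:
    """Cohort-mean scale: per-repetition R averaged per participant first,
    then across participants."""
    if not scales:
        return None
    df = pd.DataFrame(scales)
    per_participant = df.groupby("participant")["R_mm_per_px"].mean()
    return rescale.cohort_mean_fallback([
        rescale.ScaleEstimate(R=float(r), free_fall_T=float("nan"),
                              pixel_drop=float("nan"))
        for r in per_participant])


def _pair_table(results: list[JumpHeightResult]) -> pd.DataFrame:
    rows = [{"participant": r.participant, "task": r.task, "rep_id": r.rep_id,
             "method": r.method, "height_cm": r.height_cm, "usable": r.usable}
            for r in results]
    df = pd.DataFrame(rows)
    df = df[df["usable"]]
    if df.empty:
        return df
    return df.pivot_table(index=["participant", "task", "rep_id"],
                          columns="method", values="height_cm")


def run_session(recordings: list[SessionRecording],
                cfg: SessionConfig | None = None) -> SessionReport:
    """Run the full pipeline over a session and compute agreement statistics.

    Raises :class:`PipelineError` if no repetition of any recording could be
    measured (individual failures are collected in the QC log instead).
    """
    cfg = cfg or SessionConfig()
    cfg.validate()
    results: list[JumpHeightResult] = []
    scales: list[dict] = []
    pending: list[_PendingPTM] = []
    log: list[str] = []

    for rec in recordings:
        process_recording(rec, cfg, results, scales, pending, log)

    if pending and cfg.scale_fallback == "cohort_mean":
        fb = _fallback_scale(scales)
        if fb is None:
            log.append("PTM fallback requested but no fitted scale in session")
        else:
            for job in pending:
                try:
                    toe_mm = rescale.apply_scale(job.toe_up, fb)
                    r = toe_displacement_height(toe_mm, job.segment,
                                                cfg.baseline_window, "MMC_PTM")
                    r.participant, r.task = job.participant, job.task
                    r.qc_flags.add("fallback_scale")
                    results.append(r)
                except ValueError as e:
                    log.append(f"{job.participant}/{job.task}/PTM rep "
                               f"{job.segment.rep_id}: fallback failed: {e}")

    measured = [r for r in results if r.method != "TRUTH"]
    if not measured:
        raise PipelineError("no repetition could be measured; see QC log:\n"
                            + "\n".join(log))

    table = summarize_per_participant(results)
    pairs = _pair_table(results)
    agreement: dict[str, AgreementReport] = {}
    for cand, truth in AGREEMENT_PAIRS:
        if isinstance(pairs, pd.DataFrame) and not pairs.empty and \
                cand in pairs.columns and truth in pairs.columns:
            sub = pairs[[cand, truth]].dropna()
            if len(sub) >= 2:
                agreement[f"{cand}_vs_{truth}"] = bland_altman(
                    sub[cand].to_numpy(), sub[truth].to_numpy())
    return SessionReport(heights=results, table=table, agreement=agreement,
                         scales=scales, qc_log=log)
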