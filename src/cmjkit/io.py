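"""Readers and writers for the three capture formats, plus session
configuration.

Formats (all plain text, rates declared in the file, never inferred):

* force CSV — columns ``time_s, force_N``;
* marker CSV — ``time_s`` plus one mm column per marker channel
  (``hip_z_mm``, ``toe_z_mm``);
* keypoint JSON — a consolidated OpenPose-style document:
  ``{"fps": 30, "frames": [{"people": [{"pose_keypoints_2d": [x, y, c] * 25}]}]}``
  with the 25-keypoint body layout (mid-hip is joint 8, the small toe of
  the right foot joint 23).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import SampledSeries
from .synthetic import MmcRecording, OmcRecording

N_KEYPOINTS = 25
MIDHIP = 8
RSMALLTOE = 23


class KeypointParseError(ValueError):
    """Malformed keypoint JSON; carries the offending frame index."""

    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        super().__init__(message if frame is None
                         else f"frame {frame}: {message}")


# ---------------------------------------------------------------- force CSV

def write_force_csv(path: str | Path, force: SampledSeries) -> None:
    pd.DataFrame({"time_s": force.times, "force_N": force.values}).to_csv(
        path, index=False)


def read_force_csv(path: str | Path, rate: float | None = None) -> SampledSeries:
    """Read a vertical force trace. The rate comes from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    for col in ("time_s", "force_N"):
        if col not in df.columns:
            raise ValueError(f"force CSV must have a '{col}' column")
    if rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("non-uniform time column; pass rate explicitly")
        rate = 1.0 / float(dt[0])
    return SampledSeries(df["force_N"].to_numpy(), rate,
                         t0=float(df["time_s"].iloc[0]), name="force_N")


# --------------------------------------------------------------- marker CSV

def write_marker_csv(path: str | Path, omc: OmcRecording) -> None:
    pd.DataFrame({"time_s": omc.hip.times,
                  "hip_z_mm": omc.hip.values,
                  "toe_z_mm": omc.toe.values}).to_csv(path, index=False)


def read_marker_csv(path: str | Path, hip_column: str = "hip_z_mm",
                    toe_column: str = "toe_z_mm",
                    rate: float | None = None) -> OmcRecording:
    """Read vertical marker trajectories in mm. Which columns play the hip
    and toe roles is configurable for richer marker sets."""
    df = pd.read_csv(path)
    for col in ("time_s", hip_column, toe_column):
        if col not in df.columns:
            raise ValueError(f"marker CSV must have a '{col}' column")
    if rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("non-uniform time column; pass rate explicitly")
        rate = 1.0 / float(dt[0])
    t0 = float(df["time_s"].iloc[0])
    return OmcRecording(
        hip=SampledSeries(df[hip_column].to_numpy(), rate, t0=t0, name="hip_mm"),
        toe=SampledSeries(df[toe_column].to_numpy(), rate, t0=t0, name="toe_mm"))


# ------------------------------------------------------------ keypoint JSON

def write_keypoints_json(path: str | Path, mmc: MmcRecording) -> None:
    """Write hip/toe pixel traces as a consolidated OpenPose-style document.

    Joints other than mid-hip and the small toe are written as zeros with
    zero confidence (undetected), as pose estimators do.
    """
    n = len(mmc.hip)
    frames = []
    for i in range(n):
        kp = [0.0] * (3 * N_KEYPOINTS)
        for j, series in ((MIDHIP, mmc.hip), (RSMALLTOE, mmc.toe)):
            kp[3 * j] = 360.0  # nominal horizontal position
            kp[3 * j + 1] = float(series.values[i])
            kp[3 * j + 2] = float(mmc.confidence.values[i])
        frames.append({"people": [{"pose_keypoints_2d": kp}]})
    Path(path).write_text(json.dumps({"fps": mmc.hip.rate, "frames": frames}))


def read_keypoints_json(path: str | Path, hip_joint: int = MIDHIP,
                        toe_joint: int = RSMALLTOE) -> MmcRecording:
    """Read a keypoint document into hip/toe pixel series plus confidence.

    Frames with no detected person yield NaN coordinates and zero
    confidence. Frames with several people keep the person with the highest
    mean keypoint confidence (single-subject assumption).
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise KeypointParseError(f"invalid JSON: {e}") from e
    fps = doc.get("fps")
    frames = doc.get("frames")
    if not frames:
        raise KeypointParseError("empty frame list")
    if not fps or fps <= 0:
        raise KeypointParseError("missing or invalid fps")

    hip = np.full(len(frames), np.nan)
    toe = np.full(len(frames), np.nan)
    conf = np.zeros(len(frames))
    multi_person_frames = 0
    for i, frame in enumerate(frames):
        people = frame.get("people", [])
        if not people:
            continue
        if len(people) > 1:
            multi_person_frames += 1
        best, best_c = None, -1.0
        for person in people:
            kp = person.get("pose_keypoints_2d")
            if kp is None or len(kp) != 3 * N_KEYPOINTS:
                raise KeypointParseError(
                    f"expected {3 * N_KEYPOINTS} keypoint values", frame=i)
            c = float(np.mean(kp[2::3]))
            if c > best_c:
                best, best_c = kp, c
        hip[i] = best[3 * hip_joint + 1]
        toe[i] = best[3 * toe_joint + 1]
        conf[i] = min(best[3 * hip_joint + 2], best[3 * toe_joint + 2])
    if multi_person_frames:
        warnings.warn(f"{multi_person_frames} frame(s) contained multiple "
                      "people; kept the highest-confidence detection "
                      "(single-subject assumption)", stacklevel=2)
    return MmcRecording(hip=SampledSeries(hip, fps, name="hip_px"),
                        toe=SampledSeries(toe, fps, name="toe_px"),
                        confidence=SampledSeries(conf, fps, name="confidence"))


# ------------------------------------------------------------ configuration

@dataclass
class SessionConfig:
    """All tunable parameters of one processing session.

    Serialises losslessly to YAML so a session can be reproduced from its
    config file alone.
    """

    task: str = "bilateral"
    window_t: float = 1.5            # s to either side of each hip peak
    savgol_window: int = 21          # samples
    z_thresh: float = 3.0            # spike-removal z-score threshold
    alpha: float = 0.5               # free-fall window fraction for PTM
    confidence_threshold: float = 0.3
    prominence_fraction: float = 0.5
    min_flight: float = 0.08         # s
    stance_window: float = 0.5       # s, force baseline
    baseline_window: float = 0.5     # s, toe baseline
    scale_fallback: str = "cohort_mean"  # or "none"
    seed: int = 0

    def validate(self) -> None:
        if self.task not in ("bilateral", "unilateral"):
            raise ValueError("task must be bilateral or unilateral")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.savgol_window < 5 or self.savgol_window % 2 == 0:
            raise ValueError("savgol_window must be odd and >= 5")
        for name in ("window_t", "z_thresh", "min_flight", "stance_window",
                     "baseline_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.scale_fallback not in ("cohort_mean", "none"):
            raise ValueError("scale_fallback must be cohort_mean or none")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg
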