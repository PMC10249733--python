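"""Jump height from metric kinematic series.

Height is the maximum vertical displacement of the fifth metatarsal (small
toe) above its quiet-stance baseline within a repetition window. Tracking
the toe is robust to jump strategy, unlike inferring height from the flight
time of the centre of mass, which varies with landing posture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .preprocess import JumpSegment
from .series import SampledSeries

Method = Literal["FP", "OMC", "MMC_RMM", "MMC_PTM", "TRUTH"]


@dataclass
class JumpHeightResult:
    """Height of one repetition by one method, with QC flags carried through."""

    rep_id: int
    method: str
    height_cm: float
    qc_flags: set = field(default_factory=set)
    participant: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.height_cm):
            raise ValueError("height must be finite")

    @property
    def usable(self) -> bool:
        return not ({"uncharacteristic", "low_confidence"} & self.qc_flags)


def toe_displacement_height(toe_mm: SampledSeries, segment: JumpSegment,
                            baseline_window: float = 0.5,
                            method: str = "OMC") -> JumpHeightResult:
    """Measure one repetition's height from an up-positive toe series in mm.

    The baseline is the median toe height over the leading quiet-stance
    portion of the segment (before the countermovement); the height is the
    in-segment maximum minus that baseline, in cm. A baseline window that is
    empty or occluded (a zero-valued run from marker dropout) raises, since
    the reference level would be meaningless.
    """
    x = toe_mm.values[segment.start_index:segment.end_index]
    n_base = int(round(baseline_window * toe_mm.rate))
    if n_base < 1 or x.size == 0:
        raise ValueError("empty baseline window; widen the segment")
    base = x[:n_base]
    if base.size < 1:
        raise ValueError("baseline window precedes the segment; widen it")
    if np.any(base == 0.0) and np.ptp(base) > 0:
        raise ValueError("zero-valued samples in the baseline window "
                         "(marker occlusion); widen the baseline window")
    baseline = float(np.median(base))
    height_cm = (float(np.max(x)) - baseline) / 10.0
    return JumpHeightResult(rep_id=segment.rep_id, method=method,
                            height_cm=height_cm, qc_flags=set(segment.qc_flags))


def summarize_per_participant(results: list[JumpHeightResult]) -> pd.DataFrame:
    """Participant x task x method table of mean height over usable reps.

    Mirrors the standard reporting layout: each cell is the mean across
    repetitions; cells whose repetitions were all flagged are marked ``F``
    (failure), and methods excluded for a participant-task are ``E``.
    """
    rows = []
    for r in results:
        rows.append({"participant": r.participant, "task": r.task,
                     "method": r.method, "rep_id": r.rep_id,
                     "height_cm": r.height_cm, "usable": r.usable})
    df = pd.DataFrame(rows)
    if df.empty:
        return df

    def _cell(group: pd.DataFrame):
        ok = group[group["usable"]]
        if ok.empty:
            return "F"
        return round(float(ok["height_cm"].mean()), 2)

    table = (df.groupby(["participant", "task", "method"])
               .apply(_cell, include_groups=False)
               .unstack("method"))
    return table
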