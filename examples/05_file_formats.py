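"""Round-trip the three capture file formats.

The same dialects the readers consume are produced by the synthetic
writers, so synthetic fixtures are indistinguishable from real captures:
force CSV (time_s, force_N), marker CSV (time_s + mm columns), and an
OpenPose-style 25-keypoint JSON with per-frame confidence.
"""

import tempfile
from pathlib import Path

import numpy as np

import cmjkit as ck

rec = ck.simulate_recording(ck.JumpSpec(true_height=18.0, seed=5))

with tempfile.TemporaryDirectory() as d:
    d = Path(d)
    ck.write_force_csv(d / "force.csv", rec.force)
    ck.write_marker_csv(d / "markers.csv", rec.omc)
    ck.write_keypoints_json(d / "keypoints.json", rec.mmc)

    force = ck.read_force_csv(d / "force.csv")
    omc = ck.read_marker_csv(d / "markers.csv")
    mmc = ck.read_keypoints_json(d / "keypoints.json")

    print(f"force: {len(force)} samples at {force.rate:.0f} Hz, "
          f"round-trip exact: {np.allclose(force.values, rec.force.values)}")
    print(f"markers: {len(omc.toe)} samples at {omc.toe.rate:.0f} Hz, "
          f"round-trip exact: {np.allclose(omc.toe.values, rec.omc.toe.values)}")
    print(f"keypoints: {len(mmc.hip)} frames at {mmc.hip.rate:.0f} fps, "
          f"round-trip exact: {np.allclose(mmc.hip.values, rec.mmc.hip.values)}")
    print(f"files written: {sorted(p.name for p in d.iterdir())}")
# The CLI wraps the same functions:  cmjkit simulate --out captures/
# then  cmjkit force captures/force.csv  or  cmjkit mmc captures/keypoints.json
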