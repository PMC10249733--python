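"""Markerless heights from a keypoint trace alone (deployment path).

No reference object, no marker system: gravity calibrates the camera.
Around the hip apex the body is in free fall, so the observed pixel drop
over T seconds must equal 500 T^2 g millimetres, which fixes the scale
R (mm/px). Heights are then the toe's maximum displacement in mm.
"""

import numpy as np

import cmjkit as ck

spec = ck.JumpSpec(true_height=22.0, n_reps=3, pixel_noise_sd=1.0,
                   spike_prob=0.01, seed=3)
mmc = ck.render_mmc(ck.simulate_motion(spec), spec)

session = ck.SessionRecording(participant="P01", mmc=mmc)
report = ck.run_session([session])

print("fitted pixel-to-metric scales (true scale 3.43 mm/px):")
for s in report.scales:
    print(f"  rep {s['rep_id']}: R = {s['R_mm_per_px']:.3f} mm/px from "
          f"T = {s['free_fall_T_s']:.3f} s free fall, "
          f"{s['pixel_drop_px']:.1f} px drop")

df = report.heights_frame()
ptm = df[df["method"] == "MMC_PTM"]
print(ptm[["rep_id", "height_cm", "usable"]].to_string(index=False))
print(f"mean height {ptm['height_cm'].mean():.2f} cm vs true 22.00 cm")
# With 1 px keypoint noise the per-rep scale is typically within a few
# percent, and the heights land within about half a centimetre of truth.
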