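#!/usr/bin/env python
"""Generate the synthetic recordings the downstream analyses run on.

Writes, under results/data/:
  wt_planewave.csv     — wild-type-like traveling wave (C0 = -0.232 μm^-1,
                         |psi_1| = 0.68, omega = 427 rad/s, 30 rad/s rotation,
                         20 mrad tracking noise, 3000 frames at 1000 Hz)
  mbo2_planewave.csv   — mbo2-like nearly symmetric beat (C0 = -0.0276)
  wt_model.csv         — forward model under dynamic curvature control
                         (chi' = 19.8 nN/μm^2, beta'' = -6.5 nN) with noise;
                         the ground truth travels in the sidecar
  wt_centerline.csv    — tracker-style xy point table (5 nm position noise)
"""

from pathlib import Path

import axobeat as ab

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20260930


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    for preset in ("chlamy_wt", "chlamy_mbo2"):
        spec = ab.SyntheticSpec.from_preset(preset, seed=SEED)
        ser = ab.make_planewave_series(spec)
        name = preset.replace("chlamy_", "") + "_planewave.csv"
        ab.write_waveform(ser, OUT / name)
        print(f"wrote {name}: {ser.n_frames} frames x {ser.psi.shape[1]} positions")

    wt = ab.mechanical_params("chlamy_wt")
    resp = ab.MotorResponse("curvature", chi=19.8, beta=-6.5j)
    resp.chi_b = ab.critical_basal_impedance(wt, resp)
    model = ab.make_model_series(wt, resp, noise_angle=0.02, seed=SEED)
    ab.write_waveform(model, OUT / "wt_model.csv")
    print("wrote wt_model.csv (curvature-control ground truth in sidecar)")

    track_spec = ab.SyntheticSpec.from_preset("chlamy_wt", seed=SEED, n_frames=500)
    track = ab.make_centerline_series(track_spec)
    ab.write_waveform(track, OUT / "wt_centerline.csv")
    print("wrote wt_centerline.csv (xy tracks, 5 nm noise)")


if __name__ == "__main__":
    main()
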