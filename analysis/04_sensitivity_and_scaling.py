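#!/usr/bin/env python
"""Sensitivity of the curvature-control fit and the gamma ~ 1/C0 scaling.

Part 1: R² landscape over (chi', beta'') around the best curvature-control
fit of the wild-type model series, with the passive/active classification of
the closed basal impedance (the R² = 0.90 region bounds the identifiable
parameter range).

Part 2: a cohort spanning a fifty-fold range of static curvature, each
axoneme fitted with both the normal-force and the curvature model.  The
normal-force coefficient gamma is forced to scale as |C0|^-1 (log-log slope
~ -1) while beta'' stays constant — the argument that normal-force control
hinges on a residual property.

Writes results/sensitivity/{map.csv,map.png,scaling.json,scaling.png}.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import axobeat as ab

ROOT = Path(__file__).resolve().parents[1] / "results"


def sensitivity():
    series = ab.load_waveform(ROOT / "data" / "wt_model.csv", "angles")
    d = ab.decompose(series)
    params = ab.mechanical_params("chlamy_wt")
    best = ab.fit_model(d, params, "curvature")
    m = ab.sensitivity_map(d, params, best=best, n=21)
    out = ROOT / "sensitivity"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, b in enumerate(m.beta_values):
        for j, c in enumerate(m.chi_values):
            rows.append(
                {
                    "chi_norm": m.chi_norm[j],
                    "beta_norm": m.beta_norm[i],
                    "R2": m.R2[i, j],
                    "label": m.labels[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(out / "map.csv", index=False, float_format="%.6g")

    fig, ax = plt.subplots(figsize=(5, 4))
    pc = ax.pcolormesh(m.chi_norm, m.beta_norm, m.R2, shading="auto", vmin=0, vmax=1)
    ax.contour(m.chi_norm, m.beta_norm, m.R2, levels=[0.90], colors="w")
    ax.contour(
        m.chi_norm, m.beta_norm, m.passive_mask.astype(float), levels=[0.5], colors="k"
    )
    ax.set_xscale("log"); ax.set_yscale("log")
    ax.set_xlabel("chi' / chi'_best"); ax.set_ylabel("beta'' / beta''_best")
    fig.colorbar(pc, label="R²")
    fig.tight_layout(); fig.savefig(out / "map.png", dpi=150); plt.close(fig)
    print(f"sensitivity map: best R2 = {m.R2.max():.4f}, "
          f"{m.region_mask(0.90).sum()} / {m.R2.size} cells above 0.90")


def scaling():
    wt = ab.mechanical_params("chlamy_wt")
    nf_fits, cv_fits, c0s = [], [], []
    for i, fac in enumerate(np.geomspace(1.0, 1 / 50, 6)):
        p = wt.with_(C0=float(-0.232 * fac))
        r = ab.MotorResponse("curvature", chi=19.8, beta=-6.5j)
        r.chi_b = ab.critical_basal_impedance(p, r)
        ser = ab.make_model_series(p, r, noise_angle=0.01, seed=300 + i, n_frames=2000)
        d = ab.decompose(ser)
        nf_fits.append(ab.fit_model(d, p, "normal_force"))
        cv_fits.append(ab.fit_model(d, p, "curvature"))
        c0s.append(p.C0)
    res = ab.gamma_curvature_scaling(nf_fits, cv_fits)
    out = ROOT / "sensitivity"
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "C0_per_um": c0s,
        "abs_gamma": [abs(f.response.gamma) for f in nf_fits],
        "beta_pp_nN": [f.response.beta.imag for f in cv_fits],
        "gamma_loglog_slope": res.gamma_slope,
        "gamma_slope_stderr": res.gamma_stderr,
        "beta_loglog_slope": res.beta_slope,
        "beta_slope_stderr": res.beta_stderr,
    }
    (out / "scaling.json").write_text(json.dumps(payload, indent=1))

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    axes[0].loglog(np.abs(c0s), payload["abs_gamma"], "o-")
    axes[0].set_xlabel("|C0| (1/μm)"); axes[0].set_ylabel("|gamma|")
    axes[1].semilogx(np.abs(c0s), np.abs(payload["beta_pp_nN"]), "s-")
    axes[1].set_xlabel("|C0| (1/μm)"); axes[1].set_ylabel("|beta''| (nN)")
    axes[1].set_ylim(0, 10)
    fig.tight_layout(); fig.savefig(out / "scaling.png", dpi=150); plt.close(fig)
    print(f"gamma slope {res.gamma_slope:+.3f} ± {res.gamma_stderr:.3f}; "
          f"beta'' slope {res.beta_slope:+.4f} ± {res.beta_stderr:.4f}")


if __name__ == "__main__":
    sensitivity()
    scaling()
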