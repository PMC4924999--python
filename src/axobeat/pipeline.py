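"""Pipeline orchestration: convert -> decompose -> fit -> report.

A :class:`RunConfig` fully specifies one reproducible run; it is serialized
into the output directory as the provenance record, every stage writes plain
JSON/CSV (plus static plot images), and reruns with the same config and seed
produce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import modes
from .errors import AxobeatError
from .fitting import fit_model
from .geometry import angles_to_centerline, centerline_to_angles, load_waveform
from .presets import mechanical_params

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(AxobeatError, RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    input_path: str
    outdir: str
    kind: str = "angles"                     # "angles" | "centerline"
    preset: str = "chlamy_wt"
    params_overrides: dict = field(default_factory=dict)
    variants: tuple = ("sliding", "curvature", "normal_force")
    n_points: int = 20
    seed: int = 0
    make_plots: bool = True
    log_level: str = "INFO"


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, complex):
        return [round(obj.real, nd), round(obj.imag, nd)]
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), nd)
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(float(obj), nd)
    return obj


def _write_json(path: Path, payload: dict):
    path.write_text(json.dumps(_round_floats(payload), indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``; returns the report.

    Per input: modal decomposition, a fit for each requested control variant,
    a comparison table of R² per variant, Re/Im mode overlays and shape
    reconstructions.  Stage failures raise :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(out / "config.json", dataclasses.asdict(config))

    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")

    try:
        obj = load_waveform(path, kind=config.kind)
        if config.kind == "centerline":
            series = centerline_to_angles(obj, n_points=config.n_points)
        else:
            series = obj
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise PipelineError("load", e) from e

    try:
        decomp = modes.decompose(series)
        desc = modes.describe(decomp, series)
    except Exception as e:
        raise PipelineError("decompose", e) from e

    mode_table = pd.DataFrame(
        {
            "s_um": decomp.arc_positions,
            "psi0": decomp.psi0,
            "re_psi1": decomp.psi1.real,
            "im_psi1": decomp.psi1.imag,
        }
    )
    if desc.sem_psi0 is not None:
        mode_table["sem_psi0"] = desc.sem_psi0
        mode_table["sem_psi1"] = desc.sem_psi1
    mode_table.to_csv(out / "modes.csv", index=False, float_format="%.10g")

    params = mechanical_params(config.preset, **config.params_overrides)
    fits = {}
    for variant in config.variants:
        try:
            fits[variant] = fit_model(decomp, params, variant)
        except Exception as e:
            raise PipelineError(f"fit:{variant}", e) from e

    report = {
        "omega": decomp.omega,
        "omega_rot": decomp.omega_rot,
        "C0": desc.C0,
        "v": desc.v,
        "lambda": desc.wavelength_lambda,
        "power_fractions": decomp.power_fractions,
        "fits": {
            v: {
                "R2": f.R2,
                "chi": f.response.chi,
                "beta": f.response.beta,
                "gamma": f.response.gamma,
                "chi_b": f.response.chi_b,
                "delta_b0_nm": f.delta_b0,
                "delta_b1_abs_nm": f.delta_b1_abs,
                "passive_base": bool(f.passive_base),
            }
            for v, f in fits.items()
        },
    }
    _write_json(out / "report.json", report)

    if config.make_plots:
        try:
            _make_plots(out, decomp, fits, params)
        except Exception as e:
            raise PipelineError("plots", e) from e
    return report


def _make_plots(out: Path, decomp, fits, params):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = decomp.arc_positions
    n = max(1, len(fits))
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False)
    from .model import solve_dynamic_mode

    for ax, (variant, f) in zip(axes[0], fits.items()):
        sol = solve_dynamic_mode(f.params, f.response, s_grid=s, sigma_tol=1e-4)
        th = f.scale * sol.psi1
        ax.plot(s, decomp.psi1.real, "k.", label="Re data")
        ax.plot(s, decomp.psi1.imag, "b.", label="Im data")
        ax.plot(s, th.real, "k-")
        ax.plot(s, th.imag, "b-")
        ax.set_title(f"{variant} (R²={f.R2:.2f})")
        ax.set_xlabel("s (μm)")
    axes[0, 0].set_ylabel("ψ₁")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "mode_fits.png", dpi=120)
    plt.close(fig)

    angles, shapes = modes.reconstruct_shapes(
        decomp, modes={0, 1}, phases=np.linspace(0, 2 * np.pi, 12, endpoint=False)
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    for xy in shapes:
        ax.plot(xy[:, 0], xy[:, 1], lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    fig.tight_layout()
    fig.savefig(out / "shapes.png", dpi=120)
    plt.close(fig)
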