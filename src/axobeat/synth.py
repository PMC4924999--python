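"""Synthetic waveform generator.

Emulates the statistical structure of high-speed tracking data from
reactivated *Chlamydomonas* axonemes: a traveling fundamental wave on top of
a constant static curvature, a slow rigid rotation of the whole axoneme, and
tracking noise (~5 nm in position, ~20 mrad in tangent angle).  Default
record: 3000 frames at 1000 Hz on 20 arc positions.

Every generator is fully determined by its seed (single RNG stream per
spec); the ground truth is carried in the series metadata and survives the
round trip through ``write_waveform``/``load_waveform``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .geometry import TangentAngleSeries, TrackedCenterline, angles_to_centerline
from .model import MechanicalParams, MotorResponse, solve_dynamic_mode
from .presets import PRESETS

__all__ = [
    "SyntheticSpec",
    "make_planewave_series",
    "make_model_series",
    "make_centerline_series",
]


@dataclass
class SyntheticSpec:
    """Kinematic description of a synthetic beating axoneme.

    amp1 is the rms fundamental amplitude, i.e. the target |psi_1| under the
    rms modal convention (the sinusoid's peak amplitude is amp1*sqrt(2)).
    """

    preset: str = "chlamy_wt"
    L: float = 11.7            # μm
    C0: float = -0.232         # μm^-1
    amp1: float = 0.68         # rad (rms of |psi_1|)
    amp2: float = 0.0          # optional 2nd harmonic, same convention
    lam: float = 11.7          # wavelength, μm (signed; >0 = base-to-tip)
    omega: float = 427.0       # rad/s
    omega_rot: float = 30.0    # rad/s
    noise_angle: float = 0.020  # rad
    noise_xy: float = 0.005    # μm
    n_frames: int = 3000
    frame_rate: float = 1000.0  # Hz
    n_points: int = 20
    phase0: float = 0.0
    seed: int = 0

    @classmethod
    def from_preset(cls, preset: str = "chlamy_wt", **overrides) -> "SyntheticSpec":
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}")
        p = PRESETS[preset]
        kw = dict(preset=preset, L=p["L"], C0=p["C0"], omega=p["omega"], lam=p["L"])
        kw.update(overrides)
        return cls(**kw)


def make_planewave_series(spec: SyntheticSpec) -> TangentAngleSeries:
    """Traveling-wave tangent-angle series

        psi(s,t) = C0 s + amp1 sqrt(2) sin(w t - 2 pi s/lam + phi0)
                   + w_rot t + noise,

    with i.i.d. Gaussian angle noise.  Bit-reproducible for a fixed seed.
    """
    if spec.lam == 0:
        raise ValueError("wavelength lam must be nonzero")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) / spec.frame_rate
    s = np.linspace(0.0, spec.L, spec.n_points)
    arg = spec.omega * t[:, None] - 2 * np.pi * s[None, :] / spec.lam + spec.phase0
    psi = spec.C0 * s[None, :] + spec.amp1 * np.sqrt(2.0) * np.sin(arg)
    if spec.amp2:
        psi = psi + spec.amp2 * np.sqrt(2.0) * np.sin(2 * arg)
    psi = psi + spec.omega_rot * t[:, None]
    if spec.noise_angle > 0:
        psi = psi + rng.normal(0.0, spec.noise_angle, size=psi.shape)
    meta = {"generator": "planewave", **asdict(spec)}
    return TangentAngleSeries(psi, s, spec.frame_rate, spec.L, meta=meta)


def make_model_series(
    params: MechanicalParams,
    resp: MotorResponse,
    noise_angle: float = 0.020,
    seed: int = 0,
    n_frames: int = 3000,
    frame_rate: float = 1000.0,
    n_points: int = 20,
    amp_rms: float = 0.68,
    omega_rot: float = 0.0,
) -> TangentAngleSeries:
    """Forward model: a series whose fundamental mode is the critical-point
    solution of the boundary-value problem, scaled to rms |psi_1| = amp_rms,
    on top of the constant-curvature static mode.  Ground-truth response
    coefficients travel in the metadata sidecar."""
    s = np.linspace(0.0, params.L, n_points)
    sol = solve_dynamic_mode(params, resp, s_grid=s)
    psi1 = amp_rms * sol.psi1  # gauge already unit-rms
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    psi = (
        params.C0 * s[None, :]
        + np.sqrt(2.0) * np.real(psi1[None, :] * np.exp(1j * params.omega * t)[:, None])
        + omega_rot * t[:, None]
    )
    if noise_angle > 0:
        psi = psi + rng.normal(0.0, noise_angle, size=psi.shape)
    meta = {
        "generator": "model",
        "variant": resp.variant,
        "chi": [resp.chi.real, resp.chi.imag],
        "beta": [resp.beta.real, resp.beta.imag],
        "gamma": [resp.gamma.real, resp.gamma.imag],
        "chi_b": [resp.chi_b.real, resp.chi_b.imag],
        "amp_rms": amp_rms,
        "delta_b1": [
            (amp_rms * sol.delta_b1).real,
            (amp_rms * sol.delta_b1).imag,
        ],
        "omega": params.omega,
        "C0": params.C0,
        "L": params.L,
        "noise_angle": noise_angle,
        "seed": seed,
    }
    return TangentAngleSeries(psi, s, frame_rate, params.L, meta=meta)


def make_centerline_series(spec: SyntheticSpec) -> TrackedCenterline:
    """Tracker-like xy point series: the plane-wave angles integrated to
    positions on a fine grid, sampled at n_points, with isotropic Gaussian
    xy noise of sd noise_xy."""
    rng = np.random.default_rng(spec.seed)
    fine = 10 * (spec.n_points - 1) + 1
    clean = SyntheticSpec(**{**asdict(spec), "noise_angle": 0.0, "n_points": fine})
    series = make_planewave_series(clean)
    pts = np.empty((spec.n_frames, spec.n_points, 2))
    idx = np.arange(0, fine, 10)
    for i in range(spec.n_frames):
        xy = angles_to_centerline(
            series.psi[i], origin=(0.0, 0.0), arc_positions=series.arc_positions
        )
        pts[i] = xy[idx]
    if spec.noise_xy > 0:
        pts = pts + rng.normal(0.0, spec.noise_xy, size=pts.shape)
    t = np.arange(spec.n_frames) / spec.frame_rate
    return TrackedCenterline(
        t, pts, pixel_size=0.139, meta={"generator": "centerline", **asdict(spec)}
    )
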