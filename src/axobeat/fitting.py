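"""Fit motor-response coefficients to an observed fundamental mode.

For each control variant the free coefficients are adjusted to maximize the
coefficient of determination R² between the theoretical and experimental
complex fundamental modes sampled at the experimental arc positions; at every
step the basal impedance chi_b is closed by the boundary-condition
solvability requirement, and a single complex amplitude factor absorbs the
arbitrary scale/phase of the critical mode.

Free parameters per variant: sliding (chi', chi'' <= 0), curvature
(chi', beta''; the instantaneous-curvature and dissipative-sliding
coefficients chi'' = beta' = 0), normal-force (chi', gamma', gamma'').
The static mode is excluded from the objective: static balance is enforced
exactly by the tip-concentrated static force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import linregress

from .errors import AxobeatError, FitError, NoOscillatorySolutionError
from .model import (
    MechanicalParams,
    MotorResponse,
    critical_basal_impedance,
    solve_dynamic_mode,
)
from .modes import ModalDecomposition, static_curvature

__all__ = [
    "FitResult",
    "SensitivityMap",
    "ScalingResult",
    "score_R2",
    "basal_impedance_from_boundary",
    "fit_model",
    "sensitivity_map",
    "gamma_curvature_scaling",
]


def score_R2(theory_psi1, exp_psi1) -> float:
    """R² between complex modes after a least-squares complex scale factor.

    R² = 1 - sum |c*theory - data|^2 / sum |data - mean(data)|^2, clipped to
    [0, 1]; invariant under a common global phase rotation of both inputs
    and under rescaling of the data (the scale absorbs it).
    """
    th = np.asarray(theory_psi1, dtype=complex).ravel()
    d = np.asarray(exp_psi1, dtype=complex).ravel()
    if th.shape != d.shape:
        raise ValueError("theory and data must share the arc grid")
    denom = np.sum(np.abs(d - d.mean()) ** 2)
    if denom == 0:
        raise ValueError("zero-variance data")
    tt = np.vdot(th, th)
    c = np.vdot(th, d) / tt if tt != 0 else 0.0
    r2 = 1.0 - np.sum(np.abs(c * th - d) ** 2) / denom
    return float(np.clip(r2.real, 0.0, 1.0))


def _fit_scale(theory, data) -> complex:
    th = np.asarray(theory, dtype=complex).ravel()
    d = np.asarray(data, dtype=complex).ravel()
    tt = np.vdot(th, th)
    return complex(np.vdot(th, d) / tt) if tt != 0 else 0.0


def basal_impedance_from_boundary(
    params: MechanicalParams, resp: MotorResponse
) -> complex:
    """The chi_b zeroing the boundary determinant for fixed variant
    coefficients (closed form; the determinant is affine in chi_b).

    An "active base" (Re chi_b < 0 or Im chi_b < 0) is legal output; callers
    flag it via MotorResponse.passive_base.
    """
    return critical_basal_impedance(params, resp)


@dataclass
class FitResult:
    """Best-fit motor response for one variant, with the standard report
    fields (R², basal sliding amplitudes, complex scale)."""

    response: MotorResponse
    R2: float
    scale: complex                 # complex amplitude factor theory -> data
    delta_b0: float                # static basal sliding, nm
    delta_b1_abs: float            # |Delta_b1| at the fitted amplitude, nm
    params: MechanicalParams
    diagnostics: list = field(default_factory=list)

    @property
    def passive_base(self) -> bool:
        return self.response.passive_base


_STARTS = {
    # log-spaced deterministic multi-starts per variant (8 each)
    "sliding": [  # (chi', chi'') both <= 0
        (-1.0, -0.1), (-3.0, -0.3), (-10.0, -0.1), (-10.0, -1.0),
        (-30.0, -3.0), (-30.0, -0.3), (-100.0, -1.0), (-3.0, -3.0),
    ],
    "curvature": [  # (chi', beta'')
        (3.0, -1.0), (3.0, -10.0), (10.0, -3.0), (30.0, -3.0),
        (30.0, -30.0), (10.0, -30.0), (-3.0, -3.0), (100.0, -10.0),
    ],
    "normal_force": [  # (chi', gamma', gamma'')
        (3.0, 0.1, 1.0), (3.0, 1.0, 10.0), (10.0, 0.1, 1.0), (10.0, 1.0, 3.0),
        (30.0, 0.3, 10.0), (30.0, 3.0, 30.0), (10.0, 0.1, 30.0), (3.0, 0.3, 100.0),
    ],
}


def _resp_from_vector(variant: str, x) -> MotorResponse:
    if variant == "sliding":
        return MotorResponse(
            "sliding", chi=complex(-abs(x[0]), -abs(x[1]))
        )
    if variant == "curvature":
        return MotorResponse("curvature", chi=complex(x[0], 0.0), beta=1j * x[1])
    if variant == "normal_force":
        return MotorResponse(
            "normal_force", chi=complex(x[0], 0.0), gamma=complex(x[1], x[2])
        )
    raise ValueError(variant)


def _evaluate(variant, x, params, data_psi1, s_grid):
    """(R2, resp-with-chi_b, solution) at one coefficient vector; R2 = -inf
    where the boundary closure or the solve fails."""
    try:
        resp = _resp_from_vector(variant, x)
    except (ValueError, AxobeatError):
        return -np.inf, None, None
    try:
        chi_b = basal_impedance_from_boundary(params, resp)
        resp.chi_b = chi_b
        sol = solve_dynamic_mode(params, resp, s_grid=s_grid, sigma_tol=1e-4)
    except (NoOscillatorySolutionError, FloatingPointError):
        return -np.inf, None, None
    if not np.all(np.isfinite(sol.psi1)):
        return -np.inf, None, None
    try:
        r2 = score_R2(sol.psi1, data_psi1)
    except ValueError:
        return -np.inf, None, None
    return r2, resp, sol


def fit_model(
    decomp: ModalDecomposition,
    params: MechanicalParams,
    variant: str,
    starts=None,
    maxiter: int = 200,
) -> FitResult:
    """Maximize R² over the variant's free coefficients.

    The mechanical C0 and omega are taken from the decomposition (static
    curvature slope and measured beat frequency); chi_b is closed by the
    boundary conditions at every step; derivative-free simplex with
    deterministic multi-starts.
    """
    C0 = static_curvature(decomp).C0
    kw = {"C0": C0}
    if np.isfinite(decomp.omega):
        kw["omega"] = float(decomp.omega)
    params = params.with_(**kw)
    data = decomp.psi1
    if data.size < 10:
        raise ValueError("need psi_1 on at least 10 arc positions")
    s_grid = decomp.arc_positions
    if starts is None:
        starts = _STARTS[variant]

    best = None
    diag = []
    for x0 in starts:
        res = minimize(
            lambda x: -_evaluate(variant, x, params, data, s_grid)[0],
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": 1e-3,
                "fatol": 1e-7,
            },
        )
        r2 = -res.fun
        diag.append({"x0": tuple(x0), "x": tuple(res.x), "R2": float(r2)})
        if np.isfinite(r2) and (best is None or r2 > best[0]):
            best = (float(r2), res.x.copy())
    if best is None or not np.isfinite(best[0]) or best[0] == -np.inf:
        raise FitError("optimizer did not converge from any start", best_so_far=diag)

    r2, x = best
    _, resp, sol = _evaluate(variant, x, params, data, s_grid)
    scale = _fit_scale(sol.psi1, data)
    delta_b1_abs = abs(scale * sol.delta_b1) * 1e3  # μm -> nm
    kb = resp.chi_b.real
    delta_b0 = (
        params.kappa * params.C0 / (params.a * kb) * 1e3 if kb != 0 else np.inf
    )
    return FitResult(
        response=resp,
        R2=float(r2),
        scale=scale,
        delta_b0=float(delta_b0),
        delta_b1_abs=float(delta_b1_abs),
        params=params,
        diagnostics=diag,
    )


@dataclass
class SensitivityMap:
    """R² landscape over (chi', beta'') for curvature control, normalized to
    the best fit, with the passive-base classification of chi_b."""

    chi_values: np.ndarray        # absolute chi' grid
    beta_values: np.ndarray       # absolute beta'' grid
    chi_norm: np.ndarray          # chi'/chi'_best
    beta_norm: np.ndarray         # beta''/beta''_best
    R2: np.ndarray                # (len(beta), len(chi))
    chi_b: np.ndarray             # complex, same shape
    best_index: tuple

    @property
    def passive_mask(self) -> np.ndarray:
        return (self.chi_b.real >= 0) & (self.chi_b.imag >= 0)

    @property
    def labels(self) -> np.ndarray:
        """One of {passive, active_re, active_im, active_both} per cell."""
        re_bad = self.chi_b.real < 0
        im_bad = self.chi_b.imag < 0
        out = np.full(self.chi_b.shape, "passive", dtype=object)
        out[re_bad & ~im_bad] = "active_re"
        out[~re_bad & im_bad] = "active_im"
        out[re_bad & im_bad] = "active_both"
        return out

    def region_mask(self, level: float = 0.90) -> np.ndarray:
        return self.R2 >= level


def sensitivity_map(
    decomp: ModalDecomposition,
    params: MechanicalParams,
    best: FitResult | None = None,
    rel_range: tuple[float, float] = (0.2, 3.0),
    n: int = 21,
) -> SensitivityMap:
    """R² over a (chi', beta'') grid around the curvature-control best fit."""
    if best is None:
        best = fit_model(decomp, params, "curvature")
    params = best.params
    chi0 = best.response.chi.real
    beta0 = best.response.beta.imag
    factors = np.geomspace(rel_range[0], rel_range[1], n - 1)
    factors = np.sort(np.append(factors, 1.0))
    chis = chi0 * factors
    betas = beta0 * factors
    R2 = np.zeros((betas.size, chis.size))
    chi_b = np.zeros((betas.size, chis.size), dtype=complex)
    for i, b in enumerate(betas):
        for j, c in enumerate(chis):
            r2, resp, _ = _evaluate(
                "curvature", (c, b), params, decomp.psi1, decomp.arc_positions
            )
            R2[i, j] = r2 if np.isfinite(r2) else 0.0
            chi_b[i, j] = resp.chi_b if resp is not None else np.nan
    best_idx = np.unravel_index(np.argmax(R2), R2.shape)
    return SensitivityMap(
        chi_values=chis,
        beta_values=betas,
        chi_norm=chis / chi0,
        beta_norm=betas / beta0,
        R2=R2,
        chi_b=chi_b,
        best_index=tuple(int(v) for v in best_idx),
    )


@dataclass
class ScalingResult:
    gamma_slope: float
    gamma_stderr: float
    beta_slope: float | None
    beta_stderr: float | None
    n: int


def gamma_curvature_scaling(
    normal_force_fits: list[FitResult],
    curvature_fits: list[FitResult] | None = None,
) -> ScalingResult:
    """log-log regression of the fitted |gamma| on |C0| across axonemes.

    The linearized normal force is proportional to C0, so a C0-independent
    beat requires |gamma| ~ |C0|^-1 (slope -1); the companion curvature-fit
    check is that beta'' is C0-independent (slope 0).
    """
    if len(normal_force_fits) < 3:
        raise ValueError("need at least 3 normal-force fits")
    c0 = np.array([abs(f.params.C0) for f in normal_force_fits])
    if np.unique(np.round(np.log(c0), 12)).size < 2:
        raise ValueError("degenerate design: all C0 equal")
    g = np.array([abs(f.response.gamma) for f in normal_force_fits])
    reg = linregress(np.log(c0), np.log(g))
    beta_slope = beta_err = None
    if curvature_fits:
        cb = np.array([abs(f.params.C0) for f in curvature_fits])
        bb = np.array([abs(f.response.beta.imag) for f in curvature_fits])
        regb = linregress(np.log(cb), np.log(bb))
        beta_slope, beta_err = float(regb.slope), float(regb.stderr)
    return ScalingResult(
        gamma_slope=float(reg.slope),
        gamma_stderr=float(reg.stderr),
        beta_slope=beta_slope,
        beta_stderr=beta_err,
        n=len(normal_force_fits),
    )
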