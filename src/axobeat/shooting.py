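"""Independent shooting solver for the fundamental-mode boundary-value problem.

Verification tool: integrates the same two-filament mode equations with an
adaptive Runge-Kutta method (a numerical route independent of the
matrix-exponential fundamental solution in :mod:`axobeat.model`), builds the
identical boundary system from the integrated basis, and extracts the
critical mode.  Used as a cross-check oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    MechanicalParams,
    ModelSolution,
    MotorResponse,
    _boundary_matrix,
    _f_row,
    normal_force_fundamental,
)

__all__ = ["shooting_propagators", "solve_dynamic_mode_shooting"]


def _rhs_factory(params: MechanicalParams, resp: MotorResponse):
    """Real-stacked right-hand side written directly from the mode equations
    (deliberately not sharing the matrix construction of axobeat.model)."""
    chi, beta, gamma = resp.effective()
    kap, a, C0, w = params.kappa, params.a, params.C0, params.omega
    xin = params.xi_n
    r = params.xi_n / params.xi_t
    B2 = beta + gamma * C0 * kap / a

    def rhs(_, yr):
        y = yr[:8] + 1j * yr[8:]
        psi, psip, psipp, psippp, tau, taup, F, D = y
        f = chi * a * psi + B2 * psip + gamma * C0 * F + D
        fp = chi * a * psip + B2 * psipp + gamma * C0 * f
        fpp = chi * a * psipp + B2 * psippp + gamma * C0 * fp
        psi4 = (
            -1j * w * xin * psi
            + a * fpp
            + (1 + r) * C0 * taup
            + r * C0**2 * (kap * psipp - a * f)
        ) / kap
        tau2 = (C0**2 * tau - (1 + r) * C0 * (kap * psippp - a * fp)) / r
        dy = np.array([psip, psipp, psippp, psi4, taup, tau2, f, 0.0], dtype=complex)
        return np.concatenate([dy.real, dy.imag])

    return rhs


def shooting_propagators(params, resp, s_values, rtol=1e-10, atol=1e-12):
    """Phi(s), W(s) from 8 Runge-Kutta integrations of unit initial states
    (7 homogeneous + 1 carrying the constant force offset D)."""
    rhs = _rhs_factory(params, resp)
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    order = np.argsort(s_values)
    s_sorted = s_values[order]
    span = (0.0, max(float(s_sorted[-1]), 1e-12))
    cols = []
    for j in range(8):
        y0 = np.zeros(8, dtype=complex)
        y0[j] = 1.0
        sol = solve_ivp(
            rhs,
            span,
            np.concatenate([y0.real, y0.imag]),
            t_eval=np.clip(s_sorted, *span),
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"shooting integration failed: {sol.message}")
        cols.append(sol.y[:8] + 1j * sol.y[8:])
    basis = np.stack(cols, axis=1)  # (8 states, 8 columns, n_s)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    Phis = [basis[:7, :7, i] for i in inv]
    Ws = [basis[:7, 7, i] for i in inv]
    return Phis, Ws


def solve_dynamic_mode_shooting(
    params: MechanicalParams,
    resp: MotorResponse,
    s_grid: np.ndarray | None = None,
    n_grid: int = 201,
    sigma_tol: float = 1e-5,
) -> ModelSolution:
    """Shooting counterpart of :func:`axobeat.model.solve_dynamic_mode`."""
    if resp.chi_b is None:
        raise ValueError("resp.chi_b must be set")
    chi, _, _ = resp.effective()
    a, L = params.a, params.L
    if s_grid is None:
        s_grid = np.linspace(0.0, L, n_grid)
    s_grid = np.asarray(s_grid, dtype=float)

    (PhiL,), (WL,) = shooting_propagators(params, resp, [L])
    B = _boundary_matrix(params, resp, resp.chi_b, PhiL, WL)
    U, sv, Vh = np.linalg.svd(B)
    ratio = float(sv[-1] / sv[0])
    if ratio > sigma_tol:
        raise RuntimeError(
            f"no oscillatory solution at this chi_b (sigma ratio {ratio:.2e})"
        )
    z = Vh[-1].conj()
    y0, u, w = z[:7], z[7], z[8]
    D = chi * (u - a * w)

    Phis, Ws = shooting_propagators(params, resp, s_grid)
    Y = np.stack([P @ y0 + W * D for P, W in zip(Phis, Ws)])
    frow = _f_row(params, resp)
    f1 = Y @ frow + D
    psi1 = Y[:, 0]
    rms = np.sqrt(np.mean(np.abs(psi1) ** 2))
    g = 1.0 / rms if rms > 0 else 1.0
    ref = psi1[0] if abs(psi1[0]) > 1e-9 * np.abs(psi1).max() else psi1[
        int(np.argmax(np.abs(psi1)))
    ]
    if abs(ref) > 0:
        g = g * np.exp(-1j * np.angle(ref))
    Y, f1, u, w = Y * g, f1 * g, u * g, w * g
    psi1 = Y[:, 0]
    return ModelSolution(
        s=s_grid,
        psi1=psi1,
        psi1_prime=Y[:, 1],
        tau1=Y[:, 4],
        f1=f1,
        F1=Y[:, 6],
        f_perp1=normal_force_fundamental(params, Y[:, 6], Y[:, 1]),
        delta1=u + a * (psi1 - w),
        delta_b1=complex(u),
        chi_b=complex(resp.chi_b),
        sigma_ratio=ratio,
        params=params,
        resp=resp,
    )
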