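"""Planar two-filament axoneme model with motor feedback.

The axoneme is reduced to two inextensible filaments at constant spacing
``a``, bending rigidity ``kappa``, moving in a fluid with normal/tangential
drag coefficients ``xi_n``/``xi_t``.  Dynein motors exert a sliding force
density ``f(s, t)`` between the filaments.  About a static shape of constant
curvature ``C0``, the fundamental Fourier mode ``psi_1(s)`` of the tangent
angle and the mode ``tau_1(s)`` of the axial tension obey the coupled
constant-coefficient system (r = xi_n/xi_t, primes = d/ds)

    i w xi_n psi_1 = -kappa psi_1'''' + a f_1''
                     + (1 + r) C0 tau_1'
                     + r C0^2 (kappa psi_1'' - a f_1)

    r tau_1'' - C0^2 tau_1 = -(1 + r) C0 (kappa psi_1''' - a f_1')

of order six when C0 != 0 (four when the tension decouples at C0 = 0).  The
motor force responds to the local deformation,

    f_1 = chi * Delta_1 + beta * psi_1' + gamma * f_perp_1,

with sliding Delta_1 = Delta_b1 + a (psi_1 - psi_1(0)), linearized normal
force f_perp_1 = C0 (F_1 + kappa psi_1'/a), and integrated sliding force
F_1(s) = -int_s^L f_1 ds'.  For normal-force control, F_1 is promoted to an
explicit state with F_1' = f_1 and F_1(L) = 0, keeping the system local.

Boundary conditions (freely swimming axoneme: no external force or torque at
either end; viscoelastic basal compliance chi_b = k_b + i w xi_b restraining
basal sliding) are, at the fundamental mode,

    distal s = L:  psi_1' = 0,  -kappa psi_1'' + a f_1 = 0,  tau_1 = 0
    basal  s = 0:  kappa psi_1' = a F_1(0),  kappa psi_1'' - a f_1 = 0,
                   tau_1 = 0,  and  F_1(0) = chi_b * Delta_b1.

They follow from the boundary terms of the variational force balance; the
basal torque condition and sliding balance couple the mode to chi_b.  The
homogeneous boundary system has a nontrivial solution — the predicted beat,
a critical-point oscillation whose amplitude the linear theory leaves free —
exactly when its determinant vanishes.

The solver represents the general solution through the matrix-exponential
fundamental solution of the first-order system (states psi_1 ... psi_1''',
tau_1, tau_1', F_1): precisely the exponential basis of the characteristic
roots, uniformly valid at repeated roots.

Units: lengths μm, forces nN, time s; chi nN·μm⁻², beta nN, gamma
dimensionless, chi_b nN·μm⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import expm

from .errors import NoOscillatorySolutionError

__all__ = [
    "MechanicalParams",
    "MotorResponse",
    "ModelSolution",
    "StaticForce",
    "static_motor_force",
    "motor_force_fundamental",
    "normal_force_fundamental",
    "integrated_force",
    "characteristic_roots",
    "boundary_determinant",
    "boundary_sigma_ratio",
    "critical_basal_impedance",
    "solve_dynamic_mode",
]

VARIANTS = ("sliding", "curvature", "normal_force")


@dataclass(frozen=True)
class MechanicalParams:
    """Passive mechanical and geometric constants of one axoneme."""

    kappa: float      # bending rigidity, nN μm^2
    xi_n: float       # normal drag, nN s μm^-2
    xi_t: float       # tangential drag, nN s μm^-2
    a: float          # filament spacing, μm
    L: float          # length, μm
    omega: float      # beat angular frequency, rad/s
    C0: float = 0.0   # static curvature, μm^-1

    def __post_init__(self):
        for name in ("kappa", "xi_n", "xi_t", "a", "L", "omega"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def drag_ratio(self) -> float:
        return self.xi_n / self.xi_t

    def with_(self, **kw) -> "MechanicalParams":
        return replace(self, **kw)


@dataclass
class MotorResponse:
    """Complex motor response coefficients for one control variant.

    chi (nN μm^-2) couples to sliding, beta (nN) to curvature, gamma
    (dimensionless) to the normal force; chi_b = k_b + i w xi_b (nN μm^-1)
    is the basal impedance.
    """

    variant: str
    chi: complex = 0.0
    beta: complex = 0.0
    gamma: complex = 0.0
    chi_b: complex | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.validate()

    def validate(self):
        if self.variant == "sliding":
            if self.beta != 0 or self.gamma != 0:
                raise ValueError("sliding control requires beta = gamma = 0")
            if self.chi.real > 0 or self.chi.imag > 0:
                raise ValueError(
                    "sliding control is an active response: chi', chi'' <= 0"
                )
        elif self.variant == "curvature":
            if self.gamma != 0:
                raise ValueError("curvature control requires gamma = 0")
        elif self.variant == "normal_force":
            if self.beta != 0:
                raise ValueError("normal-force control requires beta = 0")

    def effective(self) -> tuple[complex, complex, complex]:
        """(chi, beta, gamma) with the variant's zeroed coefficients enforced."""
        chi = complex(self.chi)
        beta = complex(self.beta) if self.variant == "curvature" else 0.0
        gamma = complex(self.gamma) if self.variant == "normal_force" else 0.0
        return chi, beta, gamma

    @property
    def passive_base(self) -> bool:
        """True when the basal impedance is a passive spring-dashpot
        (k_b >= 0 and w xi_b >= 0)."""
        if self.chi_b is None:
            raise ValueError("chi_b not set")
        return self.chi_b.real >= 0 and self.chi_b.imag >= 0


@dataclass
class StaticForce:
    """Static motor force: a tip-concentrated point force of weight
    -kappa C0 / a (delta function at s = L) balancing the constant
    integrated force F0 = kappa C0 / a on [0, L)."""

    tip_weight: float
    F0: float

    def pair(self, test_fn) -> float:
        """Distributional pairing <f0, g> = tip_weight * g(L)."""
        return self.tip_weight * float(test_fn(self._L))

    _L: float = 0.0


def static_motor_force(params: MechanicalParams) -> StaticForce:
    """Static mode of the motor force for constant static curvature.

    Constant curvature requires arc-length-independent integrated force,
    hence force concentrated at the distal tip: f0 = -delta(s-L) kappa C0/a,
    so that kappa psi0' = a F0 with psi0' = C0 exactly.
    """
    w = -params.kappa * params.C0 / params.a
    sf = StaticForce(tip_weight=w, F0=-w)
    sf._L = params.L
    return sf


def motor_force_fundamental(resp: MotorResponse, delta1, psi1_dot, f_perp1=None):
    """Pointwise motor force density f_1 = chi Delta_1 + beta psi_1' + gamma f_perp_1."""
    chi, beta, gamma = resp.effective()
    delta1 = np.asarray(delta1, dtype=complex)
    psi1_dot = np.asarray(psi1_dot, dtype=complex)
    out = chi * delta1 + beta * psi1_dot
    if gamma != 0:
        if f_perp1 is None:
            raise ValueError("normal-force control requires f_perp1")
        out = out + gamma * np.asarray(f_perp1, dtype=complex)
    return out


def normal_force_fundamental(params: MechanicalParams, F1, psi1_dot):
    """Linearized fundamental normal force f_perp_1 = C0 (F_1 + kappa psi_1'/a).

    Uses the static balance a F0 = kappa C0; vanishes identically for
    symmetric beats (C0 = 0).
    """
    return params.C0 * (
        np.asarray(F1, dtype=complex)
        + params.kappa * np.asarray(psi1_dot, dtype=complex) / params.a
    )


def integrated_force(f1, s):
    """Integrated sliding force F_1(s) = -int_s^L f_1 ds' (tip value exactly 0)."""
    f1 = np.asarray(f1)
    s = np.asarray(s, dtype=float)
    I = cumulative_trapezoid(f1, s, initial=0.0)
    return I - I[-1]


# ---------------------------------------------------------------------------
# characteristic polynomial


def _conv(p, q):
    return np.convolve(np.asarray(p, dtype=complex), np.asarray(q, dtype=complex))


def _padd(p, q):
    """Add two ascending-coefficient polynomials of unequal length."""
    p = np.asarray(p, dtype=complex)
    q = np.asarray(q, dtype=complex)
    n = max(p.size, q.size)
    out = np.zeros(n, dtype=complex)
    out[: p.size] += p
    out[: q.size] += q
    return out


def _char_poly(params: MechanicalParams, resp: MotorResponse) -> np.ndarray:
    """Ascending coefficients of the characteristic polynomial in k for
    solutions ~ e^{ks} of the closed (motor law substituted) system."""
    chi, beta, gamma = resp.effective()
    kap, a, C0, w, xin = params.kappa, params.a, params.C0, params.omega, params.xi_n
    r = params.drag_ratio
    B2 = beta + gamma * C0 * kap / a
    Fpsi = np.array([chi * a, B2], dtype=complex)            # f on e^{ks}: Fpsi(k) P + gamma C0 G + D
    quartic = _padd(
        np.array([-1j * w * xin, 0, 0, 0, -kap], dtype=complex),
        a * _conv([0, 0, 1], Fpsi),
    )
    if C0 == 0:
        poly = quartic
        if gamma != 0:
            poly = _conv(poly, [-gamma * C0, 1])  # extra F-state root at gamma*C0
        return poly
    A1 = np.array([-1j * w * xin, 0, r * kap * C0**2, 0, -kap], dtype=complex)
    Q = np.array([-r * C0**2, 0, 1], dtype=complex)
    E1P = _padd(A1, a * _conv(Q, Fpsi))
    E1T = np.array([0, (1 + r) * C0], dtype=complex)
    E2P = _conv([0, (1 + r) * C0], np.array([-a * chi * a, -a * B2, kap], dtype=complex))
    E2T = np.array([-C0**2, 0, r], dtype=complex)
    C33 = _padd(_conv(E1P, E2T), -_conv(E1T, E2P))
    if gamma == 0:
        return C33
    E1G = a * gamma * C0 * Q
    E2G = np.array([0, -(1 + r) * C0**2 * gamma * a], dtype=complex)
    E3P = -Fpsi
    E3G = np.array([-gamma * C0, 1], dtype=complex)
    C31 = _padd(_conv(E1T, E2G), -_conv(E1G, E2T))
    return _padd(_conv(E3P, C31), _conv(E3G, C33))


def characteristic_roots(
    params: MechanicalParams, resp: MotorResponse, tol: float = 1e-8
) -> np.ndarray:
    """All complex roots k of the characteristic polynomial.

    System order: 6 for C0 != 0 (psi and tau coupled), 4 for C0 = 0, plus one
    when the integrated force is an explicit state (normal-force control).
    Numerically repeated roots are flagged with a warning; the BVP solver's
    fundamental-matrix basis remains valid there.
    """
    poly = _char_poly(params, resp)
    poly = np.trim_zeros(poly, "b")
    roots = np.roots(poly[::-1])
    if roots.size:
        scale = np.abs(roots).max()
        for i in range(roots.size):
            for j in range(i + 1, roots.size):
                if abs(roots[i] - roots[j]) < tol * max(scale, 1.0):
                    warnings.warn(
                        "numerically repeated characteristic roots "
                        f"(|k_i - k_j| < {tol} * max|k|)",
                        stacklevel=2,
                    )
                    break
            else:
                continue
            break
    return roots


# ---------------------------------------------------------------------------
# boundary-value solve


def _system_matrices(params: MechanicalParams, resp: MotorResponse):
    """First-order form y' = M y + d D of the fundamental-mode equations.

    State y = (psi, psi', psi'', psi''', tau, tau', F); D = chi (Delta_b1 -
    a psi_1(0)) is the constant part of the sliding force.
    """
    chi, beta, gamma = resp.effective()
    kap, a, C0, w = params.kappa, params.a, params.C0, params.omega
    xin = params.xi_n
    r = params.drag_ratio
    B2 = beta + gamma * C0 * kap / a
    gC0 = gamma * C0

    def rhs(y, D):
        f = chi * a * y[0] + B2 * y[1] + gC0 * y[6] + D
        fp = chi * a * y[1] + B2 * y[2] + gC0 * f
        fpp = chi * a * y[2] + B2 * y[3] + gC0 * fp
        psi4 = (
            -1j * w * xin * y[0]
            + a * fpp
            + (1 + r) * C0 * y[5]
            + r * C0**2 * (kap * y[2] - a * f)
        ) / kap
        tau2 = (C0**2 * y[4] - (1 + r) * C0 * (kap * y[3] - a * fp)) / r
        return np.array([y[1], y[2], y[3], psi4, y[5], tau2, f], dtype=complex)

    M = np.empty((7, 7), dtype=complex)
    zero = np.zeros(7, dtype=complex)
    for j in range(7):
        e = np.zeros(7, dtype=complex)
        e[j] = 1.0
        M[:, j] = rhs(e, 0.0)
    d = rhs(zero, 1.0)
    return M, d


def _propagators(params, resp, s_values):
    """Phi(s), W(s) with y(s) = Phi(s) y(0) + W(s) D, via the augmented
    matrix exponential (exact for constant coefficients)."""
    M, d = _system_matrices(params, resp)
    aug = np.zeros((8, 8), dtype=complex)
    aug[:7, :7] = M
    aug[:7, 7] = d
    Phis, Ws = [], []
    for s in np.atleast_1d(s_values):
        E = expm(aug * s)
        Phis.append(E[:7, :7])
        Ws.append(E[:7, 7])
    return Phis, Ws


def _f_row(params, resp):
    """Row vector r with f_1 = r . y + D at a point."""
    chi, beta, gamma = resp.effective()
    row = np.zeros(7, dtype=complex)
    row[0] = chi * params.a
    row[1] = beta + gamma * params.C0 * params.kappa / params.a
    row[6] = gamma * params.C0
    return row


def _boundary_matrix(params, resp, chi_b, PhiL, WL) -> np.ndarray:
    """9x9 homogeneous boundary system B z = 0 on z = (y(0), Delta_b1, psi_1(0)).

    Rows: distal curvature, distal transverse force, distal tension, basal
    torque balance, basal transverse force, basal tension, F_1(L) = 0, basal
    sliding balance F_1(0) = chi_b Delta_b1, and the self-consistency
    psi_1(0) = w.
    """
    chi, _, _ = resp.effective()
    kap, a = params.kappa, params.a
    frow = _f_row(params, resp)
    B = np.zeros((9, 9), dtype=complex)

    def distal(row_vec, extra_D=0.0):
        """Row acting on y(L) (+ extra_D * D): expressed on (y0, u, w)."""
        row = np.zeros(9, dtype=complex)
        row[:7] = row_vec @ PhiL
        dcoef = row_vec @ WL + extra_D
        row[7] += chi * dcoef          # D = chi * (u - a w)
        row[8] += -chi * a * dcoef
        return row

    e = np.eye(7, dtype=complex)
    # distal: zero curvature, zero transverse force, zero tension
    B[0] = distal(e[1])
    B[1] = distal(-kap * e[2] + a * frow, extra_D=a)
    B[2] = distal(e[4])
    # basal: torque balance through the basal impedance
    B[3, :7] = kap * e[1]
    B[3, 7] = -a * chi_b
    # basal transverse force
    B[4, :7] = kap * e[2] - a * frow
    B[4, 7] = -a * chi
    B[4, 8] = a * chi * a
    # basal tension
    B[5, :7] = e[4]
    # F_1(L) = 0 pins the integrated-force state
    B[6] = distal(e[6])
    # basal sliding balance
    B[7, :7] = e[6]
    B[7, 7] = -chi_b
    # psi_1(0) self-consistency
    B[8, 0] = 1.0
    B[8, 8] = -1.0
    return B


def boundary_determinant(
    params: MechanicalParams, resp: MotorResponse, chi_b: complex
) -> complex:
    """Determinant of the boundary system as an analytic (affine) function
    of the basal impedance chi_b."""
    (PhiL,), (WL,) = _propagators(params, resp, [params.L])
    B = _boundary_matrix(params, resp, chi_b, PhiL, WL)
    return complex(np.linalg.det(B))


def boundary_sigma_ratio(params, resp, chi_b) -> float:
    """sigma_min / sigma_max of the boundary matrix: a scale-free measure of
    how close the system is to admitting a nontrivial mode."""
    (PhiL,), (WL,) = _propagators(params, resp, [params.L])
    B = _boundary_matrix(params, resp, chi_b, PhiL, WL)
    sv = np.linalg.svd(B, compute_uv=False)
    return float(sv[-1] / sv[0])


def critical_basal_impedance(
    params: MechanicalParams, resp: MotorResponse
) -> complex:
    """The basal impedance chi_b at which the boundary determinant vanishes.

    chi_b enters only the basal-sliding column of the boundary system, so the
    determinant is affine in chi_b and the critical value is the root of a
    linear equation — unique and obtained in closed form from two determinant
    evaluations.
    """
    (PhiL,), (WL,) = _propagators(params, resp, [params.L])
    d0 = np.linalg.det(_boundary_matrix(params, resp, 0.0, PhiL, WL))
    d1 = np.linalg.det(_boundary_matrix(params, resp, 1.0, PhiL, WL))
    slope = d1 - d0
    if not np.isfinite(slope) or abs(slope) <= 1e-300 or abs(slope) < 1e-14 * abs(d0):
        raise NoOscillatorySolutionError(
            "no critical basal impedance: determinant does not depend on chi_b",
            det_abs=abs(d0),
        )
    chi_b = -d0 / slope
    if not np.isfinite(chi_b):
        raise NoOscillatorySolutionError(
            "no critical basal impedance found", det_abs=abs(d0)
        )
    # reject the trivial null mode (psi_1 = 0, free basal sliding), which
    # arises when the motor force does not couple to sliding (chi' = chi'' = 0)
    B = _boundary_matrix(params, resp, chi_b, PhiL, WL)
    _, _, Vh = np.linalg.svd(B)
    z = Vh[-1]
    deform = np.linalg.norm(z[:7]) + abs(z[8])
    if deform < 1e-10 * np.linalg.norm(z):
        raise NoOscillatorySolutionError(
            "no critical basal impedance: only the trivial (psi_1 = 0) mode "
            "exists there",
            det_abs=abs(d0),
        )
    return complex(chi_b)


@dataclass
class ModelSolution:
    """Critical oscillatory mode of the boundary-value problem.

    Fields are complex fundamental-mode profiles on ``s``; the amplitude
    gauge is rms|psi_1| = 1 over the grid with psi_1(0) real and
    non-negative (the linear problem fixes shape, not amplitude).
    """

    s: np.ndarray
    psi1: np.ndarray
    psi1_prime: np.ndarray
    tau1: np.ndarray
    f1: np.ndarray
    F1: np.ndarray
    f_perp1: np.ndarray
    delta1: np.ndarray
    delta_b1: complex
    chi_b: complex
    sigma_ratio: float
    params: MechanicalParams = None
    resp: MotorResponse = None
    meta: dict = field(default_factory=dict)


def solve_dynamic_mode(
    params: MechanicalParams,
    resp: MotorResponse,
    s_grid: np.ndarray | None = None,
    n_grid: int = 201,
    sigma_tol: float = 1e-6,
) -> ModelSolution:
    """Solve the fundamental-mode boundary-value problem at resp.chi_b.

    A nontrivial mode exists only where the boundary determinant vanishes
    (use :func:`critical_basal_impedance` to close chi_b); otherwise a
    :class:`NoOscillatorySolutionError` reports |det|.
    """
    if resp.chi_b is None:
        raise ValueError("resp.chi_b must be set (see critical_basal_impedance)")
    chi, _, _ = resp.effective()
    a, L = params.a, params.L
    if s_grid is None:
        s_grid = np.linspace(0.0, L, n_grid)
    s_grid = np.asarray(s_grid, dtype=float)

    (PhiL,), (WL,) = _propagators(params, resp, [L])
    B = _boundary_matrix(params, resp, resp.chi_b, PhiL, WL)
    U, sv, Vh = np.linalg.svd(B)
    ratio = float(sv[-1] / sv[0])
    if ratio > sigma_tol:
        det = complex(np.linalg.det(B))
        raise NoOscillatorySolutionError(
            f"no oscillatory solution at this chi_b (|det| = {abs(det):.3e}, "
            f"sigma_min/sigma_max = {ratio:.3e})",
            det_abs=abs(det),
        )
    z = Vh[-1].conj()
    if np.linalg.norm(z[:7]) + abs(z[8]) < 1e-10 * np.linalg.norm(z):
        raise NoOscillatorySolutionError(
            "only the trivial (psi_1 = 0) mode exists at this chi_b"
        )
    y0, u, w = z[:7], z[7], z[8]
    D = chi * (u - a * w)

    Phis, Ws = _propagators(params, resp, s_grid)
    Y = np.stack([P @ y0 + W * D for P, W in zip(Phis, Ws)])
    frow = _f_row(params, resp)
    f1 = Y @ frow + D
    psi1 = Y[:, 0]
    # amplitude gauge: unit rms |psi_1|, basal value real and non-negative
    rms = np.sqrt(np.mean(np.abs(psi1) ** 2))
    g = 1.0 / rms if rms > 0 else 1.0
    ref = psi1[0] if abs(psi1[0]) > 1e-9 * np.abs(psi1).max() else psi1[
        int(np.argmax(np.abs(psi1)))
    ]
    if abs(ref) > 0:
        g = g * np.exp(-1j * np.angle(ref))
    Y = Y * g
    f1 = f1 * g
    u = u * g
    w = w * g

    psi1 = Y[:, 0]
    F1 = Y[:, 6]
    f_perp1 = normal_force_fundamental(params, F1, Y[:, 1])
    delta1 = u + a * (psi1 - w)
    return ModelSolution(
        s=s_grid,
        psi1=psi1,
        psi1_prime=Y[:, 1],
        tau1=Y[:, 4],
        f1=f1,
        F1=F1,
        f_perp1=f_perp1,
        delta1=delta1,
        delta_b1=complex(u),
        chi_b=complex(resp.chi_b),
        sigma_ratio=ratio,
        params=params,
        resp=resp,
    )
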