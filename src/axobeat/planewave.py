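"""Closed-form plane-wave diagnostics.

In the plane-wave approximation psi_1(s) = exp(-2 pi i s / lambda) (wavelength
lambda positive for base-to-tip propagation), the model reduces to algebraic
dispersion relations.  These give the critical length below which sliding
control cannot propagate waves, the viscous/elastic dissipation ratio that
places *Chlamydomonas* far from Machin's efficiency optimum, and the phase
relations (compass bearings) between sliding, curvature, normal force and
motor force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MechanicalParams, ModelSolution

__all__ = [
    "critical_length",
    "sliding_dispersion",
    "curvature_dispersion",
    "solve_curvature_beta",
    "dissipation_ratio",
    "asymmetry_term_ratio",
    "PhaseBearings",
    "phase_bearings",
    "plane_wave_bearings",
]


def critical_length(params: MechanicalParams) -> float:
    """l = 2 pi (kappa / (xi_n omega))^(1/4), μm.

    Axonemes much shorter than l support only standing waves under sliding
    control; the quarter-power makes l robust to parameter uncertainty.
    """
    return float(2 * np.pi * (params.kappa / (params.xi_n * params.omega)) ** 0.25)


def sliding_dispersion(params: MechanicalParams, chi: complex) -> np.ndarray:
    """Wavelengths solving the sliding-control plane-wave dispersion relation

        i omega xi_n / kappa = -(2 pi/lambda)^4 - (2 pi/lambda)^2 a^2 chi/kappa.

    Returns all (generally complex) signed wavelengths; the set is invariant
    under lambda -> -lambda.
    """
    kap, a = params.kappa, params.a
    # quartic in q = 2 pi / lambda: q^4 + (a^2 chi / kappa) q^2 + i w xi_n/kappa = 0
    coeffs = [1.0, 0.0, a**2 * chi / kap, 0.0, 1j * params.omega * params.xi_n / kap]
    q = np.roots(coeffs)
    return 2 * np.pi / q


def curvature_dispersion(
    params: MechanicalParams, chi: complex, beta: complex, lam: float
) -> tuple[float, float]:
    """Residuals of the two real plane-wave balances for curvature control
    of a symmetric beat (C0 = 0):

        xi_n omega + a^2 chi'' q^2 - a beta' q^3      (viscous balance)
        kappa q^4 + a^2 chi' q^2 + a beta'' q^3       (elastic balance)

    with q = 2 pi / lambda.
    """
    q = 2 * np.pi / lam
    a = params.a
    r1 = params.xi_n * params.omega + a**2 * chi.imag * q**2 - a * beta.real * q**3
    r2 = params.kappa * q**4 + a**2 * chi.real * q**2 + a * beta.imag * q**3
    return float(r1), float(r2)


def solve_curvature_beta(
    params: MechanicalParams, chi: complex, lam: float
) -> complex:
    """beta = beta' + i beta'' zeroing both plane-wave balances at given
    chi and wavelength."""
    q = 2 * np.pi / lam
    a = params.a
    bp = (params.xi_n * params.omega + a**2 * chi.imag * q**2) / (a * q**3)
    bpp = -(params.kappa * q**4 + a**2 * chi.real * q**2) / (a * q**3)
    return complex(bp, bpp)


def dissipation_ratio(L: float, ell: float) -> float:
    """Viscous-to-elastic dissipation ratio (pi/2) (L/l)^4 for a plane wave.

    Much less than 1 for *Chlamydomonas* (short axoneme): elastic dissipation
    dominates, so the beat operates far from the viscous-optimum phase.
    """
    if not ell > 0:
        raise ValueError("critical length must be positive")
    return float(np.pi / 2 * (L / ell) ** 4)


def asymmetry_term_ratio(params: MechanicalParams, lam: float) -> float:
    """Ratio of the C0^2 static-curvature coupling term to the bending term
    in the dynamic-mode equation: (xi_n/xi_t) C0^2 / (2 pi/lambda)^2.

    ~0.5 for wild-type Chlamydomonas (C0 ~ pi/L, lambda ~ L): the asymmetry
    coupling cannot be neglected a priori.
    """
    if lam == 0:
        raise ValueError("wavelength must be nonzero")
    q = 2 * np.pi / lam
    return float(params.drag_ratio * params.C0**2 / q**2)


@dataclass
class PhaseBearings:
    """Arc-averaged phases (radians, relative to sliding Delta).

    Compass convention: E = 0 (in phase with sliding), N = +pi/2 (quarter
    cycle ahead), S = -pi/2 (quarter behind), W = +-pi (anti-phase).  For an
    exact base-to-tip plane wave a time derivative advances the phase by
    pi/2 (N) and an arc-length derivative delays it by pi/2 (S).
    """

    delta: float
    curvature: float
    motor_force: float
    sliding_velocity: float
    normal_force: float | None = None

    @staticmethod
    def compass(phase: float) -> str:
        labels = ["E", "NE", "N", "NW", "W", "SW", "S", "SE"]
        idx = int(np.round(((phase + 2 * np.pi) % (2 * np.pi)) / (np.pi / 4))) % 8
        return labels[idx]


def _rel_phase(x: np.ndarray, ref: np.ndarray, weight: np.ndarray, s: np.ndarray) -> float:
    """|psi_1|^2-weighted arc-average of arg(x) - arg(ref)."""
    prod = x * np.conj(ref)
    mag = np.abs(prod)
    safe = np.where(mag > 0, mag, 1.0)
    z = np.trapezoid(weight * prod / safe, s)
    return float(np.angle(z))


def phase_bearings(solution: ModelSolution) -> PhaseBearings:
    """Phase relations of a model solution, weighted by |psi_1|^2.

    Reference is the sliding displacement Delta_1 (bearing E).
    """
    if np.all(np.abs(solution.delta1) == 0):
        raise ValueError("vanishing sliding amplitude: no phase reference")
    wgt = np.abs(solution.psi1) ** 2
    s = solution.s
    d = solution.delta1
    return PhaseBearings(
        delta=0.0,
        curvature=_rel_phase(solution.psi1_prime, d, wgt, s),
        motor_force=_rel_phase(solution.f1, d, wgt, s),
        sliding_velocity=_rel_phase(1j * solution.params.omega * d, d, wgt, s),
        normal_force=_rel_phase(solution.f_perp1, d, wgt, s)
        if np.any(np.abs(solution.f_perp1) > 0)
        else None,
    )


def plane_wave_bearings(
    params: MechanicalParams, chi: complex, beta: complex, lam: float
) -> PhaseBearings:
    """Exact plane-wave phase relations for psi_1 = e^{-i q s}, q = 2 pi/lam.

    Sliding Delta = a psi (basal sliding neglected); curvature psi' = -i q psi
    (bearing S for lam > 0); motor force f = (a chi - i q beta) psi.
    """
    q = 2 * np.pi / lam
    f_coef = params.a * chi + beta * (-1j * q)
    return PhaseBearings(
        delta=0.0,
        curvature=float(np.angle(-1j * q)),
        motor_force=float(np.angle(f_coef)),
        sliding_velocity=float(np.angle(1j)),
    )
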