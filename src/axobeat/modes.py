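"""Fourier-mode decomposition of the beat.

A beating axoneme's tangent angle is periodic at the beat frequency and is
expanded as

    psi(s, t) = psi_0(s) + sum_{n >= 1} sqrt(2) * Re[ psi_n(s) e^{i n w t} ]

after removal of a slow rigid-body rotation ``w_rot * t`` (isolated axonemes
circle slowly while they beat).  ``psi_0`` is the time-averaged (static)
shape — close to a constant-curvature arc — and ``psi_1`` is the complex
fundamental mode whose amplitude and phase profile describe the traveling
bending wave.

Amplitude convention
--------------------
``psi_n`` is sqrt(2) times the complex Fourier coefficient of ``e^{i n w t}``,
so ``|psi_n(s)|`` equals the root-mean-square oscillation amplitude at ``s``.
Under this convention the measured fundamental amplitude of wild-type
*Chlamydomonas* axonemes is |psi_1| ~ 0.68 rad and the normalized bend
propagation speed

    v = int_0^L |psi_1|^2 d(arg psi_1)/ds ds

is ~ 3 in magnitude.  With the ``e^{+i w t}`` time convention a base-to-tip
traveling wave has d(arg psi_1)/ds < 0, i.e. v < 0; magnitudes are reported
where only speed matters, and the signed wavelength
``lambda = -2*pi / <d(arg psi_1)/ds>`` is positive for base-to-tip waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import NoPeriodicBeatError
from .geometry import TangentAngleSeries, angles_to_centerline

__all__ = [
    "ModalDecomposition",
    "BeatDescriptors",
    "StaticCurvature",
    "estimate_rotation",
    "decompose",
    "power_fraction",
    "static_curvature",
    "wave_speed",
    "wavelength",
    "reconstruct_shapes",
    "hexadecimation_sem",
    "describe",
]

N_HARMONICS = 4  # n = 1..4 reported; higher harmonics lumped into the residual


@dataclass
class ModalDecomposition:
    """Static and oscillatory Fourier modes of a tangent-angle series."""

    arc_positions: np.ndarray
    psi0: np.ndarray                 # static mode, radians
    harmonics: np.ndarray            # (N_HARMONICS, S) complex, rms convention
    omega: float                     # beat angular frequency, rad/s
    omega_rot: float                 # rigid rotation rate, rad/s
    power_fractions: np.ndarray      # share of dynamic power, n = 1..N_HARMONICS
    length_L: float
    n_frames_used: int = 0
    n_periods: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def psi1(self) -> np.ndarray:
        return self.harmonics[0]

    @property
    def residual_fraction(self) -> float:
        return float(max(0.0, 1.0 - self.power_fractions.sum()))


@dataclass
class StaticCurvature:
    """Least-squares constant curvature of the static mode plus residuals."""

    C0: float
    residuals: np.ndarray

    def __float__(self):
        return self.C0


@dataclass
class BeatDescriptors:
    C0: float
    v: float
    wavelength_lambda: float
    sem_psi0: np.ndarray | None = None
    sem_psi1: np.ndarray | None = None


def _mean_angle_signal(series: TangentAngleSeries) -> np.ndarray:
    return series.psi.mean(axis=1)


def estimate_rotation(series: TangentAngleSeries) -> float:
    """Rigid rotation rate (rad/s): least-squares slope of the arc-averaged
    unwrapped angle against time.

    Emits a warning (and still returns the slope) when the record appears to
    span fewer than two beat periods.
    """
    m = _mean_angle_signal(series)
    t = series.times
    slope = np.polyfit(t, m, 1)[0]
    # best-effort record-length check against the dominant spectral period
    resid = m - np.polyval(np.polyfit(t, m, 1), t)
    spec = np.abs(np.fft.rfft(resid))
    if spec.size > 2:
        k = int(np.argmax(spec[1:])) + 1
        if spec[k] > 0 and k < 2:
            warnings.warn(
                "series appears to span fewer than 2 beat periods; "
                "rotation estimate may be unreliable",
                stacklevel=2,
            )
    return float(slope)


def _refine_peak(mag: np.ndarray, k: int) -> float:
    """Parabolic interpolation of a spectral peak; returns fractional bin."""
    if k <= 0 or k >= mag.size - 1:
        return float(k)
    a, b, c = mag[k - 1], mag[k], mag[k + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(k)
    delta = 0.5 * (a - c) / denom
    # offsets below the leakage resolution are noise: keep the bin exact
    if abs(delta) < 1e-4:
        delta = 0.0
    return k + float(np.clip(delta, -0.5, 0.5))


def _find_beat_frequency(signal: np.ndarray, frame_rate: float) -> float:
    """Beat angular frequency from the largest non-DC periodogram peak,
    parabolic-refined, then polished by maximizing the projection power."""
    x = signal - signal.mean()
    n = x.size
    spec = np.abs(np.fft.rfft(x))
    if spec.size < 3:
        raise NoPeriodicBeatError("record too short for spectral analysis")
    body = spec[1:]
    k = int(np.argmax(body)) + 1
    floor = np.median(body)
    if not (spec[k] > 0) or (floor > 0 and spec[k] < 20 * floor):
        raise NoPeriodicBeatError(
            "no spectral peak above the noise floor: no periodic beat"
        )
    # subharmonic tie-break: two peaks within 1% in power -> lower frequency
    from scipy.signal import argrelmax

    (peaks,) = argrelmax(spec, order=2)
    peaks = peaks[peaks > 0]
    if peaks.size >= 2:
        order = np.argsort(spec[peaks])[::-1]
        top, second = peaks[order[0]], peaks[order[1]]
        if (spec[top] - spec[second]) / spec[top] < 0.01 and second != top:
            lower = min(top, second)
            if lower != k:
                warnings.warn(
                    "two spectral peaks within 1%; choosing the lower frequency",
                    stacklevel=3,
                )
                k = int(lower)
    kf = _refine_peak(spec, k)
    omega = 2 * np.pi * kf * frame_rate / n
    if kf != float(k):
        # polish on the continuous periodogram within +/- 1 bin
        t = np.arange(n) / frame_rate
        dw = 2 * np.pi * frame_rate / n

        def negpower(w):
            return -np.abs(np.sum(x * np.exp(-1j * w * t))) ** 2

        res = minimize_scalar(
            negpower,
            bounds=(omega - dw, omega + dw),
            method="bounded",
            options={"xatol": dw * 1e-10},
        )
        omega = float(res.x)
    # phase-slope polish: the phase drift of the projection between the two
    # halves of an integer-period window measures the residual frequency
    # error; iterating drives it to machine precision on clean records
    t = np.arange(n) / frame_rate
    for _ in range(3):
        period = 2 * np.pi * frame_rate / omega
        m = int(round(np.floor(n / (2 * period) + 1e-9) * period))
        m = min(m, n // 2)
        if m < 8:
            break
        ph1 = np.exp(-1j * omega * t[:m])
        c1 = ph1 @ x[:m]
        c2 = ph1 @ x[m : 2 * m] * np.exp(-1j * omega * t[m])
        if abs(c1) == 0 or abs(c2) == 0:
            break
        domega = float(np.angle(c2 * np.conj(c1))) / (m / frame_rate)
        omega += domega
        if abs(domega) < 1e-12 * omega:
            break
    return float(omega)


def _refined_rotation(series: TangentAngleSeries, omega: float, n_use: int) -> float:
    """Rotation rate by joint regression of the arc-averaged angle on
    {1, t, cos(wt), sin(wt)} over the projection window.

    The plain least-squares slope is biased by the residual beat oscillation
    of a finite record; including the beat sinusoid as a covariate removes
    that bias (exactly, for noiseless periodic input).
    """
    t = series.times[:n_use]
    m = _mean_angle_signal(series)[:n_use]
    X = np.column_stack(
        [np.ones_like(t), t, np.cos(omega * t), np.sin(omega * t)]
    )
    coef, *_ = np.linalg.lstsq(X, m, rcond=None)
    return float(coef[1])


def decompose(
    series: TangentAngleSeries,
    remove_rotation: bool = True,
    phase_gauge: bool = True,
    omega: float | None = None,
) -> ModalDecomposition:
    """Extract the static mode, harmonics n = 1..4 and the beat frequency.

    The rotation rate is estimated and subtracted first (matching the order
    of operations used on tracked data), the beat frequency is located on the
    arc-length-averaged power spectrum, and modes are computed by projection
    onto ``e^{i n w t}`` over the largest whole number of beat periods.

    ``phase_gauge=True`` applies the deterministic phase convention (psi_1 at
    the base real and non-negative, implemented as a time-origin shift so all
    harmonics stay consistent).  With the gauge off, a time shift of the
    input multiplies ``psi_n`` by ``e^{i n w dt}`` (equivariance).
    """
    omega_rot = estimate_rotation(series) if remove_rotation else 0.0
    t = series.times
    psi = series.psi - omega_rot * t[:, None]

    dyn = psi - psi.mean(axis=0, keepdims=True)
    total_var = float(np.mean(dyn**2))
    if total_var < 1e-20:
        # exactly static input: all oscillatory power is zero by construction
        S = series.arc_positions.size
        return ModalDecomposition(
            series.arc_positions.copy(),
            psi.mean(axis=0),
            np.zeros((N_HARMONICS, S), dtype=complex),
            float("nan"),
            omega_rot,
            np.zeros(N_HARMONICS),
            series.length_L,
            n_frames_used=series.n_frames,
        )

    if omega is None:
        omega = _find_beat_frequency(dyn.mean(axis=1), series.frame_rate)
    period_frames = 2 * np.pi * series.frame_rate / omega
    n_periods = int(series.n_frames / period_frames)
    if n_periods < 1:
        raise NoPeriodicBeatError("record shorter than one beat period")
    n_use = int(round(n_periods * period_frames))
    n_use = min(n_use, series.n_frames)

    if remove_rotation:
        # unbiased slope once the beat frequency is known
        omega_rot = _refined_rotation(series, omega, n_use)
        psi = series.psi - omega_rot * t[:, None]

    tw = t[:n_use]
    w = psi[:n_use]
    psi0 = w.mean(axis=0)
    dynw = w - psi0
    phases = np.exp(-1j * np.outer(np.arange(1, N_HARMONICS + 1) * omega, tw))
    coeffs = phases @ dynw / n_use                # (N_HARMONICS, S)
    harmonics = np.sqrt(2.0) * coeffs

    var = float(np.mean(dynw**2))
    powers = np.mean(np.abs(harmonics) ** 2, axis=1)  # = 2 <|c_n|^2>_s
    fractions = powers / var if var > 0 else np.zeros(N_HARMONICS)

    if phase_gauge:
        ref = harmonics[0, 0]
        if abs(ref) < 1e-12 * (np.abs(harmonics[0]).max() + 1e-300):
            ref = harmonics[0, np.argmax(np.abs(harmonics[0]))]
        if abs(ref) > 0:
            theta = np.angle(ref)
            rot = np.exp(-1j * theta * np.arange(1, N_HARMONICS + 1))
            harmonics = harmonics * rot[:, None]

    return ModalDecomposition(
        series.arc_positions.copy(),
        psi0,
        harmonics,
        float(omega),
        float(omega_rot),
        fractions,
        series.length_L,
        n_frames_used=n_use,
        n_periods=n_periods,
    )


def power_fraction(decomp: ModalDecomposition, n: int) -> float:
    """Share of the total dynamic power carried by harmonic ``n``."""
    if n == 0:
        raise ValueError("the static mode carries no dynamic power")
    if not 1 <= n <= N_HARMONICS:
        raise ValueError(f"harmonic index must be in 1..{N_HARMONICS}")
    return float(decomp.power_fractions[n - 1])


def static_curvature(decomp: ModalDecomposition) -> StaticCurvature:
    """Constant static curvature C0: least-squares slope of psi_0(s)."""
    s = decomp.arc_positions
    A = np.column_stack([s, np.ones_like(s)])
    coef, *_ = np.linalg.lstsq(A, decomp.psi0, rcond=None)
    resid = decomp.psi0 - A @ coef
    return StaticCurvature(float(coef[0]), resid)


def _phase_slope_integrand(psi1: np.ndarray, s: np.ndarray) -> np.ndarray:
    """|psi1|^2 d(arg psi1)/ds computed as Im(psi1* dpsi1/ds).

    The identity avoids explicit unwrapping and is exactly zero for standing
    waves (real mode up to a global phase), including at their nodes.
    """
    dpsi = np.gradient(psi1, s)
    return np.imag(np.conj(psi1) * dpsi)


def _check_phase_sampling(psi1: np.ndarray) -> None:
    amp = np.abs(psi1)
    scale = np.sqrt(np.mean(amp**2))
    d = np.diff(np.angle(psi1))
    wrapped = (d + np.pi) % (2 * np.pi) - np.pi
    bad = (np.abs(wrapped) > 0.95 * np.pi) & (
        np.minimum(amp[:-1], amp[1:]) > 0.3 * scale
    )
    if np.any(bad):
        idx = int(np.argwhere(bad)[0][0])
        raise ValueError(
            f"phase unwrap failure: jump near pi between samples {idx} and "
            f"{idx + 1} at non-negligible amplitude (grid too coarse)"
        )


def wave_speed(psi1_or_decomp, arc_positions=None) -> float:
    """Normalized bend propagation speed v = ∫ |psi1|^2 ∂s(arg psi1) ds.

    Signed: negative for base-to-tip propagation under the e^{+iwt}
    convention.  Accepts a ModalDecomposition or (psi1, arc_positions).
    """
    if isinstance(psi1_or_decomp, ModalDecomposition):
        psi1 = psi1_or_decomp.psi1
        s = psi1_or_decomp.arc_positions
    else:
        psi1 = np.asarray(psi1_or_decomp)
        s = np.asarray(arc_positions)
    if np.all(np.abs(psi1) == 0):
        return 0.0
    _check_phase_sampling(psi1)
    return float(np.trapezoid(_phase_slope_integrand(psi1, s), s))


def wavelength(psi1_or_decomp, arc_positions=None) -> float:
    """Signed wavelength from the amplitude-weighted mean phase slope;
    positive means base-to-tip propagation."""
    if isinstance(psi1_or_decomp, ModalDecomposition):
        psi1, s = psi1_or_decomp.psi1, psi1_or_decomp.arc_positions
    else:
        psi1, s = np.asarray(psi1_or_decomp), np.asarray(arc_positions)
    num = np.trapezoid(_phase_slope_integrand(psi1, s), s)
    den = np.trapezoid(np.abs(psi1) ** 2, s)
    if den == 0 or num == 0:
        return float("inf")
    return float(-2 * np.pi * den / num)


def reconstruct_shapes(
    decomp: ModalDecomposition,
    modes: set = frozenset({0, 1}),
    phases=None,
    origin=(0.0, 0.0),
):
    """xy shapes over one beat cycle from a subset of modes.

    Returns ``(angles, shapes)`` with shapes of shape (n_phases, S, 2).
    """
    if phases is None:
        phases = np.linspace(0.0, 2 * np.pi, 16, endpoint=False)
    phases = np.atleast_1d(np.asarray(phases, dtype=float))
    S = decomp.arc_positions.size
    ang = np.zeros((phases.size, S))
    if 0 in modes:
        ang += decomp.psi0[None, :]
    for n in range(1, N_HARMONICS + 1):
        if n in modes:
            ang += np.sqrt(2.0) * np.real(
                decomp.harmonics[n - 1][None, :]
                * np.exp(1j * n * phases)[:, None]
            )
    shapes = np.stack(
        [
            angles_to_centerline(a, origin=origin, arc_positions=decomp.arc_positions)
            for a in ang
        ]
    )
    return ang, shapes


def hexadecimation_sem(series: TangentAngleSeries, n_blocks: int = 16):
    """Standard errors of psi_0 and psi_1 by block decimation.

    The record is split into ``n_blocks`` contiguous blocks of whole beat
    periods; each block is decomposed at the globally refined frequency
    (projections use absolute time, so block phases are directly comparable)
    and the SEM over blocks is reported per arc position.

    Returns ``(sem_psi0, sem_psi1)``; ``sem_psi1`` combines the real and
    imaginary scatter: sqrt(Var Re + Var Im) / sqrt(n_blocks).
    """
    omega_rot = estimate_rotation(series)
    t = series.times
    psi = series.psi - omega_rot * t[:, None]
    dyn = psi - psi.mean(axis=0, keepdims=True)
    omega = _find_beat_frequency(dyn.mean(axis=1), series.frame_rate)
    omega_rot = _refined_rotation(series, omega, series.n_frames)
    psi = series.psi - omega_rot * t[:, None]
    period_frames = 2 * np.pi * series.frame_rate / omega
    per_block = int(series.n_frames / period_frames / n_blocks)
    if per_block < 1:
        raise ValueError(
            f"record holds fewer than {n_blocks} whole beat cycles; "
            "reduce n_blocks"
        )
    m = int(round(per_block * period_frames))
    psi0_blocks, psi1_blocks = [], []
    for b in range(n_blocks):
        sl = slice(b * m, (b + 1) * m)
        w = psi[sl]
        tw = t[sl]
        psi0_blocks.append(w.mean(axis=0))
        c1 = np.exp(-1j * omega * tw) @ (w - w.mean(axis=0)) / m
        psi1_blocks.append(np.sqrt(2.0) * c1)
    p0 = np.array(psi0_blocks)
    p1 = np.array(psi1_blocks)
    sem0 = p0.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    sem1 = np.sqrt(
        p1.real.var(axis=0, ddof=1) + p1.imag.var(axis=0, ddof=1)
    ) / np.sqrt(n_blocks)
    return sem0, sem1


def describe(
    decomp: ModalDecomposition, series: TangentAngleSeries | None = None
) -> BeatDescriptors:
    """Bundle the scalar beat descriptors (C0, v, lambda, optional SEMs)."""
    sem0 = sem1 = None
    if series is not None:
        try:
            sem0, sem1 = hexadecimation_sem(series)
        except ValueError:
            pass
    return BeatDescriptors(
        C0=static_curvature(decomp).C0,
        v=wave_speed(decomp),
        wavelength_lambda=wavelength(decomp),
        sem_psi0=sem0,
        sem_psi1=sem1,
    )
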