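"""Modal decomposition: frequency finding, projections, descriptors."""

import numpy as np
import pytest

import axobeat as ab
from axobeat.errors import NoPeriodicBeatError


def _series(psi, L=11.7, fr=1000.0):
    s = np.linspace(0.0, L, psi.shape[1])
    return ab.TangentAngleSeries(psi, s, fr, L)


def _clean_wave(amp1=0.68, f_hz=64.0, n=3000, L=11.7, lam=11.7, C0=0.0, phase0=0.2):
    """Bin-centred noiseless traveling wave (integer cycles in the record)."""
    t = np.arange(n) / 1000.0
    s = np.linspace(0, L, 20)
    om = 2 * np.pi * f_hz
    psi = C0 * s[None, :] + amp1 * np.sqrt(2) * np.sin(
        om * t[:, None] - 2 * np.pi * s[None, :] / lam + phase0
    )
    return _series(psi, L=L), om


class TestRotationEstimate:
    def test_pure_wave_no_rotation(self):
        ser, _ = _clean_wave()
        assert abs(ab.estimate_rotation(ser)) < 0.05

    def test_noiseless_ramp_recovers_slope_exactly(self):
        t = np.arange(500) / 1000.0
        psi = np.tile(3.7 * t[:, None], (1, 8))
        assert ab.estimate_rotation(_series(psi)) == pytest.approx(3.7, abs=1e-10)

    def test_injected_rotation_recovered(self, planewave_decomp):
        # generator injects 30 rad/s
        assert planewave_decomp.omega_rot == pytest.approx(30.0, abs=1.0)


class TestDecompose:
    def test_static_input_has_zero_dynamic_modes(self):
        psi = np.tile(np.linspace(0, 1, 12)[None, :], (100, 1))
        d = ab.decompose(_series(psi))
        np.testing.assert_allclose(np.abs(d.psi1), 0.0, atol=1e-12)
        assert d.power_fractions.sum() == 0.0

    def test_noise_only_raises_no_periodic_beat(self):
        rng = np.random.default_rng(0)
        psi = rng.normal(0, 0.02, size=(800, 12))
        with pytest.raises(NoPeriodicBeatError):
            ab.decompose(_series(psi))

    def test_exact_recovery_of_injected_mode(self):
        amp1, lam = 0.68, 11.7
        ser, om = _clean_wave(amp1=amp1, lam=lam)
        d = ab.decompose(ser)
        assert d.omega == pytest.approx(om, rel=1e-9)
        np.testing.assert_allclose(np.abs(d.psi1), amp1, atol=1e-10)
        slope = np.polyfit(d.arc_positions, np.unwrap(np.angle(d.psi1)), 1)[0]
        assert slope == pytest.approx(-2 * np.pi / lam, rel=1e-8)

    def test_projection_equals_bruteforce_dft(self, planewave_series):
        d = ab.decompose(planewave_series, phase_gauge=False)
        n = d.n_frames_used
        t = planewave_series.times[:n]
        psi = planewave_series.psi - d.omega_rot * planewave_series.times[:, None]
        w = psi[:n]
        dyn = w - w.mean(axis=0)
        c1 = np.exp(-1j * d.omega * t) @ dyn / n
        np.testing.assert_allclose(d.psi1, np.sqrt(2) * c1, atol=1e-10)

    def test_time_shift_equivariance(self):
        ser, om = _clean_wave()
        shift = 25  # frames
        d0 = ab.decompose(_series(ser.psi[: 2000]), phase_gauge=False)
        d1 = ab.decompose(_series(ser.psi[shift : 2000 + shift]), phase_gauge=False)
        dt = shift / 1000.0
        np.testing.assert_allclose(d1.psi1, d0.psi1 * np.exp(1j * d0.omega * dt), atol=1e-6)
        np.testing.assert_allclose(np.abs(d1.psi1), np.abs(d0.psi1), atol=1e-8)
        np.testing.assert_allclose(d1.psi0, d0.psi0, atol=1e-8)

    def test_phase_gauge_deterministic(self):
        ser, _ = _clean_wave()
        d = ab.decompose(ser)
        assert d.psi1[0].imag == pytest.approx(0.0, abs=1e-10)
        assert d.psi1[0].real >= 0

    def test_parseval_consistency_noiseless(self):
        ser, _ = _clean_wave()
        d = ab.decompose(ser)
        assert d.power_fractions[0] == pytest.approx(1.0, abs=1e-8)
        assert d.residual_fraction < 1e-8


class TestPowerFraction:
    def test_single_harmonic_is_unity(self):
        ser, _ = _clean_wave()
        d = ab.decompose(ser)
        assert ab.power_fraction(d, 1) == pytest.approx(1.0, abs=1e-8)

    def test_two_harmonics_amplitude_ratio_two_to_one(self):
        t = np.arange(3000) / 1000.0
        s = np.linspace(0, 11.7, 20)
        om = 2 * np.pi * 64
        arg = om * t[:, None] - 2 * np.pi * s[None, :] / 11.7
        psi = 0.6 * np.sin(arg) + 0.3 * np.sin(2 * arg + 0.4)
        d = ab.decompose(_series(psi))
        assert ab.power_fraction(d, 1) == pytest.approx(0.8, abs=1e-6)
        assert ab.power_fraction(d, 2) == pytest.approx(0.2, abs=1e-6)

    def test_static_mode_has_no_dynamic_power(self, planewave_decomp):
        with pytest.raises(ValueError):
            ab.power_fraction(planewave_decomp, 0)

    def test_periodogram_oracle(self):
        """Fraction matches total-variance (Parseval) normalization computed
        from the periodogram of the truncated window."""
        rng = np.random.default_rng(5)
        t = np.arange(3000) / 1000.0
        s = np.linspace(0, 11.7, 20)
        om = 2 * np.pi * 64
        psi = 0.68 * np.sqrt(2) * np.sin(
            om * t[:, None] - 2 * np.pi * s[None, :] / 11.7
        ) + rng.normal(0, 0.02, (3000, 20))
        d = ab.decompose(_series(psi), remove_rotation=False)
        n = d.n_frames_used
        dyn = psi[:n] - psi[:n].mean(axis=0)
        # Parseval: arc-averaged variance equals the periodogram integral
        total = np.mean(np.abs(np.fft.fft(dyn, axis=0)) ** 2) / n
        frac_oracle = np.mean(np.abs(d.psi1) ** 2) / total
        assert ab.power_fraction(d, 1) == pytest.approx(frac_oracle, abs=1e-6)


class TestStaticCurvature:
    def test_linear_static_mode(self):
        ser, _ = _clean_wave(C0=-0.232)
        d = ab.decompose(ser)
        assert ab.static_curvature(d).C0 == pytest.approx(-0.232, abs=1e-9)

    def test_constant_static_mode_zero_curvature(self):
        psi = np.tile(0.4 * np.ones(12)[None, :], (50, 1))
        d = ab.decompose(_series(psi))
        assert ab.static_curvature(d).C0 == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_perturbation_matches_lstsq_oracle(self):
        s = np.linspace(0, 11.7, 20)
        psi0 = -0.2 * s + 0.01 * s**2
        psi = np.tile(psi0[None, :], (60, 1))
        d = ab.decompose(_series(psi))
        A = np.column_stack([s, np.ones_like(s)])
        oracle = np.linalg.lstsq(A, psi0, rcond=None)[0][0]
        res = ab.static_curvature(d)
        assert res.C0 == pytest.approx(oracle, rel=1e-10)
        assert np.max(np.abs(res.residuals)) > 0


class TestWaveSpeed:
    def test_uniform_amplitude_full_phase_drop(self):
        s = np.linspace(0, 11.7, 401)
        psi1 = 0.68 * np.exp(-2j * np.pi * s / 11.7)
        v = ab.wave_speed(psi1, s)
        assert abs(v) == pytest.approx(0.68**2 * 2 * np.pi, rel=1e-3)
        assert v < 0  # base-to-tip under e^{+iwt}
        assert ab.wavelength(psi1, s) == pytest.approx(11.7, rel=1e-3)

    def test_standing_wave_zero_speed(self):
        s = np.linspace(0, 10, 101)
        psi1 = np.cos(np.pi * s / 10) * np.exp(0.3j)
        assert ab.wave_speed(psi1, s) == pytest.approx(0.0, abs=1e-12)

    def test_refinement_oracle(self):
        L = 11.7

        def mode(s):
            return (0.5 + 0.3 * s / L) * np.exp(-2j * np.pi * s / L + 0.2j * (s / L) ** 2)

        s1 = np.linspace(0, L, 801)
        s2 = np.linspace(0, L, 8001)
        assert ab.wave_speed(mode(s1), s1) == pytest.approx(
            ab.wave_speed(mode(s2), s2), abs=1e-4
        )

    def test_undersampled_phase_raises_with_index(self):
        s = np.linspace(0, 10, 8)
        psi1 = np.exp(-1j * 6.8 * np.pi * s / 10)  # ~0.97 pi jumps between samples
        with pytest.raises(ValueError, match="samples"):
            ab.wave_speed(psi1, s)


class TestReconstruction:
    def test_static_only_is_phase_independent(self, planewave_decomp):
        ang, shapes = ab.reconstruct_shapes(
            planewave_decomp, modes={0}, phases=[0.0, 1.0, 2.0]
        )
        np.testing.assert_allclose(ang[0], ang[1], atol=1e-14)
        np.testing.assert_allclose(shapes[0], shapes[2], atol=1e-12)

    def test_full_reconstruction_matches_noiseless_series(self):
        ser, om = _clean_wave(C0=-0.232)
        d = ab.decompose(ser, phase_gauge=False)
        phases = om * ser.times[:200]
        ang, _ = ab.reconstruct_shapes(d, modes={0, 1}, phases=phases)
        resid = ang - ser.psi[:200]
        ss_res = np.sum(resid**2)
        ss_tot = np.sum((ser.psi[:200] - ser.psi[:200].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999

    def test_parseval_residual_equals_second_harmonic_power(self):
        t = np.arange(3000) / 1000.0
        s = np.linspace(0, 11.7, 20)
        om = 2 * np.pi * 64
        arg = om * t[:, None] - 2 * np.pi * s[None, :] / 11.7
        psi = 0.6 * np.sin(arg) + 0.2 * np.sin(2 * arg + 0.4)
        d = ab.decompose(_series(psi), phase_gauge=False)
        phases = om * t
        ang, _ = ab.reconstruct_shapes(d, modes={0, 1}, phases=phases)
        resid_power = np.mean((ang - psi) ** 2)
        p2 = ab.power_fraction(d, 2) * np.mean((psi - psi.mean(axis=0)) ** 2)
        assert resid_power == pytest.approx(p2, abs=1e-6)


class TestHexadecimation:
    def test_noiseless_sem_vanishes(self):
        # 62.5 Hz: whole periods fit exactly into sample blocks
        ser, _ = _clean_wave(f_hz=62.5)
        sem0, sem1 = ab.hexadecimation_sem(ser)
        assert sem0.max() < 1e-8
        assert sem1.max() < 1e-8

    def test_iid_noise_scaling_matches_analytic(self):
        sigma = 0.02
        ratios0, ratios1 = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ser, _ = _clean_wave(f_hz=62.5)
            noisy = _series(ser.psi + rng.normal(0, sigma, ser.psi.shape))
            sem0, sem1 = ab.hexadecimation_sem(noisy)
            n_eff = 16 * int(ser.n_frames / 16)
            ratios0.append(sem0.mean() / (sigma / np.sqrt(n_eff)))
            ratios1.append(sem1.mean() / (np.sqrt(2) * sigma / np.sqrt(n_eff)))
        assert 1 / 1.5 < np.mean(ratios0) < 1.5
        assert 1 / 1.5 < np.mean(ratios1) < 1.5

    def test_doubling_record_halves_sem(self):
        sigma = 0.02
        rng = np.random.default_rng(1)
        ser, _ = _clean_wave(f_hz=62.5, n=6000)
        noise = rng.normal(0, sigma, ser.psi.shape)
        full = _series(ser.psi + noise)
        half = _series(ser.psi[:3000] + noise[:3000])
        s0f, _ = ab.hexadecimation_sem(full)
        s0h, _ = ab.hexadecimation_sem(half)
        ratio = s0h.mean() / s0f.mean()
        assert np.sqrt(2) * 0.7 < ratio < np.sqrt(2) * 1.3

    def test_too_few_cycles_raises(self):
        ser, _ = _clean_wave(n=200)
        with pytest.raises(ValueError, match="n_blocks"):
            ab.hexadecimation_sem(ser)
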