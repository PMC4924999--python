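"""Axoneme model: force laws, characteristic roots, boundary-value solve."""

import numpy as np
import pytest

import axobeat as ab
from axobeat.errors import NoOscillatorySolutionError
from axobeat.model import _system_matrices, characteristic_roots
from axobeat.shooting import solve_dynamic_mode_shooting


class TestStaticForce:
    def test_symmetric_beat_zero_force(self, wt_params):
        f0 = ab.static_motor_force(wt_params.with_(C0=0.0))
        assert f0.tip_weight == 0.0 and f0.F0 == 0.0

    def test_static_balance_identity(self, wt_params):
        f0 = ab.static_motor_force(wt_params)
        # kappa psi0' = a F0 with psi0' = C0
        assert wt_params.kappa * wt_params.C0 == pytest.approx(
            wt_params.a * f0.F0, rel=1e-12
        )

    def test_delta_pairing(self, wt_params):
        f0 = ab.static_motor_force(wt_params)
        for g in (np.sin, np.cos, lambda s: s**2):
            assert f0.pair(g) == pytest.approx(
                f0.tip_weight * g(wt_params.L), abs=1e-12
            )


class TestMotorForce:
    def test_zero_coefficients(self):
        r = ab.MotorResponse("curvature", chi=0.0, beta=0.0)
        f = ab.motor_force_fundamental(r, np.ones(5), np.ones(5))
        np.testing.assert_allclose(f, 0.0)

    def test_viscoelastic_sliding_form(self):
        k, xi, om = -7.0, -0.02, 427.0
        r = ab.MotorResponse("sliding", chi=complex(k, om * xi))
        delta = np.array([0.1 + 0.2j, -0.3j, 0.5])
        f = ab.motor_force_fundamental(r, delta, np.zeros(3))
        np.testing.assert_allclose(f, k * delta + 1j * om * xi * delta, atol=1e-14)

    def test_linearity_in_sliding(self, rng):
        r = ab.MotorResponse("curvature", chi=5 - 2j, beta=-3j)
        d = rng.normal(size=6) + 1j * rng.normal(size=6)
        pd = rng.normal(size=6) + 1j * rng.normal(size=6)
        alpha = 1.7 - 0.4j
        f1 = ab.motor_force_fundamental(r, alpha * d, alpha * pd)
        f2 = alpha * ab.motor_force_fundamental(r, d, pd)
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_variant_consistency_enforced(self):
        with pytest.raises(ValueError):
            ab.MotorResponse("sliding", chi=-1.0, beta=1.0)
        with pytest.raises(ValueError):
            ab.MotorResponse("sliding", chi=+1.0)
        with pytest.raises(ValueError):
            ab.MotorResponse("curvature", gamma=1.0)
        with pytest.raises(ValueError):
            ab.MotorResponse("normal_force", beta=1.0)


class TestNormalForce:
    def test_symmetric_beat_vanishes(self, wt_params, rng):
        p = wt_params.with_(C0=0.0)
        F1 = rng.normal(size=8) + 1j * rng.normal(size=8)
        out = ab.normal_force_fundamental(p, F1, F1)
        np.testing.assert_allclose(out, 0.0)

    def test_cancellation(self, wt_params, rng):
        pd = rng.normal(size=8) + 1j * rng.normal(size=8)
        F1 = -wt_params.kappa * pd / wt_params.a
        out = ab.normal_force_fundamental(wt_params, F1, pd)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_product_linearization_oracle(self, wt_params, rng):
        """f_perp,1 equals the first-order expansion of F * psi' about the
        static balance a F0 = kappa C0."""
        F1 = rng.normal(size=8) + 1j * rng.normal(size=8)
        pd = rng.normal(size=8) + 1j * rng.normal(size=8)
        p = wt_params
        F0 = p.kappa * p.C0 / p.a
        # (F0 + F1 e)(C0 + pd e) -> fundamental coefficient: F0*pd + F1*C0
        oracle = F0 * pd + F1 * p.C0
        got = ab.normal_force_fundamental(p, F1, pd)
        np.testing.assert_allclose(got, oracle, atol=1e-12)

    def test_linear_vanishing_in_C0(self, wt_params):
        """Along C0 -> 0 the solution's normal force shrinks linearly."""
        norms = []
        c0s = [-0.1, -0.05, -0.025]
        for c0 in c0s:
            p = wt_params.with_(C0=c0)
            r = ab.MotorResponse("curvature", chi=19.8, beta=-6.5j)
            r.chi_b = ab.critical_basal_impedance(p, r)
            sol = ab.solve_dynamic_mode(p, r, n_grid=101)
            norms.append(np.max(np.abs(sol.f_perp1)))
        slope = np.polyfit(np.log(np.abs(c0s)), np.log(norms), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)


class TestCharacteristicRoots:
    def test_passive_filament_closed_form(self, wt_params):
        p = wt_params.with_(C0=0.0)
        r = ab.MotorResponse("curvature", chi=0.0, beta=0.0)
        roots = characteristic_roots(p, r)
        mag = (p.omega * p.xi_n / p.kappa) ** 0.25
        assert roots.size == 4
        np.testing.assert_allclose(np.abs(roots), mag, rtol=1e-10)
        np.testing.assert_allclose(
            p.kappa * roots**4 + 1j * p.omega * p.xi_n, 0.0, atol=1e-12
        )

    def test_sliding_matches_plane_wave_dispersion(self, wt_params):
        """C0 = 0 sliding roots coincide with the wavelength solutions of the
        plane-wave dispersion relation under k = 2 pi i / lambda."""
        p = wt_params.with_(C0=0.0)
        chi = -12.2 - 1.1j
        r = ab.MotorResponse("sliding", chi=chi)
        roots = characteristic_roots(p, r)
        ks = 2j * np.pi / ab.sliding_dispersion(p, chi)
        for k in ks:
            assert min(abs(roots - k)) < 1e-9

    @pytest.mark.parametrize("variant", ["sliding", "curvature", "normal_force"])
    def test_residual_oracle_and_system_order(self, wt_params, variant):
        resp = {
            "sliding": ab.MotorResponse("sliding", chi=-12.2 - 1.1j),
            "curvature": ab.MotorResponse("curvature", chi=19.8, beta=-6.5j),
            "normal_force": ab.MotorResponse("normal_force", chi=13.2, gamma=0.12 + 2j),
        }[variant]
        roots = characteristic_roots(wt_params, resp)
        assert roots.size == {"sliding": 6, "curvature": 6, "normal_force": 7}[variant]
        from axobeat.model import _char_poly

        poly = _char_poly(wt_params, resp)
        vals = np.polyval(poly[::-1], roots)
        assert np.max(np.abs(vals)) < 1e-9 * np.abs(poly).sum()
        # roots are eigenvalues of the first-order system
        M, _ = _system_matrices(wt_params, resp)
        ev = np.linalg.eigvals(M)
        for k in roots:
            assert min(abs(ev - k)) < 1e-7 * max(1.0, abs(k))


class TestIntegratedForce:
    def test_zero(self):
        s = np.linspace(0, 10, 50)
        np.testing.assert_allclose(ab.integrated_force(np.zeros(50), s), 0.0)

    def test_constant_density_linear_force(self):
        s = np.linspace(0, 10, 201)
        F = ab.integrated_force(np.full(201, 2.5), s)
        np.testing.assert_allclose(F, -2.5 * (10 - s), atol=1e-10)
        assert F[-1] == 0.0

    def test_refinement_oracle(self):
        f = lambda s: np.sin(s) + 0.3 * s
        s1 = np.linspace(0, 10, 10001)
        s2 = np.linspace(0, 10, 100001)
        F1 = ab.integrated_force(f(s1), s1)
        F2 = ab.integrated_force(f(s2), s2)
        assert abs(F1[0] - F2[0]) < 1e-6


class TestBoundaryDeterminant:
    def test_vanishes_at_critical_impedance(self, wt_params, curvature_resp):
        det = ab.boundary_determinant(wt_params, curvature_resp, curvature_resp.chi_b)
        scale = abs(ab.boundary_determinant(wt_params, curvature_resp, 0.0)) + abs(
            ab.boundary_determinant(wt_params, curvature_resp, 1.0)
        )
        assert abs(det) < 1e-8 * scale

    def test_continuity_in_chi_b(self, wt_params, curvature_resp):
        chi_b = 10 + 5j
        d0 = ab.boundary_determinant(wt_params, curvature_resp, chi_b)
        errs = []
        for eps in (1e-3, 1e-4, 1e-5):
            d1 = ab.boundary_determinant(wt_params, curvature_resp, chi_b + eps)
            errs.append(abs(d1 - d0))
        # linear shrinkage with eps (the determinant is affine in chi_b)
        assert errs[1] == pytest.approx(errs[0] / 10, rel=1e-3)
        assert errs[2] == pytest.approx(errs[1] / 10, rel=1e-3)

    def test_passive_filament_has_no_passive_critical_base(self, wt_params):
        """Without motors no chi_b in the passive quadrant (Re, Im >= 0)
        produces spontaneous oscillation."""
        r = ab.MotorResponse("curvature", chi=0.0, beta=0.0)
        # without sliding coupling only the trivial psi_1 = 0 mode can make
        # the determinant vanish
        with pytest.raises(NoOscillatorySolutionError):
            ab.critical_basal_impedance(wt_params, r)
        # grid scan of the passive quadrant: determinant stays away from zero
        scale = abs(ab.boundary_determinant(wt_params, r, 1.0))
        for re in np.geomspace(0.1, 1e3, 6):
            for im in np.geomspace(0.1, 1e4, 6):
                assert abs(
                    ab.boundary_determinant(wt_params, r, complex(re, im))
                ) > 1e-6 * scale


class TestSolveDynamicMode:
    def test_no_motor_force_means_no_oscillation(self, wt_params):
        r = ab.MotorResponse("curvature", chi=0.0, beta=0.0, chi_b=50 + 5j)
        with pytest.raises(NoOscillatorySolutionError) as exc:
            ab.solve_dynamic_mode(wt_params, r)
        assert exc.value.det_abs is not None

    def test_solution_invariants(self, wt_params, wt_curvature_solution):
        sol = wt_curvature_solution
        a = wt_params.a
        # sliding-angle relation at the fundamental mode, pointwise
        np.testing.assert_allclose(
            sol.delta1, sol.delta_b1 + a * (sol.psi1 - sol.psi1[0]), atol=1e-12
        )
        # tip value of the integrated force
        assert abs(sol.F1[-1]) < 1e-10 * np.abs(sol.f1).max()
        # basal force balance through the compliance
        assert abs(sol.F1[0] - sol.chi_b * sol.delta_b1) < 1e-8 * abs(sol.F1[0] + 1e-30) + 1e-10
        # boundary conditions: distal curvature-free, basal/distal tension-free
        assert abs(sol.psi1_prime[-1]) < 1e-8
        assert abs(sol.tau1[0]) < 1e-8 and abs(sol.tau1[-1]) < 1e-8
        # gauge: unit rms, real non-negative base value
        assert np.sqrt(np.mean(np.abs(sol.psi1) ** 2)) == pytest.approx(1.0, rel=1e-9)
        assert sol.psi1[0].imag == pytest.approx(0.0, abs=1e-9)

    def test_curvature_control_travels_sliding_stands(
        self, wt_params, wt_curvature_solution, sliding_resp
    ):
        v_curv = ab.wave_speed(0.68 * wt_curvature_solution.psi1, wt_curvature_solution.s)
        sol_s = ab.solve_dynamic_mode(wt_params, sliding_resp, n_grid=201)
        v_slid = ab.wave_speed(0.68 * sol_s.psi1, sol_s.s)
        assert abs(v_curv) > 1.0          # traveling, experimental magnitude
        assert abs(v_slid) < 0.05         # standing: orders below measured ~2.9
        ph = np.unwrap(np.angle(wt_curvature_solution.psi1))
        assert 0.5 * 2 * np.pi < abs(ph[-1] - ph[0]) < 1.5 * 2 * np.pi

    def test_short_axoneme_sliding_always_stands(self, wt_params):
        """L << critical length: sliding control loses directionality."""
        p = wt_params.with_(L=6.0)
        r = ab.MotorResponse("sliding", chi=-12.2 - 1.1j)
        r.chi_b = ab.critical_basal_impedance(p, r)
        sol = ab.solve_dynamic_mode(p, r, n_grid=201)
        assert abs(ab.wave_speed(0.68 * sol.psi1, sol.s)) < 0.05

    def test_gauge_invariance_of_observables(self, wt_params, curvature_resp):
        sol = ab.solve_dynamic_mode(wt_params, curvature_resp, n_grid=101)
        rot = np.exp(0.73j)
        v1 = ab.wave_speed(sol.psi1, sol.s)
        v2 = ab.wave_speed(rot * sol.psi1, sol.s)
        assert v1 == pytest.approx(v2, rel=1e-12)
        r1 = ab.score_R2(sol.psi1, rot * sol.psi1)
        assert r1 == pytest.approx(1.0, abs=1e-12)

    def test_continuity_to_symmetric_limit(self, wt_params):
        """C0 -> 0 solutions converge to the 4th-order symmetric solution."""
        r0 = ab.MotorResponse("curvature", chi=19.8, beta=-6.5j)
        p_sym = wt_params.with_(C0=1e-12)
        p0 = wt_params.with_(C0=0.0)
        r0.chi_b = ab.critical_basal_impedance(p0, r0)
        sol0 = ab.solve_dynamic_mode(p0, r0, n_grid=101)
        r1 = ab.MotorResponse("curvature", chi=19.8, beta=-6.5j)
        r1.chi_b = ab.critical_basal_impedance(p_sym, r1)
        sol1 = ab.solve_dynamic_mode(p_sym, r1, n_grid=101)
        assert np.max(np.abs(sol0.psi1 - sol1.psi1)) < 1e-6


class TestShootingOracle:
    @pytest.mark.parametrize("variant", ["sliding", "curvature", "normal_force"])
    def test_exponential_basis_matches_shooting(self, wt_params, variant):
        rng = np.random.default_rng(hash(variant) % 2**31)
        p = wt_params.with_(
            L=float(rng.uniform(8, 14)),
            omega=float(rng.uniform(200, 500)),
            C0=float(rng.uniform(-0.3, -0.01)),
        )
        r = {
            "sliding": ab.MotorResponse("sliding", chi=complex(-15.0, -1.0)),
            "curvature": ab.MotorResponse("curvature", chi=20.0, beta=-6j),
            "normal_force": ab.MotorResponse("normal_force", chi=10.0, gamma=0.2 + 2j),
        }[variant]
        r.chi_b = ab.critical_basal_impedance(p, r)
        s = np.linspace(0, p.L, 41)
        a = ab.solve_dynamic_mode(p, r, s_grid=s)
        b = solve_dynamic_mode_shooting(p, r, s_grid=s)
        scale = np.max(np.abs(a.psi1))
        assert np.max(np.abs(a.psi1 - b.psi1)) < 1e-6 * scale
        assert np.max(np.abs(a.tau1 - b.tau1)) < 1e-6 * (np.max(np.abs(a.tau1)) + scale)
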