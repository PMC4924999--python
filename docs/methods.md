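# Methods

## Model

The axoneme is reduced to a planar pair of inextensible filaments at fixed
spacing `a`, with bending rigidity `κ` and resistive-force-theory drag
(normal and tangential coefficients `ξₙ`, `ξₜ`, ratio `ξₙ/ξₜ = 2`). Dynein
activity enters as a sliding force density `f(s, t)` between the filaments;
the interdoublet sliding is slaved to the tangent angle,
`Δ(s) = Δ_b + a[ψ(s) − ψ(0)]`, with basal sliding `Δ_b` restrained by a
viscoelastic compliance `χ_b = k_b + iωξ_b`. The sign convention is fixed so
that a positive dynein force density produces negative curvature; the static
balance `κψ̇₀ = aF₀` with constant curvature `C₀` then requires the static
motor force to be concentrated at the distal tip
(`f₀ = −δ(s−L) κC₀/a`).

At the beat frequency the fundamental modes `ψ₁(s)`, `τ₁(s)` satisfy the
constant-coefficient system (`r = ξₙ/ξₜ`, primes arc-length derivatives)

    iωξₙψ₁ = −κψ₁'''' + a f₁'' + (1+r) C₀ τ₁' + r C₀² (κψ₁'' − a f₁)
    r τ₁'' − C₀² τ₁ = −(1+r) C₀ (κψ₁''' − a f₁')

closed by the motor law `f₁ = χΔ₁ + βψ̇₁ + γ f⊥,₁` with the linearized
normal force `f⊥,₁ = C₀(F₁ + κψ̇₁/a)`, `F₁(s) = −∫ₛᴸ f₁`. For normal-force
control `F₁` is promoted to an explicit state (`F₁' = f₁`, `F₁(L) = 0`),
keeping the system local. The system is of order six for `C₀ ≠ 0`, four for
a symmetric beat (tension decouples), plus one for the explicit `F₁` state.

## Boundary conditions

The source material for this model states the physical content of the
boundary conditions — no external forces or torques at the ends of a freely
swimming axoneme, basal balance through `χ_b` — and we derived their
algebraic form variationally from the work functional
`G = ∫ (κ/2)ψ'² + fΔ + (Λ/2)(r'² − 1) ds + (k_b/2)Δ_b²`. The boundary terms
of `δG` give, at the fundamental mode,

* distal (s = L): `ψ₁' = 0` (torque/curvature-free),
  `−κψ₁'' + a f₁ = 0` (transverse force), `τ₁ = 0` (axial force);
* basal (s = 0): `κψ₁'(0) = a F₁(0)` (torque balance),
  `κψ₁'' − a f₁ = 0`, `τ₁ = 0`, and the basal sliding balance
  `F₁(0) = χ_b Δ_b,₁`.

The tension mode is `τ = Λ + κψ'²` (zero in statics). With the two scalar
unknowns `Δ_b,₁` and `ψ₁(0)` carried explicitly (they enter the motor law as
the constant `D = χ(Δ_b,₁ − aψ₁(0))`), the boundary conditions form a
homogeneous 9×9 linear system; a beat exists where its determinant
vanishes.

## Numerics

**Solver.** The general solution of the constant-coefficient system is
represented by the matrix-exponential fundamental solution of the
first-order form (states `ψ₁ … ψ₁'''`, `τ₁`, `τ₁'`, `F₁`): the exponential
basis of the characteristic roots in matrix form, uniformly valid at
repeated roots (the `s·e^{ks}` degeneracy is handled by `expm` without case
switching). The particular solution for the constant forcing `D` comes from
the augmented 8×8 exponential. Boundary rows are assembled on
`(y(0), Δ_b,₁, ψ₁(0))`; the critical mode is the SVD null vector, accepted
when `σ_min/σ_max < 10⁻⁶`. An independent Runge–Kutta (DOP853) shooting
solver with its own right-hand side serves as a verification oracle; the
two routes agree to better than 10⁻⁶ relative across all three control
variants and random parameter sets.

**Basal-impedance closure.** `χ_b` enters only the basal-sliding column of
the boundary matrix, so the determinant is affine in `χ_b` and the critical
value is the root of a linear equation — computed exactly from two
determinant evaluations. There is therefore a unique closure for given
motor coefficients; no root search or tie-breaking is needed. The limiting
case `χ′ = χ″ = 0` decouples basal sliding from the dynamics and only the
trivial `ψ₁ = 0` mode can zero the determinant; this is detected and
reported as "no oscillatory solution" (it also encodes the physical
statement that a passive filament does not oscillate spontaneously: a grid
scan of the passive quadrant `Re χ_b, Im χ_b ≥ 0` leaves the determinant
bounded away from zero).

**Gauge.** The linear problem fixes the mode shape only; solutions are
normalized to unit rms `|ψ₁|` with `ψ₁(0)` real and non-negative. All
reported observables (wave speed, R², phase bearings) are invariant under
this gauge, and comparison with data fits a single complex scale factor by
least squares.

## Modal decomposition

Convention: `ψ(s,t) = ψ₀(s) + Σₙ √2·Re[ψₙ(s) e^{inωt}]`, i.e. `ψₙ` is √2
times the complex Fourier coefficient, so `|ψₙ(s)|` is the rms oscillation
amplitude at `s` — the convention under which the wild-type fundamental has
`|ψ₁| ≈ 0.68` rad and the normalized bend propagation speed
`v = ∫|ψ₁|² ∂ₛ arg ψ₁ ds` is ≈ 3 in magnitude. With the `e^{+iωt}` time
convention, base-to-tip propagation means `∂ₛ arg ψ₁ < 0` (v < 0, signed
wavelength `λ = −2π/⟨∂ₛ arg ψ₁⟩ > 0`).

The beat frequency is the largest non-DC peak of the arc-averaged
periodogram (error if the peak is below 20× the median floor; warning and
lower-frequency choice if two peaks lie within 1%), refined by parabolic
interpolation, bounded maximization of the projection power, and a
phase-slope polish (the projection phase drift between the two halves of an
integer-period window measures the residual frequency error; iterating
converges to machine precision on clean records). Modes are projections
onto `e^{inωt}` over the largest whole number of periods, n = 1…4 reported,
higher harmonics lumped into the residual.

Rigid rotation is removed before decomposition. The plain least-squares
slope of the arc-averaged angle is biased by the residual oscillation of a
finite record, so once ω is known the slope is re-estimated jointly with
the beat sinusoid (regressors {1, t, cos ωt, sin ωt}); this makes the
decomposition an exact inverse of the generator on noiseless periodic
input. The wave-speed integrand is computed as `Im(ψ₁* ψ₁')` — identical to
`|ψ₁|² ∂ₛ arg ψ₁` but continuous through the nodes of standing waves (where
it vanishes exactly); an error is raised only when the phase advances by
≈ π between samples at non-negligible amplitude (genuine undersampling).
Standard errors come from hexadecimation: 16 contiguous blocks of whole
periods, each decomposed at the global frequency with absolute-time
projections so that block phases are directly comparable.

The deterministic output phase gauge (ψ₁ at the base real and
non-negative, applied as a time-origin shift to all harmonics) can be
disabled (`phase_gauge=False`), in which case a time shift of the input
multiplies `ψₙ` by `e^{inωΔt}` exactly (equivariance).

## Fitting

The objective is R² between the complex theoretical and experimental
fundamental modes at the experimental arc positions, after the single
complex scale factor; the static mode is excluded (static balance holds
exactly by construction). Free parameters: sliding `(χ′, χ″ ≤ 0)`,
curvature `(χ′, β″)` with `χ″ = β′ = 0`, normal force `(χ′, γ′, γ″)`; `χ_b`
is closed from the boundary conditions at every evaluation, and `ω` and
`C₀` are fixed from the decomposition. Optimization is Nelder–Mead from 8
deterministic log-spaced starts per variant; evaluations where the closure
or the solve fails score −∞. Reported units follow the field's convention:
χ in nN·μm⁻², β in nN, γ dimensionless, χ_b in nN·μm⁻¹, basal sliding in
nm (static basal sliding `Δ_b,₀ = κC₀/(a k_b)`). Fits whose closed `χ_b`
has a negative real or imaginary part are flagged as "active base".

## Parameters

Mechanical constants are the package's standard estimates: `κ = 0.4 nN·μm²`
(axonemal bending rigidity), `ξₙ = 3.4×10⁻⁶ nN·s·μm⁻²` (resistive-force
theory for a ≈0.2 μm filament in water), `ξₜ = ξₙ/2`, `a = 0.066 μm`.
Together with the wild-type beat frequency these give the critical length
`ℓ = 2π(κ/ξₙω)^¼ ≈ 26 μm`, the value that controls all the length-scale
arguments; ℓ depends on κ and ξₙ only through a fourth root, so the
conclusions tolerate several-fold parameter uncertainty. Presets:
wild type `L = 11.7 μm`, `ω = 427 rad/s`, `C₀ = −0.232 μm⁻¹`; the mbo2
mutant (nearly symmetric beat) `L = 9.2 μm`, `ω = 176 rad/s`,
`C₀ = −0.0276 μm⁻¹`. Mean fitted response coefficients per variant are
shipped as presets (e.g. wild-type curvature control `χ′ = 19.8 nN·μm⁻²`,
`β″ = −6.5 nN`).

## Synthetic data

The generator emulates high-speed tracking of reactivated axonemes: a
traveling fundamental wave `C₀s + amp1·√2·sin(ωt − 2πs/λ)` (rms amplitude
`amp1 = 0.68`, `λ = L`), slow rigid rotation (30 rad/s), i.i.d. Gaussian
tracking noise (20 mrad in angle; 5 nm in position for the centerline
variant), 3000 frames at 1000 Hz on 20 arc positions, single seeded RNG
stream (bit-reproducible). A second-harmonic amplitude knob defaults to 0.
A forward-model generator builds series from the boundary-value solution
itself, with the ground-truth coefficients in the metadata sidecar, for
parameter-recovery tests.

What the generator does *not* emulate: amplitude and frequency drift,
correlated tracking errors along the filament, harmonic content above n=1
(unless dialed in), deviations of the static mode from constant curvature,
and axoneme-to-axoneme variability. Passing tests therefore demonstrate
correctness of the estimators and solver under the model's own statistical
assumptions, not robustness to every artifact of real recordings.

## Numerical choices and limitations

* Centerline → angle conversion: per-frame interpolating cubic spline
  (not-a-knot ends — natural ends would force zero end curvature and bias
  the basal tangent by ~0.1 rad), arc length by cumulative chord on a 10×
  oversampled curve, resampling at equally spaced arc lengths, unwrapping
  first along s then along t. With 20 tracked points the interpolation
  error of the wild-type waveform is ≈5 mrad (interior) — below the 20 mrad
  tracking noise; it falls below 1 mrad with ≥3× denser tracking.
* Position reconstruction uses composite trapezoid quadrature on the given
  grid; accuracy is O(h²), so sub-nanometer round trips require grids of a
  few hundred points.
* Wave-speed and wavelength integrals use second-order differences and
  trapezoid quadrature (relative accuracy ~10⁻⁵ at 400 grid points).
* The solver's boundary matrix conditioning degrades for motor coefficients
  far outside the physical range (boundary-layer roots `e^{kL}` large); the
  optimizer treats such evaluations as failed rather than trusting them.
* Problem sizes in the shipped tests and analyses (1000–3000 frames, 5–10
  seeds, 50 random solver cross-checks, 21×21 sensitivity grids) are chosen
  to exercise every claim at full fidelity while keeping a complete run in
  minutes.
* Amplitude saturation beyond the critical point, arc-length-dependent
  motor coefficients, time-domain nonlinear dynamics and 3-D effects are
  out of scope; the model predicts mode shapes, not amplitudes.
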