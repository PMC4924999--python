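"""Named parameter presets for *Chlamydomonas* axonemes.

Mechanical constants: bending rigidity kappa = 0.4 nN·μm² (the standard
axonemal estimate), normal drag xi_n = 3.4e-6 nN·s·μm⁻² (resistive-force
theory for a ~0.2 μm filament in water) and xi_n/xi_t = 2.  Together with
the wild-type beat frequency these give a critical length
l = 2 pi (kappa / xi_n omega)^(1/4) of about 26 μm.

Beat parameters: wild type L = 11.7 μm, omega = 427 rad/s (68 Hz),
C0 = -0.232 μm⁻¹; the mbo2 ("moves backwards only") mutant beats nearly
symmetrically: L = 9.2 μm, omega = 176 rad/s (28 Hz), C0 = -0.0276 μm⁻¹.

Motor-response presets are the mean fitted coefficients per control variant
(chi nN·μm⁻², beta nN, gamma dimensionless, chi_b nN·μm⁻¹).
"""

from __future__ import annotations

from .model import MechanicalParams, MotorResponse

__all__ = ["mechanical_params", "motor_response", "PRESETS"]

KAPPA = 0.4          # nN μm^2
XI_N = 3.4e-6        # nN s μm^-2
XI_T = XI_N / 2.0
SPACING_A = 0.066    # μm

PRESETS = {
    "chlamy_wt": dict(L=11.7, omega=427.0, C0=-0.232),
    "chlamy_mbo2": dict(L=9.2, omega=176.0, C0=-0.0276),
}

# mean fitted coefficients per (preset, variant)
_RESPONSES = {
    ("chlamy_wt", "sliding"): dict(chi=-12.2 - 1.1j, chi_b=42.4 + 2800j),
    ("chlamy_wt", "curvature"): dict(chi=19.8 + 0j, beta=-6.5j, chi_b=42.2 + 2.2j),
    ("chlamy_wt", "normal_force"): dict(
        chi=13.2 + 0j, gamma=0.12 + 2.0j, chi_b=80 + 13000j
    ),
    ("chlamy_mbo2", "sliding"): dict(chi=-15.0 - 0.4j, chi_b=30.6 + 1.6j),
    ("chlamy_mbo2", "curvature"): dict(chi=17.4 + 0j, beta=-0.66j, chi_b=2.1 + 2.3j),
    ("chlamy_mbo2", "normal_force"): dict(
        chi=10.5 + 0j, gamma=1.52 + 32j, chi_b=2.3 + 13.6j
    ),
}


def mechanical_params(preset: str = "chlamy_wt", **overrides) -> MechanicalParams:
    """MechanicalParams for a named preset; keyword overrides allowed."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kw = dict(kappa=KAPPA, xi_n=XI_N, xi_t=XI_T, a=SPACING_A, **PRESETS[preset])
    kw.update(overrides)
    return MechanicalParams(**kw)


def motor_response(preset: str, variant: str, **overrides) -> MotorResponse:
    """Mean fitted MotorResponse for a named preset and control variant."""
    key = (preset, variant)
    if key not in _RESPONSES:
        raise KeyError(f"no response preset for {key}")
    kw = dict(_RESPONSES[key])
    kw.update(overrides)
    return MotorResponse(variant=variant, **kw)
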