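"""Low-Reynolds-number closed forms for a beating slender filament.

All inputs are user-supplied (drag coefficients ξ⊥, ξ∥ in pN·s/μm² and
flexural rigidity κ in pN·μm² come from the resistive-force-theory
literature and are never hardcoded here):

* Machin number  Ma = f ξ⊥ λ⁴ / (8π³ κ) — ratio of hydrodynamic to bending
  forces; Ma ≪ 1 means the beat is bending-dominated.
* Propulsive force per unit length of a small-amplitude sinusoidal beat,
  F/L = 2π² (ξ⊥ − ξ∥) f y0² / λ (y0 = transverse amplitude in μm).
* Swimming speed v = F / (L ξ∥).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "MechanicsInput",
    "machin_number",
    "propulsive_force_per_length",
    "swimming_speed",
]


@dataclass(frozen=True)
class MechanicsInput:
    """Parameters of the closed-form mechanics estimates.

    frequency_hz (f), lambda_um (λ), xi_perp / xi_par (ξ⊥, ξ∥, pN·s/μm²),
    kappa_pn_um2 (κ), amplitude_um (y0), length_um (L).
    """

    frequency_hz: float
    lambda_um: float
    xi_perp: float
    xi_par: float
    kappa_pn_um2: float = np.nan
    amplitude_um: float = np.nan
    length_um: float = np.nan

    def __post_init__(self):
        if self.frequency_hz < 0:
            raise ParameterError("frequency_hz", "must be non-negative")
        if self.lambda_um <= 0:
            raise ParameterError("lambda_um", "must be positive")
        if self.xi_perp <= 0 or self.xi_par <= 0:
            raise ParameterError("xi_perp/xi_par", "drag coefficients must be positive")
        if self.xi_perp < self.xi_par:
            raise ParameterError("xi_perp", "must exceed xi_par for a slender filament")


def machin_number(inp: MechanicsInput) -> float:
    """Ma = f ξ⊥ λ⁴ / (8π³ κ); dimensionless."""
    if not inp.kappa_pn_um2 > 0:
        raise ParameterError("kappa_pn_um2", "must be positive")
    return inp.frequency_hz * inp.xi_perp * inp.lambda_um**4 / (8 * np.pi**3 * inp.kappa_pn_um2)


def propulsive_force_per_length(inp: MechanicsInput) -> float:
    """F/L = 2π² (ξ⊥ − ξ∥) f y0² / λ, in pN/μm."""
    if not inp.amplitude_um >= 0:
        raise ParameterError("amplitude_um", "must be non-negative")
    return (
        2 * np.pi**2 * (inp.xi_perp - inp.xi_par) * inp.frequency_hz * inp.amplitude_um**2
        / inp.lambda_um
    )


def swimming_speed(force_pn: float, length_um: float, xi_par: float) -> float:
    """v = F / (L ξ∥), in μm/s."""
    if length_um <= 0:
        raise ParameterError("length_um", "must be positive")
    if xi_par <= 0:
        raise ParameterError("xi_par", "must be positive")
    return force_pn / (length_um * xi_par)
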