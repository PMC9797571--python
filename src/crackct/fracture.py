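"""Closed-form fracture-mechanics estimates for enamel cracks.

Relates crack geometry, material constants, and applied stress through the
classical brittle-fracture formulas: stress concentration at an elliptical
flaw, the theoretical (cohesive) strength, Griffith/Irwin critical stresses,
and the bite-pressure-to-critical-stress ratio. All computation is in SI
units (Pa, m, J/m^2); fracture toughness is accepted in the conventional
MPa*sqrt(m) at the interface and converted.

Enamel fracture toughness is strongly anisotropic: K_Ic is about
1.24 MPa*sqrt(m) across the hydroxyapatite crystallite orientation and about
0.70 MPa*sqrt(m) in plane, which is why crack planes favour particular
directions. Surface energy gamma and the interplanar spacing a0 have no
consensus values for enamel and remain user inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MPA_SQRT_M = 1.0e6  # Pa*sqrt(m) per MPa*sqrt(m)
STANDARD_GRAVITY = 9.81  # m/s^2; use g=10 for order-of-magnitude estimates


@dataclass
class MaterialConstants:
    """Material constants for enamel fracture estimates (SI)."""

    K_Ic_perp_MPa_sqrt_m: float = 1.24  # across crystallite orientation
    K_Ic_par_MPa_sqrt_m: float = 0.70   # in plane
    E_Pa: float = 100e9                 # Young's modulus (enamel ~70-120 GPa)
    gamma_J_m2: float | None = None     # surface energy per area
    a0_m: float | None = None           # intra-atomic plane distance

    def __post_init__(self) -> None:
        for v in (self.K_Ic_perp_MPa_sqrt_m, self.K_Ic_par_MPa_sqrt_m, self.E_Pa):
            if not v > 0:
                raise ValueError("material constants must be positive")

    @property
    def K_Ic_perp(self) -> float:
        return self.K_Ic_perp_MPa_sqrt_m * MPA_SQRT_M

    @property
    def K_Ic_par(self) -> float:
        return self.K_Ic_par_MPa_sqrt_m * MPA_SQRT_M


def _positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


def stress_concentration(sigma: float, l_c: float, l_rho: float) -> float:
    """Stress at the tip of an elliptical flaw: sigma_max = 2 sigma sqrt(l_c / l_rho).

    ``l_c`` is the flaw half-length and ``l_rho`` the tip curvature radius (m).
    """
    _positive(sigma=sigma, l_c=l_c, l_rho=l_rho)
    return 2.0 * sigma * np.sqrt(l_c / l_rho)


def theoretical_strength(gamma: float, E: float, a0: float) -> float:
    """Cohesive strength sigma_th = sqrt(gamma E / a0)."""
    _positive(gamma=gamma, E=E, a0=a0)
    return float(np.sqrt(gamma * E / a0))


def approx_theoretical_strength(E: float) -> float:
    """The common approximation sigma_th ~ E / (2 pi)."""
    _positive(E=E)
    return E / (2.0 * np.pi)


def critical_stress_linear(K_Ic: float, l: float) -> float:
    """Irwin criterion for a linear crack of length ``l``: sigma_c = K_Ic / sqrt(pi l)."""
    _positive(K_Ic=K_Ic, l=l)
    return K_Ic / np.sqrt(np.pi * l)


def critical_stress_elliptical(K_Ic: float, l: float) -> float:
    """Elliptical-crack criterion K_Ic = (2/pi) sigma_c sqrt(pi l), inverted:
    sigma_c = (pi/2) K_Ic / sqrt(pi l) — exactly pi/2 times the linear value."""
    _positive(K_Ic=K_Ic, l=l)
    return (np.pi / 2.0) * K_Ic / np.sqrt(np.pi * l)


def griffith_elliptical(gamma: float, E: float, l: float) -> float:
    """Griffith energy balance for an elliptical crack: sigma_c = sqrt(2 gamma E / (pi l))."""
    _positive(gamma=gamma, E=E, l=l)
    return float(np.sqrt(2.0 * gamma * E / (np.pi * l)))


def bite_pressure(mass_kg: float = 100.0, area_m2: float = 1e-4,
                  g: float = 10.0) -> float:
    """Pressure of a bite of ``mass_kg`` concentrated on ``area_m2``.

    Defaults give the canonical order-of-magnitude figure: 100 kg on a
    1 cm^2 single-tooth contact at g = 10 m/s^2 -> 1e7 Pa.
    """
    _positive(mass_kg=mass_kg, area_m2=area_m2, g=g)
    return mass_kg * g / area_m2


def stress_ratio(pressure_Pa: float, sigma_c_Pa: float) -> float:
    """Applied pressure as a percentage of the critical stress."""
    _positive(pressure_Pa=pressure_Pa, sigma_c_Pa=sigma_c_Pa)
    return 100.0 * pressure_Pa / sigma_c_Pa
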