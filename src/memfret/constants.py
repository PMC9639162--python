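"""Physical constants and the unit conversions used throughout the pipeline.

All internal arithmetic is carried out in SI: energies in J, dipoles in C·m,
distances in m.  Spectroscopic units (eV, cm⁻¹, Debye, atomic units, Å) appear
only at module boundaries, so that squared couplings |V_DA|² come out directly
in kg² m⁴ s⁻⁴ (= J²) and are comparable with published tables without any
further scaling.

Constant values are taken from :mod:`scipy.constants` (CODATA) at full
precision; nothing is hand-rounded inside formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _sc

__all__ = [
    "Constants",
    "CONSTANTS",
    "EPSILON_0",
    "HBAR",
    "PLANCK",
    "LIGHT_SPEED",
    "K_B",
    "COULOMB_METER_PER_DEBYE",
    "COULOMB_METER_PER_AU",
    "DEBYE_PER_AU",
    "HC_JCM",
    "EV_PER_WAVENUMBER",
    "WAVENUMBER_PER_EV",
    "KJ_PER_MOL_TO_J",
    "HARTREE_TO_J",
    "ANGSTROM",
    "dipole_strength_au2_to_SI",
    "dipole_strength_au2_to_debye",
    "debye_to_coulomb_meter",
    "ev_to_wavenumber",
    "wavenumber_to_ev",
    "ev_to_joule",
    "joule_to_ev",
    "wavenumber_to_joule",
    "joule_to_wavenumber",
    "coupling_J_to_wavenumber",
    "rate_to_lifetime",
    "fwhm_to_sigma",
]

# 1 Debye = 1e-21 / c  C·m (exact in terms of the defined speed of light)
_DEBYE_SI = 1e-21 / _sc.c
# atomic unit of electric dipole moment: e * a0
_AU_DIPOLE_SI = _sc.e * _sc.physical_constants["Bohr radius"][0]


@dataclass(frozen=True)
class Constants:
    """CODATA physical constants in SI, plus the two derived products the
    rate expressions need (Debye/atomic-unit dipole conversion and h·c in
    J·cm for cm⁻¹ ↔ J)."""

    vacuum_permittivity: float = _sc.epsilon_0          # F m^-1
    reduced_planck: float = _sc.hbar                    # J s
    planck: float = _sc.h                               # J s
    light_speed: float = _sc.c                          # m s^-1
    boltzmann: float = _sc.k                            # J K^-1
    debye_per_au: float = _AU_DIPOLE_SI / _DEBYE_SI     # D per atomic unit
    hc_Jcm: float = field(default=_sc.h * _sc.c * 100.0)  # J cm

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"constant {name} must be positive")


CONSTANTS = Constants()

EPSILON_0 = CONSTANTS.vacuum_permittivity
HBAR = CONSTANTS.reduced_planck
PLANCK = CONSTANTS.planck
LIGHT_SPEED = CONSTANTS.light_speed
K_B = CONSTANTS.boltzmann
COULOMB_METER_PER_DEBYE = _DEBYE_SI
COULOMB_METER_PER_AU = _AU_DIPOLE_SI
DEBYE_PER_AU = CONSTANTS.debye_per_au
HC_JCM = CONSTANTS.hc_Jcm

# 1 cm^-1 in eV, and its inverse
EV_PER_WAVENUMBER = HC_JCM / _sc.e
WAVENUMBER_PER_EV = 1.0 / EV_PER_WAVENUMBER

KJ_PER_MOL_TO_J = 1e3 / _sc.N_A
HARTREE_TO_J = _sc.physical_constants["Hartree energy"][0]
ANGSTROM = 1e-10  # m


def dipole_strength_au2_to_SI(mu2):
    """Convert a transition dipole strength |μ|² from au² to C² m²."""
    mu2 = np.asarray(mu2, dtype=float)
    if np.any(mu2 < 0):
        raise ValueError("dipole strength must be non-negative")
    out = mu2 * COULOMB_METER_PER_AU**2
    return out.item() if out.ndim == 0 else out


def dipole_strength_au2_to_debye(mu2):
    """|μ| in Debye for a dipole strength |μ|² given in au²."""
    mu2 = np.asarray(mu2, dtype=float)
    if np.any(mu2 < 0):
        raise ValueError("dipole strength must be non-negative")
    out = np.sqrt(mu2) * DEBYE_PER_AU
    return out.item() if out.ndim == 0 else out


def debye_to_coulomb_meter(mu_debye):
    return np.asarray(mu_debye, dtype=float) * COULOMB_METER_PER_DEBYE


def ev_to_wavenumber(e_ev):
    return np.asarray(e_ev, dtype=float) * WAVENUMBER_PER_EV


def wavenumber_to_ev(nu_cm):
    return np.asarray(nu_cm, dtype=float) * EV_PER_WAVENUMBER


def ev_to_joule(e_ev):
    return np.asarray(e_ev, dtype=float) * _sc.e


def joule_to_ev(e_j):
    return np.asarray(e_j, dtype=float) / _sc.e


def wavenumber_to_joule(nu_cm):
    return np.asarray(nu_cm, dtype=float) * HC_JCM


def joule_to_wavenumber(e_j):
    return np.asarray(e_j, dtype=float) / HC_JCM


def coupling_J_to_wavenumber(v_joule):
    """Express a coupling energy |V| (J) in cm⁻¹, the unit used for printed
    coupling magnitudes."""
    v = np.asarray(v_joule, dtype=float)
    if np.any(v < 0):
        raise ValueError("coupling magnitude must be non-negative")
    out = v / HC_JCM
    return out.item() if out.ndim == 0 else out


def rate_to_lifetime(k):
    """Lifetime τ = 1/k for a first-order rate constant k (s⁻¹)."""
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("rate must be positive to define a lifetime")
    out = 1.0 / k
    return out.item() if out.ndim == 0 else out


def fwhm_to_sigma(fwhm):
    """Gaussian standard deviation from a full width at half maximum."""
    fwhm = np.asarray(fwhm, dtype=float)
    if np.any(fwhm <= 0):
        raise ValueError("fwhm must be positive")
    out = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return out.item() if out.ndim == 0 else out
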