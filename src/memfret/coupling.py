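"""Screened point-dipole couplings between membrane-embedded chromophores.

The coupling between a donor and an acceptor transition dipole at distance r
along the membrane normal is

    V = κ |μ_D| |μ_A| / (4π ε₀ η² r³),      κ = μ̂_D·μ̂_A − 3 (μ̂_D·r̂)(μ̂_A·r̂)

with the solvent screening carried by the squared refractive index η².  A
membrane confines only the tilt ϕ of a TDM against its surface (the xy-plane);
the azimuth φ about the normal is free, so |V|² is averaged over a uniform
azimuth grid of the acceptor while the donor is kept fixed — by symmetry this
equals averaging both azimuths.  For TDMs parameterized by tilts only, the
average has the closed form

    ⟨κ²⟩_φ = ½ cos²ϕ_D cos²ϕ_A + 4 sin²ϕ_D sin²ϕ_A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM, COULOMB_METER_PER_DEBYE, EPSILON_0, dipole_strength_au2_to_SI

__all__ = [
    "MembraneFrameTDM",
    "CouplingGeometry",
    "kappa",
    "kappa2_azimuthal_mean",
    "kappa2_azimuthal_mean_vectors",
    "coupling_squared",
    "rotational_average_V2",
    "isotropic_kappa2",
    "kappa2_max_grid",
    "DEFAULT_REFRACTIVE_INDEX",
]

# experimental refractive index of a DPPC monolayer
DEFAULT_REFRACTIVE_INDEX = 1.478
_UNIT_TOL = 1e-8
Z_HAT = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class MembraneFrameTDM:
    """A TDM in the membrane frame: magnitude μ (C·m), tilt ϕ against the
    xy-plane (deg) and azimuth φ about the normal (deg).

    Vector form: μ · (cos ϕ cos φ, cos ϕ sin φ, sin ϕ).  Vectors start in the
    xz-plane (φ = 0) and are rotated about z during azimuthal sampling.
    """

    magnitude: float
    tilt_deg: float
    azimuth_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("dipole magnitude must be non-negative")
        if not -90.0 <= self.tilt_deg <= 90.0:
            raise ValueError("tilt must lie in [-90, 90] degrees")

    @classmethod
    def from_debye(cls, mu_debye: float, tilt_deg: float, azimuth_deg: float = 0.0):
        return cls(mu_debye * COULOMB_METER_PER_DEBYE, tilt_deg, azimuth_deg)

    @classmethod
    def from_strength_au2(cls, mu2_au2: float, tilt_deg: float, azimuth_deg: float = 0.0):
        return cls(float(np.sqrt(dipole_strength_au2_to_SI(mu2_au2))), tilt_deg, azimuth_deg)

    def unit_vector(self, azimuth_deg: float | None = None) -> np.ndarray:
        phi = np.radians(self.tilt_deg)
        az = np.radians(self.azimuth_deg if azimuth_deg is None else azimuth_deg)
        return np.array([np.cos(phi) * np.cos(az), np.cos(phi) * np.sin(az), np.sin(phi)])

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * self.unit_vector()


@dataclass(frozen=True)
class CouplingGeometry:
    """Donor–acceptor separation along the membrane normal and the screening
    refractive index."""

    r_angstrom: float
    eta: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self) -> None:
        if self.r_angstrom <= 0:
            raise ValueError("distance must be positive")
        if self.eta < 1:
            raise ValueError("refractive index must be >= 1")

    @classmethod
    def from_depths(cls, d_donor_angstrom: float, d_acceptor_angstrom: float,
                    eta: float = DEFAULT_REFRACTIVE_INDEX):
        return cls(d_donor_angstrom + d_acceptor_angstrom, eta)

    @property
    def r_meter(self) -> float:
        return self.r_angstrom * ANGSTROM

    @property
    def prefactor(self) -> float:
        """1 / (4π ε₀ η² r³) in SI; multiply by |μ_D||μ_A|κ to get V in J."""
        return 1.0 / (4 * np.pi * EPSILON_0 * self.eta**2 * self.r_meter**3)


def _require_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be a unit vector")
    return v


def kappa(mu_d_hat, mu_a_hat, r_hat) -> float:
    """Orientation factor κ = μ̂_D·μ̂_A − 3(μ̂_D·r̂)(μ̂_A·r̂) ∈ [−2, 2]."""
    d = _require_unit(mu_d_hat, "mu_d_hat")
    a = _require_unit(mu_a_hat, "mu_a_hat")
    r = _require_unit(r_hat, "r_hat")
    return float(d @ a - 3.0 * (d @ r) * (a @ r))


def kappa2_azimuthal_mean(tilt_d_deg, tilt_a_deg):
    """Closed-form azimuthal average ⟨κ²⟩ = ½cos²ϕ_D cos²ϕ_A + 4sin²ϕ_D sin²ϕ_A
    for TDMs at fixed tilts with r̂ along the membrane normal."""
    pd_ = np.radians(np.asarray(tilt_d_deg, dtype=float))
    pa = np.radians(np.asarray(tilt_a_deg, dtype=float))
    out = 0.5 * np.cos(pd_) ** 2 * np.cos(pa) ** 2 + 4.0 * np.sin(pd_) ** 2 * np.sin(pa) ** 2
    return out.item() if np.ndim(out) == 0 else out


def kappa2_azimuthal_mean_vectors(d_hat: np.ndarray, a_hat: np.ndarray) -> float:
    """Analytic azimuthal average of κ² for arbitrary unit vectors when the
    acceptor is rotated about z (r̂ = ẑ): with κ(φ) = A cos φ + B sin φ + C,
    ⟨κ²⟩ = (A² + B²)/2 + C²."""
    d = _require_unit(d_hat, "d_hat")
    a = _require_unit(a_hat, "a_hat")
    A = d[0] * a[0] + d[1] * a[1]
    B = d[1] * a[0] - d[0] * a[1]
    C = -2.0 * d[2] * a[2]
    return float(0.5 * (A * A + B * B) + C * C)


def coupling_squared(mu_d: np.ndarray, mu_a: np.ndarray, geom: CouplingGeometry,
                     r_hat=Z_HAT) -> float:
    """|V_DA|² (J², i.e. kg² m⁴ s⁻⁴) for two TDM vectors in C·m."""
    mu_d = np.asarray(mu_d, dtype=float).reshape(3)
    mu_a = np.asarray(mu_a, dtype=float).reshape(3)
    nd = np.linalg.norm(mu_d)
    na = np.linalg.norm(mu_a)
    if nd == 0.0 or na == 0.0:
        return 0.0
    k = kappa(mu_d / nd, mu_a / na, r_hat)
    v = k * nd * na * geom.prefactor
    return float(v * v)


def rotational_average_V2(
    donor: MembraneFrameTDM,
    acceptor: MembraneFrameTDM,
    geom: CouplingGeometry,
    azimuth_step_deg: float = 1.0,
) -> float:
    """⟨|V_DA|²⟩ over the acceptor azimuth grid (donor azimuth kept fixed).

    The default 1° grid covers a full period, so the discrete mean agrees with
    the analytic ⟨κ²⟩ closed form to machine precision.
    """
    if azimuth_step_deg <= 0:
        raise ValueError("azimuth step must be positive")
    phis = np.arange(0.0, 360.0, azimuth_step_deg)
    d_hat = donor.unit_vector()
    tilt = np.radians(acceptor.tilt_deg)
    az = np.radians(phis)
    a_hats = np.column_stack(
        [np.cos(tilt) * np.cos(az), np.cos(tilt) * np.sin(az), np.full_like(az, np.sin(tilt))]
    )
    kappas = a_hats @ d_hat - 3.0 * d_hat[2] * a_hats[:, 2]
    v = kappas * donor.magnitude * acceptor.magnitude * geom.prefactor
    return float(np.mean(v * v))


def isotropic_kappa2(n: int, rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo ⟨κ²⟩ for isotropically oriented donor and acceptor TDMs.

    Returns (mean, standard error); the analytic isotropic value is 2/3.
    """
    d = rng.normal(size=(n, 3))
    a = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    k = np.einsum("ij,ij->i", d, a) - 3.0 * d[:, 2] * a[:, 2]
    k2 = k * k
    return float(k2.mean()), float(k2.std(ddof=1) / np.sqrt(n))


def kappa2_max_grid(step_deg: float = 1.0) -> float:
    """Brute-force maximum of κ² over a uniform orientation grid.

    κ depends on the two polar angles against r̂ and the azimuth difference
    only, so the search runs over (θ_D, θ_A, Δφ); the supremum 4 is attained
    for both dipoles collinear with r̂.
    """
    theta = np.radians(np.arange(0.0, 180.0 + step_deg, step_deg))
    dphi = np.radians(np.arange(0.0, 360.0, step_deg))
    st, ct = np.sin(theta), np.cos(theta)
    best = 0.0
    cc = np.outer(ct, ct)
    ss = np.outer(st, st)
    for c in np.cos(dphi):
        k = ss * c - 2.0 * cc
        m = float(np.max(k * k))
        if m > best:
            best = m
    return best
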