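"""Transition dipole moments, molecular reference vectors and alignment
diagnostics.

A flexible chromophore's transition dipole moment (TDM) cannot be tracked in a
classical trajectory, but its orientation can be proxied by a vector built
from atomic positions (for a rigid planar dye, simply the N–N connecting
vector; for a tris-bipyridine complex, signed linear combinations of the six
nitrogen positions giving one vector along and one perpendicular to the C₂
axis).  This module maps TDMs onto such reference vectors and quantifies the
quality of the mapping via cos²θ diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionDipole",
    "ReferenceVectorSpec",
    "reference_vector",
    "cos2_alignment",
    "alignment_profile",
    "AlignmentProfile",
    "linearity_score",
    "check_orthogonality_defect",
]

_STRENGTH_RTOL = 1e-6


@dataclass
class TransitionDipole:
    """A labelled electronic transition: dipole vector (au), dipole strength
    |μ|² (au²) and vertical excitation energy (eV).

    If ``strength_au2`` is omitted it is computed from the vector; if both are
    supplied they must agree to 1e-6 relative.
    """

    state_label: str
    vector_au: np.ndarray
    strength_au2: float | None = None
    vertical_energy_ev: float | None = None

    def __post_init__(self) -> None:
        self.vector_au = np.asarray(self.vector_au, dtype=float).reshape(3)
        norm2 = float(self.vector_au @ self.vector_au)
        if self.strength_au2 is None:
            self.strength_au2 = norm2
        elif norm2 > 0:
            if abs(self.strength_au2 - norm2) > _STRENGTH_RTOL * max(norm2, self.strength_au2):
                raise ValueError(
                    f"{self.state_label}: strength {self.strength_au2} au² inconsistent "
                    f"with |vector|² = {norm2} au²"
                )
        if self.strength_au2 < 0:
            raise ValueError("dipole strength must be non-negative")

    @property
    def unit_vector(self) -> np.ndarray:
        n = np.linalg.norm(self.vector_au)
        if n == 0:
            raise ValueError(f"{self.state_label}: zero TDM has no direction")
        return self.vector_au / n


@dataclass(frozen=True)
class ReferenceVectorSpec:
    """v = Σ_k c_k · r_k over atom positions; e.g. ``[(0, 1.0), (1, -1.0)]``
    is the difference vector between the first two atoms."""

    atom_index_coefficients: tuple[tuple[int, float], ...]
    label: str = "ref"

    def __post_init__(self) -> None:
        coeffs = [(int(i), float(c)) for i, c in self.atom_index_coefficients]
        object.__setattr__(self, "atom_index_coefficients", tuple(coeffs))
        nonzero = [c for _, c in coeffs if c != 0.0]
        if len(nonzero) < 2:
            raise ValueError("a reference vector needs at least two nonzero coefficients")

    @property
    def translation_invariant(self) -> bool:
        return abs(sum(c for _, c in self.atom_index_coefficients)) < 1e-12


def reference_vector(geometry: np.ndarray, spec: ReferenceVectorSpec) -> np.ndarray:
    """Evaluate Σ c_k r_k (not normalized) on an (N, 3) coordinate array (Å)."""
    geometry = np.asarray(geometry, dtype=float)
    if geometry.ndim != 2 or geometry.shape[1] != 3:
        raise ValueError("geometry must be an (N, 3) array")
    n = geometry.shape[0]
    v = np.zeros(3)
    for idx, coeff in spec.atom_index_coefficients:
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n} atoms ({spec.label})")
        v += coeff * geometry[idx]
    return v


def cos2_alignment(tdm, ref) -> float:
    """Squared cosine of the angle between two vectors (sign-blind).

    Invariant under rescaling of either vector and under a global rotation.
    """
    a = np.asarray(tdm, dtype=float).reshape(3)
    b = np.asarray(ref, dtype=float).reshape(3)
    na2 = float(a @ a)
    nb2 = float(b @ b)
    if na2 == 0.0 or nb2 == 0.0:
        raise ValueError("cannot compute alignment with a zero vector")
    return float((a @ b) ** 2 / (na2 * nb2))


def linearity_score(sorted_values: np.ndarray) -> float:
    """R² of the best straight line through a sorted cos²θ curve.

    An ensemble of randomly oriented TDMs yields a near-linear sorted curve
    (score close to 1); a population split between "aligned" and "orthogonal"
    yields a sigmoid/step curve and a visibly lower score.  A constant curve
    (perfect alignment) carries no linear trend and scores 0.
    """
    y = np.sort(np.asarray(sorted_values, dtype=float))
    n = y.size
    if n < 2 or np.ptp(y) < 1e-12:
        return 0.0
    x = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class AlignmentProfile:
    """Per-state alignment diagnostics against the ∥ and ⊥ reference vectors."""

    state_label: str
    n_parallel: int
    n_perpendicular: int
    sorted_parallel: np.ndarray
    sorted_perpendicular: np.ndarray
    linearity_parallel: float
    linearity_perpendicular: float


def alignment_profile(
    cos2_by_state: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, AlignmentProfile]:
    """Summarize cos²θ_∥ / cos²θ_⊥ ensembles per electronic state.

    For each state: how many conformers are dominated by the parallel vs the
    perpendicular reference vector (ties count as parallel and are logged),
    the sorted diagnostic curves, and a linearity score separating disordered
    (near-linear) from well-aligned (sigmoid/step) populations.
    """
    if not cos2_by_state:
        raise ValueError("no states supplied")
    out: dict[str, AlignmentProfile] = {}
    for state, (c_par, c_perp) in cos2_by_state.items():
        par = np.asarray(c_par, dtype=float)
        perp = np.asarray(c_perp, dtype=float)
        if par.size == 0 or par.shape != perp.shape:
            raise ValueError(f"{state}: parallel/perpendicular arrays must be equal, non-empty")
        ties = int(np.sum(par == perp))
        if ties:
            logger.info("%s: %d ties in dominance counts broken toward the parallel vector",
                        state, ties)
        n_par = int(np.sum(par >= perp))
        out[state] = AlignmentProfile(
            state_label=state,
            n_parallel=n_par,
            n_perpendicular=par.size - n_par,
            sorted_parallel=np.sort(par),
            sorted_perpendicular=np.sort(perp),
            linearity_parallel=linearity_score(par),
            linearity_perpendicular=linearity_score(perp),
        )
    return out


def check_orthogonality_defect(cos2_par, cos2_perp, threshold: float = 0.1):
    """Defect |cos²θ_∥ + cos²θ_⊥ − 1| per conformer, with a flag above threshold.

    For exactly perpendicular reference vectors and a TDM in their plane the
    defect is zero; out-of-plane TDM components and distorted (non-orthogonal)
    reference vectors both inflate it.
    """
    par = np.asarray(cos2_par, dtype=float)
    perp = np.asarray(cos2_perp, dtype=float)
    if np.any((par < 0) | (par > 1)) or np.any((perp < 0) | (perp > 1)):
        raise ValueError("cos² values must lie in [0, 1]")
    defect = np.abs(par + perp - 1.0)
    return defect, defect > threshold
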