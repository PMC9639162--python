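"""Boltzmann weighting of conformer ensembles.

Flexible chromophores (long alkyl tails) require ensemble averaging: every
photophysical property p is reported as the Boltzmann expectation
⟨p⟩ = Σ_i w_i p_i with w_i ∝ exp(−E_i / k_B T) over the conformer ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax

from .constants import HARTREE_TO_J, K_B, KJ_PER_MOL_TO_J
from .tdm import TransitionDipole

__all__ = [
    "Conformer",
    "WeightedEnsemble",
    "boltzmann_weights",
    "ensemble_expectation",
    "read_conformer_energies",
]

DEFAULT_TEMPERATURE_K = 298.15

_ENERGY_COLUMNS = {
    "energy_j": 1.0,
    "energy_kj_mol": KJ_PER_MOL_TO_J,
    "energy_hartree": HARTREE_TO_J,
}


@dataclass
class Conformer:
    """One member of a conformational ensemble: a relative energy (J, vs the
    ensemble minimum), its electronic transitions and optionally its geometry."""

    id: str
    relative_energy: float
    transitions: list[TransitionDipole] = field(default_factory=list)
    geometry: np.ndarray | None = None


def boltzmann_weights(energies, temperature: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
    """Normalized Boltzmann weights w_i = exp(−E_i/kT) / Σ_j exp(−E_j/kT).

    Energies in J (any common offset cancels). Evaluated with the max-shift
    (softmax) trick so large energy spreads cannot underflow the normalization.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("energies must be non-empty")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return softmax(-e / (K_B * temperature))


def ensemble_expectation(values, weights) -> float:
    """Weighted expectation ⟨p⟩ = Σ w_i p_i over the ensemble."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError(f"length mismatch: {v.shape} values vs {w.shape} weights")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights are not normalized")
    return float(w @ v)


@dataclass
class WeightedEnsemble:
    """Conformers with their Boltzmann weights at a given temperature."""

    conformers: list[Conformer]
    weights: np.ndarray
    temperature: float

    @classmethod
    def from_conformers(
        cls, conformers: Sequence[Conformer], temperature: float = DEFAULT_TEMPERATURE_K
    ) -> "WeightedEnsemble":
        energies = [c.relative_energy for c in conformers]
        return cls(list(conformers), boltzmann_weights(energies, temperature), temperature)

    def expectation(self, values) -> float:
        return ensemble_expectation(values, self.weights)

    def top_weight_fraction(self, n: int) -> float:
        """Summed weight of the n highest-weighted conformers."""
        return float(np.sort(self.weights)[::-1][:n].sum())


def read_conformer_energies(path: str | Path) -> pd.DataFrame:
    """Read a delimited (conformer id, relative energy) table.

    The energy unit is declared by the column name: ``energy_kj_mol``,
    ``energy_hartree`` or ``energy_j``.  Returns a frame with columns
    ``conformer`` and ``energy_j`` (shifted so the minimum is zero).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "conformer" not in df.columns:
        raise ValueError(f"{path}: missing 'conformer' column")
    for col, factor in _ENERGY_COLUMNS.items():
        if col in df.columns:
            e = df[col].to_numpy(dtype=float) * factor
            break
    else:
        raise ValueError(
            f"{path}: no energy column; expected one of {sorted(_ENERGY_COLUMNS)}"
        )
    return pd.DataFrame({"conformer": df["conformer"], "energy_j": e - e.min()})
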