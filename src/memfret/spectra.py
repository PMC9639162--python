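"""Gaussian line shapes and spectral overlap integrals.

Stick spectra (vertical excitation energies + intensities) are convoluted
with Gaussians of a given fwhm into continuous spectra; the spectral overlap

    J = ∫ f_D(ν̃) f_A(ν̃) dν̃

of the unit-area donor emission and acceptor absorption line shapes is then
evaluated either numerically on a wavenumber grid or, for a single pair of
Gaussians, in closed form.  All spectra live on a wavenumber axis (cm⁻¹) so
that J carries the unit cm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import ev_to_wavenumber, fwhm_to_sigma

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "convolve_sticks",
    "overlap_numeric",
    "overlap_gaussian_pair",
    "read_sticks",
    "read_spectrum",
    "write_spectrum",
]

DEFAULT_GRID_STEP_CM = 1.0
GRID_PAD_FWHM = 5.0
_NORM_TOL = 1e-6


@dataclass
class Spectrum:
    """Intensity density per cm⁻¹ on a uniform ascending wavenumber grid."""

    axis: np.ndarray
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity must be matching 1-D arrays")
        if self.axis.size < 2 or np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be ascending with at least two points")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def step(self) -> float:
        return float(self.axis[1] - self.axis[0])

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.axis))

    def normalize(self) -> "Spectrum":
        """Return a unit-area copy (trapezoidal integral = 1)."""
        a = self.area()
        if a <= 0:
            raise ValueError("cannot normalize a spectrum with zero area")
        return replace(self, intensity=self.intensity / a, normalized=True)


def convolve_sticks(
    energies_ev,
    intensities,
    fwhm_ev: float,
    *,
    weights=None,
    shift_ev: float = 0.0,
    grid: np.ndarray | None = None,
    grid_step_cm: float = DEFAULT_GRID_STEP_CM,
) -> Spectrum:
    """Sum of unit-area Gaussians (σ = fwhm / 2√(2 ln 2)) centered at each
    stick, weighted by intensity × weight.

    ``shift_ev`` is an explicit, logged rigid shift applied to the stick
    energies before convolution (to match an experimental band position); it
    is never inferred.  If no grid is given one is built spanning all sticks
    ± 5 fwhm at ``grid_step_cm``; a supplied grid must cover that span.
    """
    e = np.asarray(energies_ev, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if e.size == 0 or e.shape != i.shape:
        raise ValueError("energies and intensities must be matching non-empty arrays")
    if np.any(i < 0):
        raise ValueError("stick intensities must be non-negative")
    if fwhm_ev <= 0:
        raise ValueError("fwhm must be positive")
    w = np.ones_like(e) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != e.shape:
        raise ValueError("weights must match the stick list")

    if shift_ev != 0.0:
        logger.info("applying rigid spectral shift of %+.3f eV to %d sticks", shift_ev, e.size)
        e = e + shift_ev

    centers_cm = ev_to_wavenumber(e)
    sigma_cm = fwhm_to_sigma(ev_to_wavenumber(fwhm_ev))
    pad = GRID_PAD_FWHM * ev_to_wavenumber(fwhm_ev)

    if grid is None:
        grid = np.arange(centers_cm.min() - pad, centers_cm.max() + pad + grid_step_cm,
                         grid_step_cm)
    else:
        grid = np.asarray(grid, dtype=float)
        lo, hi = grid[0], grid[-1]
        for k, c in enumerate(centers_cm):
            if c - pad < lo or c + pad > hi:
                raise ValueError(
                    f"grid [{lo:.1f}, {hi:.1f}] cm⁻¹ truncates stick {k} at "
                    f"{c:.1f} cm⁻¹ (needs ±{pad:.1f} cm⁻¹)"
                )

    gauss = np.exp(-((grid[None, :] - centers_cm[:, None]) ** 2) / (2 * sigma_cm**2))
    gauss /= sigma_cm * np.sqrt(2 * np.pi)
    intensity = (i * w) @ gauss
    return Spectrum(axis=grid, intensity=intensity)


def overlap_numeric(donor_emission: Spectrum, acceptor_absorption: Spectrum) -> float:
    """Spectral overlap J = ∫ f_D f_A dν̃ (cm) of two unit-area spectra.

    The spectra are resampled onto their common wavenumber window at the finer
    of the two grid steps; disjoint spectra overlap to zero.
    """
    for name, s in (("donor", donor_emission), ("acceptor", acceptor_absorption)):
        if not s.normalized:
            raise ValueError(f"{name} spectrum is not normalized to unit area")
    lo = max(donor_emission.axis[0], acceptor_absorption.axis[0])
    hi = min(donor_emission.axis[-1], acceptor_absorption.axis[-1])
    if hi <= lo:
        return 0.0
    step = min(donor_emission.step, acceptor_absorption.step)
    grid = np.arange(lo, hi + step, step)
    f_d = np.interp(grid, donor_emission.axis, donor_emission.intensity, left=0.0, right=0.0)
    f_a = np.interp(grid, acceptor_absorption.axis, acceptor_absorption.intensity,
                    left=0.0, right=0.0)
    return float(np.trapezoid(f_d * f_a, grid))


def overlap_gaussian_pair(e_d_ev, fwhm_d_ev, e_a_ev, fwhm_a_ev):
    """Closed-form overlap (cm) of two unit-area Gaussians on the wavenumber
    axis, centered at the two vertical excitation energies:

        J = exp(−Δν̃² / 2(σ_D² + σ_A²)) / √(2π (σ_D² + σ_A²))

    Broadcasts over array inputs (used per snapshot pair and state).
    """
    if np.any(np.asarray(fwhm_d_ev) <= 0) or np.any(np.asarray(fwhm_a_ev) <= 0):
        raise ValueError("fwhm must be positive")
    d_cm = ev_to_wavenumber(np.asarray(e_d_ev, dtype=float))
    a_cm = ev_to_wavenumber(np.asarray(e_a_ev, dtype=float))
    sig_d = fwhm_to_sigma(ev_to_wavenumber(fwhm_d_ev))
    sig_a = fwhm_to_sigma(ev_to_wavenumber(fwhm_a_ev))
    var = sig_d**2 + sig_a**2
    out = np.exp(-((d_cm - a_cm) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
    return out.item() if np.ndim(out) == 0 else out


def read_sticks(path: str | Path) -> pd.DataFrame:
    """Read a delimited stick list with columns ``energy_ev``, ``intensity``
    and optionally ``weight`` and ``conformer``."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"energy_ev", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_spectrum(path: str | Path, normalized: bool = False) -> Spectrum:
    """Read a two-column (wavenumber_cm, intensity) delimited curve."""
    arr = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    return Spectrum(axis=arr[:, 0], intensity=arr[:, 1], normalized=normalized)


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    header = "wavenumber_cm intensity" + (" (unit area)" if spectrum.normalized else "")
    np.savetxt(path, np.column_stack([spectrum.axis, spectrum.intensity]), header=header)
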