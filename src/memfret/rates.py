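"""FRET rate assembly: the golden-rule rate expression, the two-step
(ensemble photophysics × membrane geometry statistics) protocol and the
one-step (per-snapshot pairing) protocol.

The per-state transfer rate is

    k_FRET = (2π/ħ) |V_DA|² · J / (h c)

with |V_DA|² in J² and the spectral overlap J in cm (h·c taken in J·cm), and
the total rate is the sum over acceptor states.  In the one-step protocol the
rate is evaluated for every donor × acceptor snapshot pair — distance, TDMs
and per-pair Gaussian overlap together — and only the final rates are
averaged; averaging the interaction factors first and composing afterwards
would miss correlated close-approach arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import (
    ANGSTROM,
    COULOMB_METER_PER_AU,
    EPSILON_0,
    HBAR,
    HC_JCM,
    coupling_J_to_wavenumber,
)
from .coupling import (
    DEFAULT_REFRACTIVE_INDEX,
    CouplingGeometry,
    MembraneFrameTDM,
    rotational_average_V2,
)
from .spectra import overlap_gaussian_pair
from .tdm import TransitionDipole

__all__ = [
    "fret_rate",
    "RateBreakdown",
    "AcceptorState",
    "two_step_total",
    "merge_degenerate_states",
    "SnapshotRecord",
    "OneStepResult",
    "one_step_total",
    "read_snapshots",
    "write_snapshots",
    "snapshots_to_frame",
]

DEFAULT_FWHM_DONOR_EV = 0.05
DEFAULT_FWHM_ACCEPTOR_EV = 0.2


def fret_rate(v2, j_overlap_cm):
    """Golden-rule rate k = (2π/ħ) |V|² (J/hc) in s⁻¹.

    ``v2`` in J² (kg² m⁴ s⁻⁴), ``j_overlap_cm`` in cm.  Broadcasts.
    """
    v2 = np.asarray(v2, dtype=float)
    j = np.asarray(j_overlap_cm, dtype=float)
    if np.any(v2 < 0) or np.any(j < 0):
        raise ValueError("|V|² and J must be non-negative")
    out = (2.0 * np.pi / HBAR) * v2 * (j / HC_JCM)
    return out.item() if out.ndim == 0 else out


@dataclass
class RateBreakdown:
    """Per-state coupling/overlap/rate table plus totals.

    ``table`` columns: V2_J2, V_cm, J_cm, k_fret_s, tau_s (index: state label).
    """

    table: pd.DataFrame
    k_total: float
    tau_total: float

    @classmethod
    def from_states(cls, labels: Sequence[str], v2: np.ndarray, j_cm: np.ndarray):
        v2 = np.asarray(v2, dtype=float)
        j_cm = np.asarray(j_cm, dtype=float)
        k = fret_rate(v2, j_cm)
        k = np.atleast_1d(k)
        table = pd.DataFrame(
            {
                "V2_J2": v2,
                "V_cm": coupling_J_to_wavenumber(np.sqrt(v2)),
                "J_cm": j_cm,
                "k_fret_s": k,
                "tau_s": np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), np.inf),
            },
            index=pd.Index(labels, name="state"),
        )
        k_total = float(k.sum())
        tau_total = 1.0 / k_total if k_total > 0 else np.inf
        return cls(table=table, k_total=k_total, tau_total=tau_total)


@dataclass(frozen=True)
class AcceptorState:
    """Two-step input for one acceptor state: Boltzmann-weighted dipole
    strength (Debye), membrane tilt of the mapped TDM (deg) and the spectral
    overlap with the donor emission (cm)."""

    label: str
    strength_debye: float
    tilt_deg: float
    overlap_cm: float | None = None


def merge_degenerate_states(states: Sequence[AcceptorState],
                            groups: Iterable[Sequence[str]]) -> list[AcceptorState]:
    """Average strength and overlap within each declared near-degenerate group
    while keeping each member's own TDM orientation.

    Two states that swap electronic character across the conformer ensemble
    cannot be assigned individual strengths/overlaps; they share the averages
    but retain distinct (mutually orthogonal-ish) orientations.
    """
    by_label = {s.label: s for s in states}
    out = dict(by_label)
    for group in groups:
        members = [by_label[g] for g in group]
        mean_strength = float(np.mean([m.strength_debye for m in members]))
        overlaps = [m.overlap_cm for m in members]
        mean_overlap = None if any(o is None for o in overlaps) else float(np.mean(overlaps))
        for m in members:
            out[m.label] = AcceptorState(m.label, mean_strength, m.tilt_deg, mean_overlap)
    return [out[s.label] for s in states]


def two_step_total(
    donor_strength_debye: float,
    donor_tilt_deg: float,
    states: Sequence[AcceptorState],
    geom: CouplingGeometry,
    azimuth_step_deg: float = 1.0,
) -> RateBreakdown:
    """Two-step protocol: per state, azimuthally averaged |V_DA|² from the
    membrane-frame TDMs, then the golden-rule rate with the supplied spectral
    overlap; the total rate is the sum over states."""
    if not states:
        raise ValueError("at least one acceptor state is required")
    donor = MembraneFrameTDM.from_debye(donor_strength_debye, donor_tilt_deg)
    v2 = np.empty(len(states))
    j = np.empty(len(states))
    for idx, s in enumerate(states):
        if s.overlap_cm is None:
            raise ValueError(f"state {s.label}: missing spectral overlap")
        acceptor = MembraneFrameTDM.from_debye(s.strength_debye, s.tilt_deg)
        v2[idx] = rotational_average_V2(donor, acceptor, geom, azimuth_step_deg)
        j[idx] = s.overlap_cm
    return RateBreakdown.from_states([s.label for s in states], v2, j)


@dataclass
class SnapshotRecord:
    """One QM/MM snapshot of a chromophore: membrane depth plus per-state
    transition dipoles in the membrane frame (z = membrane normal)."""

    chromophore: str
    frame: int
    depth_angstrom: float
    transitions: dict[str, TransitionDipole]
    role: str = "acceptor"  # "donor" or "acceptor"

    def __post_init__(self) -> None:
        if self.depth_angstrom <= 0:
            raise ValueError("depth must be positive")
        if self.role not in ("donor", "acceptor"):
            raise ValueError("role must be 'donor' or 'acceptor'")
        if self.role == "donor" and len(self.transitions) != 1:
            raise ValueError("a donor snapshot carries exactly one emissive transition")

    @property
    def emission(self) -> TransitionDipole:
        if self.role != "donor":
            raise ValueError("emission is defined for donor snapshots only")
        return next(iter(self.transitions.values()))


@dataclass
class OneStepResult:
    """Mean FRET rate over all donor × acceptor snapshot pairs with per-state
    mean diagnostics (means of the per-pair values, never rates of means)."""

    k_mean: float
    tau_mean: float
    n_pairs: int
    per_state: pd.DataFrame  # index state; columns mean_V2_J2, mean_J_cm, mean_k_s
    pair_rates: np.ndarray = field(repr=False)  # (n_donor, n_acceptor) total rate


def _stack_transitions(snaps: Sequence[SnapshotRecord], labels: Sequence[str]):
    """(n_snap, n_state) arrays of |μ| (C·m), unit vectors and energies (eV)."""
    n, m = len(snaps), len(labels)
    mu = np.zeros((n, m))
    uhat = np.zeros((n, m, 3))
    e = np.zeros((n, m))
    for i, snap in enumerate(snaps):
        for j, lab in enumerate(labels):
            if lab not in snap.transitions:
                raise ValueError(
                    f"state {lab} missing from {snap.chromophore} frame {snap.frame}"
                )
            t = snap.transitions[lab]
            if t.vertical_energy_ev is None:
                raise ValueError(f"state {lab}: vertical energy required for overlap")
            mu[i, j] = np.sqrt(t.strength_au2) * COULOMB_METER_PER_AU
            norm = np.linalg.norm(t.vector_au)
            uhat[i, j] = t.vector_au / norm if norm > 0 else 0.0
            e[i, j] = t.vertical_energy_ev
    return mu, uhat, e


def one_step_total(
    donor_snaps: Sequence[SnapshotRecord],
    acceptor_snaps: Sequence[SnapshotRecord],
    state_labels: Sequence[str] | None = None,
    fwhm_donor_ev: float = DEFAULT_FWHM_DONOR_EV,
    fwhm_acceptor_ev: float = DEFAULT_FWHM_ACCEPTOR_EV,
    eta: float = DEFAULT_REFRACTIVE_INDEX,
    azimuth_step_deg: float = 1.0,
) -> OneStepResult:
    """One-step protocol over the full Cartesian product of snapshots.

    For each pair (i, j): the interchromophoric distance is the sum of the two
    membrane depths, r_ij = d_i + d_j along the normal; the acceptor TDMs are
    rotated about the normal on the azimuth grid (donor fixed); the per-state
    overlap is the closed-form Gaussian pair overlap of the two vertical
    energies; and the pair rate is the sum of per-state golden-rule rates.
    The reported rate is the arithmetic mean of the pair rates, and the
    per-state diagnostics are means of the per-pair |V|², J and k.

    No spectral shift is applied: snapshot energies enter as computed.
    """
    if not donor_snaps or not acceptor_snaps:
        raise ValueError("snapshot sets must be non-empty")
    if azimuth_step_deg <= 0:
        raise ValueError("azimuth step must be positive")
    if state_labels is None:
        state_labels = sorted(acceptor_snaps[0].transitions)

    mu_d = np.array([np.sqrt(s.emission.strength_au2) * COULOMB_METER_PER_AU
                     for s in donor_snaps])
    d_hat = np.array([s.emission.unit_vector for s in donor_snaps])
    e_d = np.array([s.emission.vertical_energy_ev for s in donor_snaps])
    if np.any(np.equal(e_d, None)):
        raise ValueError("donor snapshots need vertical energies")
    d_depth = np.array([s.depth_angstrom for s in donor_snaps])

    mu_a, a_hat, e_a = _stack_transitions(acceptor_snaps, state_labels)
    a_depth = np.array([s.depth_angstrom for s in acceptor_snaps])

    # screened point-dipole prefactor per pair: 1/(4πε0 η² r³)
    r_m = (d_depth[:, None] + a_depth[None, :]) * ANGSTROM
    pref = 1.0 / (4 * np.pi * EPSILON_0 * eta**2 * r_m**3)

    # azimuthal mean of κ² per (donor i, acceptor j, state s), accumulated
    # over the rotation grid of the acceptor about the membrane normal
    phis = np.radians(np.arange(0.0, 360.0, azimuth_step_deg))
    A = np.einsum("id,jsd->ijs", d_hat[:, :2], a_hat[:, :, :2])  # in-plane dot
    B = (d_hat[:, 1][:, None, None] * a_hat[None, :, :, 0]
         - d_hat[:, 0][:, None, None] * a_hat[None, :, :, 1])
    C = -2.0 * d_hat[:, 2][:, None, None] * a_hat[None, :, :, 2]
    k2_mean = np.zeros_like(A)
    for phi in phis:
        k = A * np.cos(phi) + B * np.sin(phi) + C
        k2_mean += k * k
    k2_mean /= phis.size

    v2 = k2_mean * (mu_d[:, None, None] * mu_a[None, :, :] * pref[:, :, None]) ** 2
    j_cm = overlap_gaussian_pair(e_d[:, None, None], fwhm_donor_ev,
                                 e_a[None, :, :], fwhm_acceptor_ev)
    k_state = fret_rate(v2, j_cm)
    pair_rates = k_state.sum(axis=2)

    per_state = pd.DataFrame(
        {
            "mean_V2_J2": v2.mean(axis=(0, 1)),
            "mean_J_cm": np.broadcast_to(j_cm, v2.shape).mean(axis=(0, 1)),
            "mean_k_s": k_state.mean(axis=(0, 1)),
        },
        index=pd.Index(state_labels, name="state"),
    )
    k_mean = float(pair_rates.mean())
    return OneStepResult(
        k_mean=k_mean,
        tau_mean=1.0 / k_mean if k_mean > 0 else np.inf,
        n_pairs=pair_rates.size,
        per_state=per_state,
        pair_rates=pair_rates,
    )


_SNAPSHOT_COLUMNS = [
    "chromophore", "role", "frame", "depth_angstrom", "state",
    "energy_ev", "mu_x_au", "mu_y_au", "mu_z_au", "strength_au2",
]


def snapshots_to_frame(snaps: Sequence[SnapshotRecord]) -> pd.DataFrame:
    rows = []
    for s in snaps:
        for lab, t in s.transitions.items():
            rows.append({
                "chromophore": s.chromophore, "role": s.role, "frame": s.frame,
                "depth_angstrom": s.depth_angstrom, "state": lab,
                "energy_ev": t.vertical_energy_ev,
                "mu_x_au": t.vector_au[0], "mu_y_au": t.vector_au[1],
                "mu_z_au": t.vector_au[2], "strength_au2": t.strength_au2,
            })
    return pd.DataFrame(rows, columns=_SNAPSHOT_COLUMNS)


def write_snapshots(path: str | Path, snaps: Sequence[SnapshotRecord]) -> None:
    snapshots_to_frame(snaps).to_csv(path, index=False)


def read_snapshots(path: str | Path) -> list[SnapshotRecord]:
    """Read the per-snapshot transition table written by :func:`write_snapshots`."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(_SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[SnapshotRecord] = []
    for (chrom, role, frame, depth), grp in df.groupby(
        ["chromophore", "role", "frame", "depth_angstrom"], sort=True
    ):
        transitions = {
            row.state: TransitionDipole(
                state_label=row.state,
                vector_au=np.array([row.mu_x_au, row.mu_y_au, row.mu_z_au]),
                strength_au2=None,  # recomputed from the vector on read
                vertical_energy_ev=row.energy_ev,
            )
            for row in grp.itertuples()
        }
        out.append(SnapshotRecord(chrom, int(frame), float(depth), transitions, role))
    return out
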