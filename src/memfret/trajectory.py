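"""Reduce coordinate time series to membrane pose observables.

The two-step protocol consumes only two observables per chromophore and frame:
the insertion depth d (distance along the membrane normal between the
chromophore's center of mass and the membrane center) and the tilt ϕ of a
TDM-proxy reference vector against the membrane plane.  The membrane is
assumed assembled in the xy-plane with normal z; inputs in another frame must
be pre-rotated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tdm import ReferenceVectorSpec, reference_vector

__all__ = [
    "pose_series",
    "trajectory_means",
    "detachment_screen",
    "ScreenResult",
    "load_xyz_trajectory",
    "read_pose_table",
    "write_pose_table",
    "DETACHMENT_THRESHOLD_ANGSTROM",
    "DETACHMENT_MIN_FRACTION",
]

# a chromophore sustained beyond ~40 Å from the membrane center has left the
# bilayer (outer binding modes sit just below 30 Å)
DETACHMENT_THRESHOLD_ANGSTROM = 40.0
DETACHMENT_MIN_FRACTION = 0.25

POSE_COLUMNS = ["time_ns", "depth_angstrom", "tilt_deg"]


def _com_z(coords: np.ndarray, indices: np.ndarray, masses: np.ndarray) -> np.ndarray:
    m = masses[indices]
    return coords[:, indices, 2] @ m / m.sum()


def pose_series(
    coords: np.ndarray,
    masses: np.ndarray,
    chromophore_indices: Sequence[int],
    center_indices: Sequence[int],
    ref_spec: ReferenceVectorSpec,
    times_ns: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame depth and tilt from a (T, N, 3) coordinate array (Å).

    Depth is |z_COM(chromophore) − z_COM(center reference)|; tilt is the
    folded angle arcsin(|v_z|/|v|) ∈ [0°, 90°] of the reference vector, since
    the membrane normal has no preferred sign.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must be a (frames, atoms, 3) array")
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    chrom = np.asarray(chromophore_indices, dtype=int)
    center = np.asarray(center_indices, dtype=int)
    if chrom.size == 0 or center.size == 0:
        raise ValueError("atom selections must be non-empty")

    depth = np.abs(_com_z(coords, chrom, masses) - _com_z(coords, center, masses))
    vecs = np.array([reference_vector(frame, ref_spec) for frame in coords])
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("reference vector vanished in at least one frame")
    tilt = np.degrees(np.arcsin(np.abs(vecs[:, 2]) / norms))

    t = np.arange(coords.shape[0], dtype=float) if times_ns is None else np.asarray(times_ns)
    return pd.DataFrame({"time_ns": t, "depth_angstrom": depth, "tilt_deg": tilt})


@dataclass(frozen=True)
class ScreenResult:
    exclude: bool
    fraction_beyond: float
    reason: str


def detachment_screen(
    series: pd.DataFrame,
    threshold_angstrom: float = DETACHMENT_THRESHOLD_ANGSTROM,
    min_fraction: float = DETACHMENT_MIN_FRACTION,
) -> ScreenResult:
    """Exclude a trajectory whose chromophore left the membrane: depth beyond
    ``threshold_angstrom`` for more than ``min_fraction`` of the frames."""
    if threshold_angstrom <= 0:
        raise ValueError("threshold must be positive")
    frac = float(np.mean(series["depth_angstrom"].to_numpy() > threshold_angstrom))
    if frac > min_fraction:
        return ScreenResult(True, frac,
                            f"detached: {frac:.0%} of frames beyond {threshold_angstrom} Å")
    return ScreenResult(False, frac, "attached")


def trajectory_means(
    series_list: Sequence[pd.DataFrame],
    screens: Sequence[ScreenResult] | None = None,
) -> dict:
    """Per-trajectory and pooled means of depth and tilt.

    Excluded trajectories (per the detachment screen) are reported with their
    reason but do not enter the pooled means, which run over all frames of the
    retained trajectories.
    """
    if not series_list:
        raise ValueError("no trajectories supplied")
    if screens is None:
        screens = [ScreenResult(False, 0.0, "attached")] * len(series_list)
    rows = []
    kept_frames = []
    for i, (s, sc) in enumerate(zip(series_list, screens)):
        rows.append({
            "trajectory": i,
            "mean_depth_angstrom": float(s["depth_angstrom"].mean()),
            "mean_tilt_deg": float(s["tilt_deg"].mean()),
            "n_frames": len(s),
            "excluded": sc.exclude,
            "reason": sc.reason,
        })
        if not sc.exclude:
            kept_frames.append(s)
    if not kept_frames:
        raise ValueError("all trajectories were excluded by the detachment screen")
    pooled = pd.concat(kept_frames, ignore_index=True)
    return {
        "per_trajectory": pd.DataFrame(rows).set_index("trajectory"),
        "pooled_depth_angstrom": float(pooled["depth_angstrom"].mean()),
        "pooled_tilt_deg": float(pooled["tilt_deg"].mean()),
        "n_frames_pooled": len(pooled),
    }


def load_xyz_trajectory(path: str | Path):
    """Read a (possibly multi-frame) XYZ file via MDAnalysis.

    Returns ``(coords, masses, names)`` with coords of shape (T, N, 3) in Å
    and masses guessed from the element names.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path), to_guess=("masses",))
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return coords, u.atoms.masses.astype(float), list(u.atoms.names)


def read_pose_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed (time_ns, depth_angstrom, tilt_deg) pose table,
    bypassing raw coordinates."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(POSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[POSE_COLUMNS].astype(float)


def write_pose_table(path: str | Path, series: pd.DataFrame) -> None:
    series[POSE_COLUMNS].to_csv(path, index=False)
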