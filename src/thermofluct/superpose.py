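"""Rigid-body superposition, per-frame RMSD and per-residue RMSF.

The central quantities of the comparison: RMSD after optimal (Kabsch)
superposition measures global structural drift per frame; RMSF measures each
residue's fluctuation about its trajectory-mean position after all frames have
been superposed onto an iterated mean structure.

Estimator note: fitting rotation + translation to every frame absorbs six
degrees of freedom of the thermal noise, so for N fitted atoms with isotropic
per-axis standard deviation sigma the expected mean-square fluctuation is
3 * sigma^2 * (1 - 2/N), not 3 * sigma^2; the closed forms used in the tests
carry this finite-N factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "RMSDSeries",
    "RMSFProfile",
    "kabsch_superpose",
    "apply_transform",
    "trajectory_rmsd",
    "rmsf",
]

_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float  # Angstrom, after applying the transform


@dataclass
class RMSDSeries:
    """Per-frame RMSD (Angstrom) with the matching frame times (ps)."""

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must have equal length")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")

    def to_frame(self, protein: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"frame_time_ps": self.frame_times, "rmsd_A": self.values}
        )
        if protein is not None:
            df.insert(0, "protein", protein)
        return df


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Angstrom), keyed by the protein's own numbering."""

    residue_numbers: np.ndarray
    values: np.ndarray
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residue_numbers.shape != self.values.shape:
            raise ValueError("residue_numbers and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be non-negative")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residue_numbers.tolist(), self.values.tolist()))

    def to_frame(self, protein: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"residue_number": self.residue_numbers, "rmsf_A": self.values}
        )
        if protein is not None:
            df.insert(0, "protein", protein)
        return df


def _check_points(points: np.ndarray, label: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{label} must have shape (n, 3)")
    if pts.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    return pts


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R (determinant +1, reflections suppressed) and
    translation t minimising the (weighted) RMSD of ``mobile @ R.T + t``
    against ``reference``.  Degenerate point sets (fewer than 3 points, or all
    points collinear) are rejected.
    """
    mob = _check_points(mobile, "mobile")
    ref = _check_points(reference, "reference")
    if mob.shape != ref.shape:
        raise ValueError("mobile and reference must have equal point counts")
    if weights is None:
        w = np.full(mob.shape[0], 1.0 / mob.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mob.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mob
    cr = w @ ref
    mob_c = mob - cm
    ref_c = ref - cr
    # collinearity check: centered points must span at least a plane
    for pts in (mob_c, ref_c):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= _DEGENERACY_TOL * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) point set")
    cov = (mob_c * w[:, None]).T @ ref_c
    u, _s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cr - rotation @ cm
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - ref) ** 2)))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a superposition transform to an (n, 3) coordinate array."""
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def _selection_indices(structure: Structure, atom_selection: str) -> np.ndarray:
    """Indices for a selection: an atom name, comma-separated names or "all"."""
    if atom_selection == "all":
        return np.arange(len(structure))
    names = {s.strip() for s in atom_selection.split(",")}
    idx = np.array(
        [i for i, a in enumerate(structure.atoms) if a.atom_name in names], dtype=int
    )
    if idx.size == 0:
        raise ValueError(f"atom selection {atom_selection!r} matches no atoms")
    return idx


def trajectory_rmsd(
    traj: Trajectory,
    reference: Structure | None = None,
    atom_selection: str = "CA",
    burn_in_frames: int = 0,
) -> RMSDSeries:
    """Per-frame RMSD after independent optimal superposition onto a reference.

    ``reference`` defaults to the trajectory topology.  ``burn_in_frames``
    drops that many leading frames before the series is computed.
    """
    reference = traj.topology if reference is None else reference
    idx = _selection_indices(traj.topology, atom_selection)
    ref_idx = _selection_indices(reference, atom_selection)
    if idx.size != ref_idx.size:
        raise ValueError("selection sizes differ between trajectory and reference")
    ref = reference.coords[ref_idx]
    frames = traj.frames[burn_in_frames:, idx, :]
    times = traj.frame_times[burn_in_frames:]
    values = np.array([kabsch_superpose(f, ref).rmsd for f in frames])
    return RMSDSeries(values=values, frame_times=times)


def _per_residue_selection(structure: Structure, atom_selection: str) -> np.ndarray:
    """Selection indices, verified to resolve to one atom per residue."""
    idx = _selection_indices(structure, atom_selection)
    seen: dict[tuple[str, int], int] = {}
    for i in idx:
        a = structure.atoms[int(i)]
        key = (a.chain_id, a.residue_number)
        if key in seen:
            raise ValueError(
                f"atom selection {atom_selection!r} resolves to more than one "
                f"atom in residue {key}; RMSF must be per-residue"
            )
        seen[key] = i
    return idx


def rmsf(
    traj: Trajectory,
    atom_selection: str = "CA",
    burn_in_frames: int = 0,
    n_mean_passes: int = 2,
) -> RMSFProfile:
    """Per-residue RMSF about the trajectory mean structure.

    Iterated-mean procedure (fixed pass count, deterministic): superpose every
    frame onto the first frame and form the mean structure; then re-superpose
    the frames onto that mean and recompute it.  RMSF_i is the root of the
    per-frame mean squared deviation of residue i's selected atom from its
    final mean position.
    """
    frames = traj.frames[burn_in_frames:]
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _per_residue_selection(traj.topology, atom_selection)
    sel = frames[:, idx, :]
    reference = sel[0]
    for _ in range(n_mean_passes):
        fitted = np.empty_like(sel)
        for k in range(sel.shape[0]):
            fitted[k] = apply_transform(sel[k], kabsch_superpose(sel[k], reference))
        reference = fitted.mean(axis=0)
    dev = fitted - reference
    values = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    numbers = np.array(
        [traj.topology.atoms[int(i)].residue_number for i in idx], dtype=int
    )
    chains = tuple(traj.topology.atoms[int(i)].chain_id for i in idx)
    return RMSFProfile(residue_numbers=numbers, values=values, chain_ids=chains)
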