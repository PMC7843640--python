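"""Independent oracles and small builders shared by the test modules.

The oracles deliberately avoid the implementation paths they check: the
superposition oracle minimises RMSD by quaternion sampling with shrinking
refinement, and the alignment oracle enumerates every global alignment path
explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from thermofluct.core import SequenceRecord
from thermofluct.mapping import align_many, build_map
from thermofluct.regions import delta_profile, detect_regions
from thermofluct.superpose import rmsf
from thermofluct.synthetic import (
    FluctuationSpec,
    make_homolog_set,
    make_reference_structure,
    make_trajectory,
)


def quaternion_grid_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    n_coarse: int = 800,
    n_refine: int = 50,
    n_iters: int = 70,
    seed: int = 0,
) -> float:
    """Brute-force minimum RMSD over rotations via quaternion grid refinement.

    Random unit quaternions seed a coarse search; the best is refined by
    sampling shrinking Gaussian perturbations.  Translation is handled in
    closed form (centroid matching is optimal for any fixed rotation).
    """
    rng = np.random.default_rng(seed)
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def rmsd_for(quats: np.ndarray) -> np.ndarray:
        mats = Rotation.from_quat(quats).as_matrix()
        moved = np.einsum("qij,nj->qni", mats, mob_c)
        return np.sqrt(((moved - ref_c) ** 2).sum(axis=2).mean(axis=1))

    quats = rng.standard_normal((n_coarse, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    values = rmsd_for(quats)
    best_q = quats[values.argmin()]
    best = values.min()
    scale = 0.5
    for _ in range(n_iters):
        cand = best_q + scale * rng.standard_normal((n_refine, 4))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        values = rmsd_for(cand)
        if values.min() < best:
            best = values.min()
            best_q = cand[values.argmin()]
        scale *= 0.85
    return float(best)


def enumerate_alignment_score(
    seq_a: str,
    seq_b: str,
    table: dict[tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best global alignment score by explicit enumeration of every path.

    A gap run of length L costs gap_open + (L - 1) * gap_extend.  Feasible
    only for short sequences; used as the optimality oracle.
    """
    n, m = len(seq_a), len(seq_b)
    best = -np.inf

    def rec(i: int, j: int, score: float, state: int) -> None:
        nonlocal best
        if i == n and j == m:
            best = max(best, score)
            return
        if i < n and j < m:
            rec(i + 1, j + 1, score + table[(seq_a[i], seq_b[j])], 0)
        if j < m:
            rec(i, j + 1, score - (gap_extend if state == 1 else gap_open), 1)
        if i < n:
            rec(i + 1, j, score - (gap_extend if state == 2 else gap_open), 2)

    rec(0, 0, 0.0, 0)
    return float(best)


def build_region_experiment(
    seed: int,
    n_frames: int = 1000,
    n_residues: int = 125,
    regions: tuple[tuple[int, int], ...] = ((10, 27), (34, 41), (78, 91), (103, 112)),
    baseline_sigma: float = 0.3,
    region_sigma: float = 0.9,
):
    """One planted-region experiment: flat thermophiles vs regional mesophile.

    Returns (detected regions, planted regions as column spans, map).
    Substitution-only homologs keep the alignment gap-free, so common columns
    coincide with base-sequence positions.
    """
    rng = np.random.default_rng(seed)
    base = make_reference_structure(n_residues, seed=int(rng.integers(2**31)))
    base_seq = base.sequence()
    variants, _ = make_homolog_set(
        base_seq, 2, substitution_rate=0.2, indel_rate=0.0,
        seed=int(rng.integers(2**31)), ids=["thermo2", "meso"],
    )
    records = [SequenceRecord("thermo1", base_seq), variants[0], variants[1]]
    profiles = {}
    for record, role_regions in (
        (records[0], ()),
        (records[1], ()),
        (records[2], tuple((s, e, region_sigma) for s, e in regions)),
    ):
        ref = make_reference_structure(
            n_residues, seed=int(rng.integers(2**31)), sequence=record.sequence
        )
        spec = FluctuationSpec.uniform(
            n_residues,
            baseline_sigma,
            region_plan=role_regions,
            rigid_body_noise=(5.0, 1.0),
            seed=int(rng.integers(2**31)),
        )
        traj = make_trajectory(ref, spec, [], n_frames=n_frames)
        profiles[record.id] = rmsf(traj)
    amap = build_map(align_many(records))
    dprof = delta_profile(profiles, amap, "meso", ["thermo1", "thermo2"])
    detected = detect_regions(dprof)
    planted = [
        (amap.column_for("meso", s), amap.column_for("meso", e)) for s, e in regions
    ]
    return detected, planted, amap


def regions_match(detected, planted, tolerance: int = 2) -> bool:
    """All planted spans recovered within +/- tolerance and nothing else."""
    if len(detected) != len(planted):
        return False
    return all(
        abs(d.start_column - s) <= tolerance and abs(d.end_column - e) <= tolerance
        for d, (s, e) in zip(detected, planted)
    )
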