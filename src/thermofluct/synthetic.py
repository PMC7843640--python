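"""Synthetic reference structures, trajectories and homolog sequence sets.

This module is the stand-in for real MD output.  It emulates the features the
analysis stages care about and nothing else: a coarse two-atoms-per-residue
topology (CA plus one named side-chain tip atom), per-residue harmonic
fluctuation amplitudes that differ by region, global rigid-body frame noise
(so superposition has real work to do), and planted two-state residue-pair
contacts whose occupancy is an independent Bernoulli draw per frame.

Default bookkeeping follows the study conditions the package targets: frames
saved every 400 ps so that a 400 ns run yields exactly 1,000 frames (frame i
at t = i * 400 ps, i = 1..1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Atom, SequenceRecord, Structure, Trajectory, one_to_three

__all__ = [
    "TIP_ATOMS",
    "GENERATOR_ALPHABET",
    "FluctuationSpec",
    "InteractionPlan",
    "make_reference_structure",
    "make_trajectory",
    "make_homolog_set",
    "n_frames_from_duration",
]

#: side-chain tip atom (name, element) per residue under the coarse topology.
#: Charged/polar tips are the atoms the interaction search knows about; GLY is
#: absent (no side chain to represent).
TIP_ATOMS: dict[str, tuple[str, str]] = {
    "ALA": ("CB", "C"),
    "ARG": ("NE", "N"),
    "ASN": ("OD1", "O"),
    "ASP": ("OD1", "O"),
    "CYS": ("SG", "S"),
    "GLN": ("OE1", "O"),
    "GLU": ("OE1", "O"),
    "HIS": ("NE2", "N"),
    "ILE": ("CD1", "C"),
    "LEU": ("CD1", "C"),
    "LYS": ("NZ", "N"),
    "MET": ("SD", "S"),
    "PHE": ("CZ", "C"),
    "PRO": ("CG", "C"),
    "SER": ("OG", "O"),
    "THR": ("OG1", "O"),
    "TRP": ("NE1", "N"),
    "TYR": ("OH", "O"),
    "VAL": ("CB", "C"),
}

#: one-letter alphabet the generator draws from
GENERATOR_ALPHABET = "ARNDCQEHILKMFPSTWYV"

_CA_SPACING = (3.75, 3.85)  # consecutive CA-CA distance window, Angstrom
_CA_CLASH = 3.5  # minimum CA-CA distance for non-consecutive residues
_TIP_BOND = 2.4  # CA-to-tip distance, Angstrom


@dataclass
class FluctuationSpec:
    """Planted per-residue fluctuation amplitudes for one trajectory.

    ``per_residue_sigma`` holds the per-axis Gaussian standard deviation (A)
    of each residue's thermal displacement; ``region_plan`` entries
    ``(start, end, sigma)`` (1-based, inclusive) override contiguous spans,
    which is how high-fluctuation regions are planted.  ``rigid_body_noise``
    is ``(max rotation angle in degrees, max translation in A)`` applied to
    every frame as a whole.
    """

    n_residues: int
    per_residue_sigma: np.ndarray
    region_plan: tuple[tuple[int, int, float], ...] = ()
    rigid_body_noise: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.per_residue_sigma = np.asarray(self.per_residue_sigma, dtype=float)
        if self.per_residue_sigma.shape != (self.n_residues,):
            raise ValueError("per_residue_sigma must have one entry per residue")
        if np.any(self.per_residue_sigma < 0):
            raise ValueError("sigmas must be non-negative")
        for start, end, sigma in self.region_plan:
            if not (1 <= start <= end <= self.n_residues):
                raise ValueError(f"region span ({start}, {end}) outside [1, n_residues]")
            if sigma < 0:
                raise ValueError("region sigma must be non-negative")

    @classmethod
    def uniform(
        cls,
        n_residues: int,
        sigma: float,
        region_plan: Iterable[tuple[int, int, float]] = (),
        rigid_body_noise: tuple[float, float] = (0.0, 0.0),
        seed: int = 0,
    ) -> "FluctuationSpec":
        return cls(
            n_residues=n_residues,
            per_residue_sigma=np.full(n_residues, float(sigma)),
            region_plan=tuple(tuple(r) for r in region_plan),
            rigid_body_noise=tuple(rigid_body_noise),
            seed=seed,
        )

    def resolved_sigma(self) -> np.ndarray:
        """Per-residue sigma after applying the region overrides."""
        sigma = self.per_residue_sigma.copy()
        for start, end, s in self.region_plan:
            sigma[start - 1 : end] = s
        return sigma


@dataclass(frozen=True)
class InteractionPlan:
    """A planted two-state contact between two named atoms.

    Each frame the pair distance is set to ``bound_distance`` with probability
    ``occupancy`` (independent Bernoulli draw) and ``unbound_distance``
    otherwise, plus Gaussian jitter, by moving the second atom along the
    current pair axis.
    """

    residue_pair: tuple[int, int]
    atom_pair: tuple[str, str]
    bound_distance: float
    unbound_distance: float
    occupancy: float
    jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.bound_distance < self.unbound_distance:
            raise ValueError("bound_distance must be smaller than unbound_distance")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")


def _random_unit(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    v = rng.standard_normal(3 if n is None else (n, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _grow_ca_trace(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with ~3.8 A steps and mild confinement."""
    radius = 4.0 * max(n_residues, 8) ** (1 / 3) + 6.0
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        placed = False
        for attempt in range(500):
            step = _random_unit(rng) * rng.uniform(*_CA_SPACING)
            candidate = coords[i - 1] + step
            if np.linalg.norm(candidate) > radius:
                continue
            if i >= 2:
                dists = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                if dists.min() < _CA_CLASH:
                    continue
            coords[i] = candidate
            placed = True
            break
        if not placed:  # extremely unlikely; widen the box and go straight on
            coords[i] = coords[i - 1] + _random_unit(rng) * rng.uniform(*_CA_SPACING)
    return coords


def make_reference_structure(
    n_residues: int,
    seed: int = 0,
    sequence: str | None = None,
    chain_id: str = "A",
    name: str = "synthetic",
) -> Structure:
    """Coarse reference model: per residue a CA and one side-chain tip atom.

    CA positions lie on a self-avoiding curve with consecutive spacing in
    [3.75, 3.85] A; the tip atom sits 2.4 A from its CA in a random direction.
    If ``sequence`` is omitted a random sequence over the generator alphabet
    is assigned.  Deterministic for a given seed.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be at least 2")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(GENERATOR_ALPHABET), size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    ca = _grow_ca_trace(n_residues, rng)
    atoms: list[Atom] = []
    for i, letter in enumerate(sequence):
        res_name = one_to_three(letter)
        if res_name not in TIP_ATOMS:
            raise ValueError(
                f"residue {res_name} has no side-chain tip under the coarse "
                "topology (glycine is not supported)"
            )
        tip_name, tip_element = TIP_ATOMS[res_name]
        atoms.append(Atom(chain_id, i + 1, res_name, "CA", "C", ca[i]))
        atoms.append(
            Atom(chain_id, i + 1, res_name, tip_name, tip_element,
                 ca[i] + _random_unit(rng) * _TIP_BOND)
        )
    return Structure(atoms, name=name)


def place_planted_pairs(
    reference: Structure, plans: Sequence[InteractionPlan], seed: int = 0
) -> Structure:
    """Reposition each plan's partner tip atom near its counterpart.

    A random CA trace does not bring arbitrary residue pairs close together,
    so for every plan the second atom is placed at the first atom's position
    plus the plan's resting distance (bound if occupancy > 0, else unbound)
    along a random, seed-deterministic direction.  This is an abstraction of
    the coarse topology: the partner tip may end up far from its own CA.
    """
    rng = np.random.default_rng(seed)
    coords = reference.coords
    for plan in plans:
        i, j = _plan_indices(reference, plan)
        rest = plan.bound_distance if plan.occupancy > 0 else plan.unbound_distance
        coords[j] = coords[i] + _random_unit(rng) * rest
    return reference.with_coords(coords)


def _plan_indices(reference: Structure, plan: InteractionPlan) -> tuple[int, int]:
    chains = {a.chain_id for a in reference.atoms}
    if len(chains) != 1:
        raise ValueError("interaction plans require a single-chain reference")
    chain = next(iter(chains))
    try:
        i = reference.atom_index(chain, plan.residue_pair[0], plan.atom_pair[0])
        j = reference.atom_index(chain, plan.residue_pair[1], plan.atom_pair[1])
    except KeyError as exc:
        raise ValueError(f"interaction plan references a missing atom: {exc}") from None
    return i, j


def make_trajectory(
    reference: Structure,
    fluct_spec: FluctuationSpec,
    interaction_plans: Sequence[InteractionPlan] = (),
    n_frames: int = 1000,
    frame_interval: float = 400.0,
    temperature: float | None = 358.0,
) -> Trajectory:
    """Trajectory with planted fluctuations, contacts and rigid-body noise.

    Per frame: the reference plus an independent Gaussian displacement per
    atom (that residue's sigma per axis); then each planted pair's distance
    is overridden by moving the partner atom along the current pair axis;
    finally the whole frame is rotated/translated by random rigid-body noise.
    Deterministic given ``fluct_spec.seed``.
    """
    residues = list(reference.residues())
    if fluct_spec.n_residues != len(residues):
        raise ValueError(
            f"fluct_spec covers {fluct_spec.n_residues} residues but the "
            f"reference has {len(residues)}"
        )
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    plan_indices = [_plan_indices(reference, p) for p in interaction_plans]

    rng = np.random.default_rng(fluct_spec.seed)
    sigma_res = fluct_spec.resolved_sigma()
    sigma_atom = np.empty(len(reference))
    for (cid, num, name, idx), s in zip(residues, sigma_res):
        sigma_atom[idx] = s

    frames = reference.coords[None, :, :] + rng.standard_normal(
        (n_frames, len(reference), 3)
    ) * sigma_atom[None, :, None]

    for plan, (i, j) in zip(interaction_plans, plan_indices):
        bound = rng.random(n_frames) < plan.occupancy
        target = np.where(bound, plan.bound_distance, plan.unbound_distance)
        if plan.jitter_sigma > 0:
            target = target + rng.normal(0.0, plan.jitter_sigma, n_frames)
        target = np.clip(target, 0.05, None)
        axis = frames[:, j, :] - frames[:, i, :]
        norm = np.linalg.norm(axis, axis=1)
        degenerate = norm < 1e-9
        if np.any(degenerate):
            axis[degenerate] = _random_unit(rng, int(degenerate.sum()))
            norm[degenerate] = 1.0
        unit = axis / norm[:, None]
        frames[:, j, :] = frames[:, i, :] + unit * target[:, None]

    max_rot_deg, max_trans = fluct_spec.rigid_body_noise
    if max_rot_deg > 0 or max_trans > 0:
        axes = _random_unit(rng, n_frames)
        angles = rng.uniform(0.0, np.deg2rad(max_rot_deg), n_frames)
        mats = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
        trans = rng.uniform(-max_trans, max_trans, (n_frames, 3))
        frames = np.einsum("nij,naj->nai", mats, frames) + trans[:, None, :]

    return Trajectory(
        topology=reference,
        frames=frames,
        frame_interval=frame_interval,
        temperature=temperature,
    )


def n_frames_from_duration(duration_ns: float, frame_interval_ps: float) -> int:
    """Number of saved frames for a run of ``duration_ns`` sampled every
    ``frame_interval_ps`` (frame i at t = i * interval, i >= 1)."""
    if duration_ns <= 0 or frame_interval_ps <= 0:
        raise ValueError("duration and frame interval must be positive")
    n = duration_ns * 1000.0 / frame_interval_ps
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9:
        raise ValueError(
            f"duration {duration_ns} ns is not a multiple of the frame "
            f"interval {frame_interval_ps} ps"
        )
    return n_int


def make_homolog_set(
    base_sequence: str,
    n_variants: int,
    substitution_rate: float,
    indel_rate: float,
    seed: int = 0,
    ids: Sequence[str] | None = None,
    protected_positions: frozenset[int] | set[int] = frozenset(),
) -> tuple[list[SequenceRecord], list[dict[int, int | None]]]:
    """Homologous variants of a base sequence with ground-truth correspondence.

    Each variant is produced site-by-site: with probability ``indel_rate`` a
    single-residue indel occurs (deletion of the site or insertion of a random
    residue before it, equal odds); otherwise with probability
    ``substitution_rate`` the residue is substituted by a different random
    residue.  ``protected_positions`` (1-based) are exempt from mutation so
    planted interaction motifs survive.  Returns the variant records plus, per
    variant, the mapping from base position to variant position (``None`` for
    deleted sites).
    """
    if not base_sequence:
        raise ValueError("base sequence is empty")
    if not (0.0 <= substitution_rate < 1.0 and 0.0 <= indel_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    alphabet = list(GENERATOR_ALPHABET)
    records: list[SequenceRecord] = []
    maps: list[dict[int, int | None]] = []
    for v in range(n_variants):
        out: list[str] = []
        mapping: dict[int, int | None] = {}
        for pos, letter in enumerate(base_sequence, start=1):
            protected = pos in protected_positions
            if not protected and rng.random() < indel_rate:
                if rng.random() < 0.5:  # deletion
                    mapping[pos] = None
                    continue
                out.append(str(rng.choice(alphabet)))  # insertion before site
            if not protected and rng.random() < substitution_rate:
                choices = [c for c in alphabet if c != letter]
                out.append(str(rng.choice(choices)))
            else:
                out.append(letter)
            mapping[pos] = len(out)
        name = ids[v] if ids is not None else f"var{v + 1}"
        records.append(SequenceRecord(id=name, sequence="".join(out)))
        maps.append(mapping)
    return records, maps
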