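"""Salt-bridge and hydrogen-bond candidates, distance series and occupancy.

Criteria are distance-only over heavy atoms (the coarse topology carries no
hydrogens and no angles are evaluated): a salt bridge is a basic side-chain
nitrogen (Lys NZ; Arg NH1/NH2/NE; His ND1/NE2) within a cutoff of an acidic
side-chain oxygen (Asp OD1/OD2; Glu OE1/OE2), default 4.0 A; a hydrogen bond
is any donor/acceptor N/O heavy-atom pair within 3.5 A.  Symmetric side-chain
atoms are treated as equivalent (the per-frame distance is the minimum over
the listed atoms).  Occupancy is the fraction of frames within the contact
cutoff; an interaction counts as formed when occupancy reaches the presence
threshold (default 0.1), otherwise it is classified NI (no interaction) —
as is a homolog whose partner residue cannot chemically form the contact
(e.g. the basic residue replaced by a methionine).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import STANDARD_RESIDUES, Structure, Trajectory, three_to_one
from .mapping import AlignmentMap

__all__ = [
    "BASIC_SIDECHAIN_ATOMS",
    "ACIDIC_SIDECHAIN_ATOMS",
    "SALT_BRIDGE_CUTOFF",
    "HBOND_CUTOFF",
    "InteractionPair",
    "InteractionSeries",
    "candidate_pairs",
    "distance_series",
    "compare_across_homologs",
]

logger = logging.getLogger(__name__)

BASIC_SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),  # protonation states out of scope
}
ACIDIC_SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

SALT_BRIDGE_CUTOFF = 4.0  # A, closest charged-group heavy atoms
HBOND_CUTOFF = 3.5  # A, donor/acceptor heavy atoms
DEFAULT_SEARCH_CUTOFF = 6.0  # A, candidate search on the reference structure
DEFAULT_PRESENCE_THRESHOLD = 0.1  # occupancy needed to call a contact formed

_BACKBONE_NO = ("N", "O")  # backbone donor/acceptor atom names


@dataclass(frozen=True)
class InteractionPair:
    """A candidate contact between two residues.

    ``atom_groups`` lists, per residue, the equivalent atoms actually present
    in the topology; the pair distance is the minimum over the cross product.
    """

    kind: str  # "salt_bridge" | "hydrogen_bond"
    residues: tuple[tuple[str, int, str], tuple[str, int, str]]
    atom_groups: tuple[tuple[str, ...], tuple[str, ...]]
    cutoff: float

    def __post_init__(self) -> None:
        if self.kind not in ("salt_bridge", "hydrogen_bond"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not self.atom_groups[0] or not self.atom_groups[1]:
            raise ValueError("both atom groups must be nonempty")

    @property
    def short_kind(self) -> str:
        return "SB" if self.kind == "salt_bridge" else "HB"

    def residue_labels(self) -> tuple[str, str]:
        return tuple(
            f"{three_to_one(name)}{num}" for _c, num, name in self.residues
        )


@dataclass
class InteractionSeries:
    """Per-frame distance trace and occupancy for one interaction pair."""

    pair: InteractionPair
    distances: np.ndarray  # A, one per frame
    occupancy: float
    classification: str  # SB | HB | NI

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    def to_frame(self, protein: str, frame_times: np.ndarray) -> pd.DataFrame:
        labels = self.pair.residue_labels()
        return pd.DataFrame(
            {
                "protein": protein,
                "pair": f"{labels[0]}-{labels[1]}",
                "kind": self.pair.short_kind,
                "frame_time_ps": np.asarray(frame_times, dtype=float),
                "distance_A": self.distances,
            }
        )


def _residue_table(structure: Structure) -> list[tuple[str, int, str, dict[str, int]]]:
    table = []
    for chain, num, name, idx in structure.residues():
        atoms = {structure.atoms[i].atom_name: i for i in idx}
        table.append((chain, num, name, atoms))
    return table


def _group_min_distance(
    coords: np.ndarray, idx_a: list[int], idx_b: list[int]
) -> float:
    a = coords[idx_a][:, None, :]
    b = coords[idx_b][None, :, :]
    return float(np.sqrt(((a - b) ** 2).sum(axis=2)).min())


def candidate_pairs(
    structure: Structure,
    kind: str,
    search_cutoff: float = DEFAULT_SEARCH_CUTOFF,
) -> list[InteractionPair]:
    """Find residue pairs whose reference-structure distance permits a contact.

    Salt bridges pair basic with acidic side chains; hydrogen bonds pair any
    two N/O heavy atoms, excluding pairs within one residue and
    backbone-backbone pairs of adjacent residues.  Pairs are reported once,
    in canonical (chain, residue number) order.  Residues with nonstandard
    chemistry are skipped with a logged warning.
    """
    if kind not in ("salt_bridge", "hydrogen_bond"):
        raise ValueError(f"unknown interaction kind {kind!r}")
    coords = structure.coords
    residues = []
    for chain, num, name, atoms in _residue_table(structure):
        if name not in STANDARD_RESIDUES:
            logger.warning(
                "skipping residue %s/%s %s: unknown chemistry", chain, num, name
            )
            continue
        residues.append((chain, num, name, atoms))

    pairs: list[InteractionPair] = []
    if kind == "salt_bridge":
        basics, acidics = [], []
        for chain, num, name, atoms in residues:
            group = [a for a in BASIC_SIDECHAIN_ATOMS.get(name, ()) if a in atoms]
            if group:
                basics.append(((chain, num, name), group, [atoms[a] for a in group]))
            group = [a for a in ACIDIC_SIDECHAIN_ATOMS.get(name, ()) if a in atoms]
            if group:
                acidics.append(((chain, num, name), group, [atoms[a] for a in group]))
        for res_b, names_b, idx_b in basics:
            for res_a, names_a, idx_a in acidics:
                if res_b[:2] == res_a[:2]:
                    continue
                if _group_min_distance(coords, idx_b, idx_a) > search_cutoff:
                    continue
                first, second = sorted(
                    [(res_b, names_b), (res_a, names_a)], key=lambda r: (r[0][0], r[0][1])
                )
                pairs.append(
                    InteractionPair(
                        kind="salt_bridge",
                        residues=(first[0], second[0]),
                        atom_groups=(tuple(first[1]), tuple(second[1])),
                        cutoff=SALT_BRIDGE_CUTOFF,
                    )
                )
    else:
        donors_acceptors = []
        for chain, num, name, atoms in residues:
            group = [
                a
                for a, i in atoms.items()
                if structure.atoms[i].element in ("N", "O")
            ]
            if group:
                donors_acceptors.append(((chain, num, name), group, atoms))
        for (res_1, names_1, atoms_1), (res_2, names_2, atoms_2) in combinations(
            donors_acceptors, 2
        ):
            adjacent = res_1[0] == res_2[0] and abs(res_1[1] - res_2[1]) == 1
            g1 = [a for a in names_1 if not (adjacent and a in _BACKBONE_NO)]
            g2 = [a for a in names_2 if not (adjacent and a in _BACKBONE_NO)]
            if not g1 or not g2:
                continue
            idx_1 = [atoms_1[a] for a in g1]
            idx_2 = [atoms_2[a] for a in g2]
            if _group_min_distance(coords, idx_1, idx_2) > search_cutoff:
                continue
            pairs.append(
                InteractionPair(
                    kind="hydrogen_bond",
                    residues=(res_1, res_2),
                    atom_groups=(tuple(g1), tuple(g2)),
                    cutoff=HBOND_CUTOFF,
                )
            )
    pairs.sort(key=lambda p: (p.residues[0][:2], p.residues[1][:2]))
    return pairs


def distance_series(
    traj: Trajectory,
    pair: InteractionPair,
    cutoff: float | None = None,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> InteractionSeries:
    """Per-frame minimum distance over the pair's equivalent atoms.

    Distances need no superposition (they are invariant under the rigid-body
    motion of a frame).  Occupancy is the fraction of frames at or below the
    contact cutoff; classification is the pair's kind when occupancy reaches
    the presence threshold, otherwise NI.
    """
    cutoff = pair.cutoff if cutoff is None else cutoff
    topo = traj.topology
    try:
        idx_a = [
            topo.atom_index(pair.residues[0][0], pair.residues[0][1], a)
            for a in pair.atom_groups[0]
        ]
        idx_b = [
            topo.atom_index(pair.residues[1][0], pair.residues[1][1], a)
            for a in pair.atom_groups[1]
        ]
    except KeyError as exc:
        raise ValueError(f"pair atom missing from topology: {exc}") from None
    a = traj.frames[:, idx_a, :][:, :, None, :]
    b = traj.frames[:, idx_b, :][:, None, :, :]
    distances = np.sqrt(((a - b) ** 2).sum(axis=3)).min(axis=(1, 2))
    occupancy = float(np.mean(distances <= cutoff))
    classification = pair.short_kind if occupancy >= presence_threshold else "NI"
    return InteractionSeries(
        pair=pair,
        distances=distances,
        occupancy=occupancy,
        classification=classification,
    )


def compare_across_homologs(
    series_by_protein: dict[str, list[InteractionSeries]],
    alignment_map: AlignmentMap,
    sequences: dict[str, str] | None = None,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Tabulate interactions across homologs on the common numbering.

    Rows are common column pairs at which any protein shows a candidate
    contact; per protein the table reports the residue identities, occupancy
    and SB/HB/NI classification.  A protein with no measurable contact at a
    row (partner residue absent, of non-interacting type, or never within
    the cutoff) is classified NI; residue identities are then read from
    ``sequences`` (id -> one-letter string) where provided.  Pairs whose
    residues cannot be mapped to common columns are flagged, not dropped.
    """
    rows: dict[tuple[str, int, int], dict] = {}
    unmapped_label = 0
    for pid, series_list in series_by_protein.items():
        for series in series_list:
            key_cols = []
            flag = ""
            for _chain, num, _name in series.pair.residues:
                col = alignment_map.to_column.get(pid, {}).get(num)
                if col is None:
                    flag = "unmapped"
                    col = -1
                key_cols.append(col)
            if flag:
                unmapped_label -= 1
                cols = (unmapped_label, unmapped_label)
            else:
                cols = tuple(sorted(key_cols))
            key = (series.pair.short_kind, *cols)
            row = rows.setdefault(
                key,
                {
                    "common_pair": f"{cols[0]}-{cols[1]}",
                    "kind": series.pair.short_kind,
                    "flags": flag,
                },
            )
            labels = series.pair.residue_labels()
            row[f"{pid}_residues"] = f"{labels[0]}-{labels[1]}"
            row[f"{pid}_occupancy"] = round(series.occupancy, 4)
            row[f"{pid}_class"] = (
                series.pair.short_kind
                if series.occupancy >= presence_threshold
                else "NI"
            )

    protein_ids = list(series_by_protein)
    for key, row in rows.items():
        if row.get("flags"):
            continue
        for pid in protein_ids:
            if f"{pid}_class" in row:
                continue
            labels = []
            for col in key[1:]:
                residue = alignment_map.residue_for(pid, col)
                if residue is None:
                    labels.append("-")
                elif sequences and pid in sequences:
                    labels.append(f"{sequences[pid][residue - 1]}{residue}")
                else:
                    labels.append(f"?{residue}")
            row[f"{pid}_residues"] = "-".join(labels)
            row[f"{pid}_occupancy"] = float("nan")
            row[f"{pid}_class"] = "NI"

    ordered = sorted(rows.items(), key=lambda kv: (kv[0][1] < 0, kv[0][1], kv[0][2], kv[0][0]))
    columns = ["common_pair", "kind", "flags"]
    for pid in protein_ids:
        columns += [f"{pid}_residues", f"{pid}_occupancy", f"{pid}_class"]
    return pd.DataFrame([row for _k, row in ordered], columns=columns)
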