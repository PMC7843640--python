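"""Core in-memory containers shared by every analysis stage.

The package works on a deliberately small structural vocabulary: an
:class:`Atom` (one PDB ATOM record), a :class:`Structure` (ordered atom list,
one coordinate set), a :class:`Trajectory` (the same topology plus an ordered
stack of coordinate frames with a sampling interval in picoseconds) and a
:class:`SequenceRecord` (one-letter protein sequence).  Distances are in
Angstrom throughout, times in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "SequenceRecord",
    "STANDARD_RESIDUES",
    "one_to_three",
    "three_to_one",
]

#: the 20 standard residues, three-letter codes
STANDARD_RESIDUES = frozenset(c.upper() for c in protein_letters_1to3.values())

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}

#: allowed one-letter alphabet for sequence records
SEQUENCE_ALPHABET = frozenset(_1TO3) | {"X"}


def one_to_three(letter: str) -> str:
    """Map a one-letter residue code to its three-letter code."""
    try:
        return _1TO3[letter.upper()]
    except KeyError:
        raise ValueError(f"unknown one-letter residue code {letter!r}") from None


def three_to_one(code: str) -> str:
    """Map a three-letter residue code to one letter ('X' if nonstandard)."""
    return _3TO1.get(code.upper(), "X")


@dataclass(frozen=True)
class Atom:
    """One atom: identity plus a position in Angstrom."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        object.__setattr__(self, "position", pos)

    @property
    def is_standard(self) -> bool:
        return self.residue_name in STANDARD_RESIDUES

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Structure:
    """An ordered list of atoms with one coordinate set.

    ``(chain_id, residue_number, atom_name)`` must be unique; residues must be
    contiguous within a chain in file order (author numbering is kept as-is).
    """

    atoms: list[Atom]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            k = atom.key()
            if k in seen:
                raise ValueError(f"duplicate atom {k} in structure {self.name!r}")
            seen.add(k)
        last_residue: dict[str, int] = {}
        closed: set[tuple[str, int]] = set()
        for atom in self.atoms:
            prev = last_residue.get(atom.chain_id)
            if prev is not None and atom.residue_number != prev:
                closed.add((atom.chain_id, prev))
                if (atom.chain_id, atom.residue_number) in closed:
                    raise ValueError(
                        f"residue {atom.chain_id}/{atom.residue_number} is not "
                        "contiguous in atom order"
                    )
            last_residue[atom.chain_id] = atom.residue_number

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        if len(self.atoms) != len(other.atoms):
            return False
        for a, b in zip(self.atoms, other.atoms):
            if (a.key(), a.residue_name, a.element) != (b.key(), b.residue_name, b.element):
                return False
            if not np.allclose(a.position, b.position, atol=5e-4):
                return False
        return True

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [
            Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name, a.element, c)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.name if name is None else name)

    def select_indices(self, atom_name: str) -> np.ndarray:
        """Indices of atoms whose name matches (e.g. ``"CA"``)."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.atom_name == atom_name], dtype=int
        )

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.key() == (chain_id, residue_number, atom_name):
                return i
        raise KeyError(f"atom {(chain_id, residue_number, atom_name)} not in structure")

    def residues(self) -> Iterator[tuple[str, int, str, list[int]]]:
        """Yield (chain_id, residue_number, residue_name, atom indices) in order."""
        current: tuple[str, int, str] | None = None
        idx: list[int] = []
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_number, a.residue_name)
            if key != current:
                if current is not None:
                    yield (*current, idx)
                current, idx = key, []
            idx.append(i)
        if current is not None:
            yield (*current, idx)

    def sequence(self, chain_id: str | None = None) -> str:
        """One-letter sequence of the (single or named) chain, in file order."""
        chains = {a.chain_id for a in self.atoms}
        if chain_id is None:
            if len(chains) != 1:
                raise ValueError("structure has multiple chains; pass chain_id")
            chain_id = next(iter(chains))
        return "".join(
            three_to_one(name)
            for cid, _num, name, _idx in self.residues()
            if cid == chain_id
        )


@dataclass
class Trajectory:
    """Coordinate frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3); every frame is congruent with
    the topology's atom order.  ``frame_interval`` is the sampling interval in
    picoseconds; ``temperature`` (Kelvin) is carried as metadata only.
    """

    topology: Structure
    frames: np.ndarray
    frame_interval: float = 400.0
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology)}"
            )
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive (picoseconds)")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_times(self) -> np.ndarray:
        """Time stamps in ps: frame i sits at (i + 1) * frame_interval."""
        return (np.arange(self.n_frames) + 1) * self.frame_interval

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class SequenceRecord:
    """A named one-letter protein sequence (20 standard letters plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence record {self.id!r} is empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence record {self.id!r} contains non-amino-acid "
                f"letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)
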