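"""Reading and writing PDB, FASTA and the package's tidy text outputs.

PDB parsing and formatting is delegated to :mod:`biotite`; a light pre-scan of
the raw lines enforces the contracts the rest of the package relies on
(congruent atom counts across MODEL blocks, no altloc/insertion codes,
parseable coordinates).  Only ATOM records are considered; HETATM records are
ignored.  Multi-model files become a :class:`~thermofluct.core.Trajectory`
whose frame interval is supplied by the caller (PDB cannot carry it); the
default is 400 ps.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .core import Atom, SequenceRecord, Structure, Trajectory

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "write_fasta",
    "fetch_genbank_proteins",
    "PDBFormatError",
]

# widest value an %8.3f PDB coordinate field can hold
_PDB_COORD_MIN, _PDB_COORD_MAX = -999.999, 9999.999


class PDBFormatError(ValueError):
    """Raised for files violating the fixed-column PDB contract."""


def _prescan(lines: list[str], path: str) -> list[int]:
    """Validate ATOM records line-by-line; return atoms-per-model counts.

    A file without MODEL records is treated as one model.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            in_model = False
            counts.append(current)
        elif rec == "ATOM":
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"{path}:{lineno}: truncated ATOM record")
            if line[16] not in (" ", ""):
                raise PDBFormatError(
                    f"{path}:{lineno}: alternate location indicator "
                    f"{line[16]!r} is not supported"
                )
            if line[26] not in (" ", ""):
                raise PDBFormatError(
                    f"{path}:{lineno}: residue insertion code "
                    f"{line[26]!r} is not supported"
                )
            try:
                int(line[22:26])
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise PDBFormatError(
                    f"{path}:{lineno}: unparseable ATOM record"
                ) from None
            current += 1
    if saw_model:
        if in_model:  # MODEL without ENDMDL
            counts.append(current)
    else:
        counts = [current]
    counts = [c for c in counts if c > 0] or [0]
    for i, c in enumerate(counts, start=1):
        if c != counts[0]:
            raise PDBFormatError(
                f"{path}: model {i} has {c} atoms but model 1 has {counts[0]}"
            )
    return counts


def _to_structure(array: struc.AtomArray, name: str) -> Structure:
    atoms = [
        Atom(
            chain_id=str(array.chain_id[i]),
            residue_number=int(array.res_id[i]),
            residue_name=str(array.res_name[i]),
            atom_name=str(array.atom_name[i]),
            element=str(array.element[i]),
            position=array.coord[i],
        )
        for i in range(array.array_length())
    ]
    return Structure(atoms, name=name)


def read_pdb(
    path: str | os.PathLike,
    frame_interval: float = 400.0,
    temperature: float | None = None,
) -> Structure | Trajectory:
    """Read a PDB file; one model gives a Structure, several a Trajectory.

    ``frame_interval`` (ps) annotates multi-model files; PDB itself has no
    field for it.  HETATM records are ignored.
    """
    path = os.fspath(path)
    pdb = PDBFile.read(path)
    _prescan(pdb.lines, path)
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    stack = stack[:, ~stack.hetero]
    if stack.array_length() == 0:
        raise PDBFormatError(f"{path}: no ATOM records")
    name = os.path.splitext(os.path.basename(path))[0]
    first = _to_structure(stack[0], name)
    if stack.stack_depth() == 1:
        return first
    return Trajectory(
        topology=first,
        frames=np.asarray(stack.coord, dtype=float),
        frame_interval=frame_interval,
        temperature=temperature,
    )


def _structure_to_array(structure: Structure) -> struc.AtomArray:
    n = len(structure)
    array = struc.AtomArray(n)
    array.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    array.res_id = np.array([a.residue_number for a in structure.atoms], dtype=int)
    array.res_name = np.array([a.residue_name for a in structure.atoms], dtype="U5")
    array.atom_name = np.array([a.atom_name for a in structure.atoms], dtype="U6")
    array.element = np.array([a.element for a in structure.atoms], dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    array.coord = structure.coords.astype(np.float32)
    return array


def write_pdb(obj: Structure | Trajectory, path: str | os.PathLike) -> None:
    """Write a Structure (one model) or Trajectory (one MODEL per frame)."""
    path = os.fspath(path)
    if isinstance(obj, Trajectory):
        coords = obj.frames
        template = obj.topology
    else:
        coords = obj.coords[None, :, :]
        template = obj
    if coords.min() < _PDB_COORD_MIN or coords.max() > _PDB_COORD_MAX:
        raise ValueError(
            "coordinates exceed the PDB fixed-column field width "
            f"([{_PDB_COORD_MIN}, {_PDB_COORD_MAX}] A)"
        )
    array = _structure_to_array(template)
    if coords.shape[0] == 1:
        array.coord = coords[0].astype(np.float32)
        out = array
    else:
        out = struc.from_template(array, coords.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(out)
    pdb.write(path)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read FASTA records in file order, whitespace stripped, upper-cased."""
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has no sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60
) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(os.fspath(path), "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def fetch_genbank_proteins(
    accessions: Iterable[str], email: str = "thermofluct@example.org", timeout: float = 15.0
) -> list[SequenceRecord]:
    """Fetch protein records from NCBI by accession (requires network access)."""
    import socket

    from Bio import Entrez

    Entrez.email = email
    Entrez.max_tries = 1
    old = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        handle = Entrez.efetch(
            db="protein", id=",".join(accessions), rettype="fasta", retmode="text"
        )
        try:
            records = [
                SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
                for rec in SeqIO.parse(handle, "fasta")
            ]
        finally:
            handle.close()
    finally:
        socket.setdefaulttimeout(old)
    if not records:
        raise RuntimeError("no records returned for " + ", ".join(accessions))
    return records
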