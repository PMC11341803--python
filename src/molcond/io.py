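"""Readers and writers for system matrices and structures.

Two containers are supported for (H, S) pairs exported from an LCAO code:

* plain text — a header line with N, then N rows of N whitespace-separated
  floats; one file per matrix;
* HDF5 — datasets ``/H``, ``/S`` and an ``/orbital_meta`` compound table.

PDB files are read (via Biopython) only for atom coordinates, element
symbols and hydrogen flags; no chemistry is derived from them.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .electronic import OrbitalMeta, RawSystem

__all__ = [
    "read_matrix_text",
    "write_matrix_text",
    "read_system_h5",
    "write_system_h5",
    "read_pdb_atoms",
    "raw_system_from_files",
]

PathLike = Union[str, Path]


def read_matrix_text(path: PathLike) -> np.ndarray:
    """Read the 'N then N×N floats' plain-text matrix format."""
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) != 1:
            raise ValueError(f"{path}: expected a single integer N on line 1")
        n = int(first[0])
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    if data.shape != (n, n):
        raise ValueError(f"{path}: header says {n}×{n}, found {data.shape}")
    return data


def write_matrix_text(path: PathLike, matrix: np.ndarray) -> None:
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        np.savetxt(fh, matrix, fmt="%.17g")


_META_DTYPE = np.dtype([
    ("atom_index", "i4"), ("element", "S4"), ("label", "S8"),
    ("zeta", "f8"), ("x", "f8"), ("y", "f8"), ("z", "f8"),
    ("is_hydrogen", "?"),
])


def write_system_h5(path: PathLike, raw: RawSystem) -> None:
    import h5py

    table = np.zeros(raw.n_orbitals, dtype=_META_DTYPE)
    for i, m in enumerate(raw.orbital_meta):
        table[i] = (m.atom_index, m.element.encode(), m.label.encode(),
                    m.zeta, *m.position, m.is_hydrogen)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("H", data=raw.H)
        fh.create_dataset("S", data=raw.S)
        fh.create_dataset("orbital_meta", data=table)
        fh.attrs["energy_unit"] = "eV"
        fh.attrs["length_unit"] = "A"


def read_system_h5(path: PathLike) -> RawSystem:
    import h5py

    with h5py.File(path, "r") as fh:
        h = fh["H"][()]
        s = fh["S"][()]
        meta = []
        for row in fh["orbital_meta"][()]:
            meta.append(OrbitalMeta(
                atom_index=int(row["atom_index"]),
                element=row["element"].decode(),
                label=row["label"].decode(),
                zeta=float(row["zeta"]),
                position=np.array([row["x"], row["y"], row["z"]]),
                is_hydrogen=bool(row["is_hydrogen"]),
            ))
    return RawSystem(H=h, S=s, orbital_meta=meta)


def read_pdb_atoms(path: PathLike) -> list[OrbitalMeta]:
    """Atom records from a PDB file as one metadata entry per atom.

    Elements come from the element column when present, with a fallback to
    the atom-name convention.  Only coordinates/element/hydrogen flags are
    used downstream.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sloppy toy PDBs
        structure = PDBParser(QUIET=True).get_structure("mol", str(path))
    meta = []
    for i, atom in enumerate(structure.get_atoms()):
        element = (atom.element or "").strip().capitalize()
        if not element:
            name = atom.get_name().strip()
            element = "".join(c for c in name if c.isalpha())[:1].capitalize()
        meta.append(OrbitalMeta(
            atom_index=i, element=element, label="1s",
            position=np.array(atom.coord, dtype=float),
        ))
    if not meta:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return meta


def raw_system_from_files(
    h_path: PathLike,
    s_path: Optional[PathLike] = None,
    pdb_path: Optional[PathLike] = None,
) -> RawSystem:
    """Assemble a RawSystem from matrix files plus optional PDB coordinates."""
    h = read_matrix_text(h_path)
    s = read_matrix_text(s_path) if s_path is not None else np.eye(h.shape[0])
    if pdb_path is not None:
        meta = read_pdb_atoms(pdb_path)
        if len(meta) != h.shape[0]:
            raise ValueError(
                f"PDB has {len(meta)} atoms but H is {h.shape[0]}×{h.shape[0]}; "
                "one orbital per atom is assumed for text input"
            )
    else:
        meta = [OrbitalMeta(atom_index=i) for i in range(h.shape[0])]
    return RawSystem(H=h, S=s, orbital_meta=meta)
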