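"""Minimal fixed-column PDB writing plus Bio.PDB-backed reading.

Writing is done directly so the B-factor column carries exact two-decimal
connectivity percentages and pseudoatom files stay one-CA-per-residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser

__all__ = ["AtomRecord", "write_pdb", "read_atoms", "read_ca_coords", "format_atom_line"]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Heavy-atom count per residue type (backbone + sidechain, no hydrogens).
HEAVY_ATOM_COUNT = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7,
    "L": 8, "I": 8, "N": 8, "D": 8, "M": 8, "E": 9, "Q": 9,
    "K": 9, "H": 10, "F": 11, "R": 11, "Y": 12, "W": 14,
}


def three_letter(code: str) -> str:
    return _ONE_TO_THREE.get(code.upper(), "UNK")


@dataclass
class AtomRecord:
    name: str
    res_name: str
    chain: str
    res_seq: int
    xyz: np.ndarray
    b_factor: float = 0.0
    element: str = ""
    hetatm: bool = False


def format_atom_line(serial: int, atom: AtomRecord) -> str:
    """One ATOM/HETATM line in strict PDB v3.3 columns."""
    name = atom.name
    if len(name) < 4 and (not atom.element or len(atom.element) == 1):
        name = f" {name}"
    element = atom.element or atom.name.strip()[0]
    record = "HETATM" if atom.hetatm else "ATOM  "
    x, y, z = (float(v) for v in atom.xyz)
    return (
        f"{record}{serial:5d} {name:<4s}{'':1s}{atom.res_name:>3s} {atom.chain:1s}"
        f"{atom.res_seq:4d}{'':4s}{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
        f"{atom.b_factor:6.2f}{'':10s}{element:>2s}"
    )


def write_pdb(atoms, path, remarks=()) -> None:
    """Write atom records; raises ``IOError`` on unwritable paths."""
    lines = [f"REMARK   3 {r}" for r in remarks]
    for serial, atom in enumerate(atoms, start=1):
        lines.append(format_atom_line(serial, atom))
    lines.append("END")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write PDB to {path!r}: {exc}") from exc


def read_atoms(path) -> list[AtomRecord]:
    """Read all atoms from a PDB file."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(path))
    records = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    records.append(
                        AtomRecord(
                            name=atom.get_name(),
                            res_name=residue.get_resname(),
                            chain=chain.id if chain.id.strip() else "A",
                            res_seq=residue.get_id()[1],
                            xyz=np.array(atom.get_coord(), dtype=float),
                            b_factor=float(atom.get_bfactor()),
                            hetatm=residue.get_id()[0].strip() != "",
                        )
                    )
        break  # first model only
    return records


def read_ca_coords(path) -> np.ndarray:
    """CA coordinates of a model, in file order."""
    return np.array(
        [a.xyz for a in read_atoms(path) if a.name == "CA"], dtype=float
    )
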