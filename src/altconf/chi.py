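"""Side-chain chi dihedral topology and rotation kinematics.

IUPAC chi definitions for the 18 chi-bearing standard amino acids
(glycine and alanine have no chi; proline is excluded as ring-constrained).
``set_chi`` rigidly rotates the distal side-chain atoms about the chi bond,
preserving all bond lengths and angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = ["ChiDefinition", "chi_definitions", "measure_dihedral", "set_chi",
           "measure_chi_angles", "apply_chi_angles", "CHI_TOPOLOGY"]


@dataclass(frozen=True)
class ChiDefinition:
    """One chi dihedral of a residue type.

    ``atoms`` is the defining quadruple; ``moving_atom`` (the 4th atom) is
    where map density is measured during a Ringer scan; ``rotating`` is the
    set of atoms rigidly rotated when the chi is set (everything distal to
    the bond between atoms 2 and 3).
    """

    residue_type: str
    index: int
    atoms: tuple[str, str, str, str]
    rotating: frozenset[str]

    @property
    def moving_atom(self) -> str:
        return self.atoms[3]


# (chi quadruple, rotating set) per residue type, chi1..chi4 in order.
# Branched residues measure density at the IUPAC-priority branch atom
# (Val CG1, Thr OG1, Ile CG1); the partner branch still rotates.
_RAW_TOPOLOGY: dict[str, list[tuple[tuple[str, str, str, str], set[str]]]] = {
    "SER": [(("N", "CA", "CB", "OG"), {"OG"})],
    "CYS": [(("N", "CA", "CB", "SG"), {"SG"})],
    "THR": [(("N", "CA", "CB", "OG1"), {"OG1", "CG2"})],
    "VAL": [(("N", "CA", "CB", "CG1"), {"CG1", "CG2"})],
    "ILE": [
        (("N", "CA", "CB", "CG1"), {"CG1", "CG2", "CD1"}),
        (("CA", "CB", "CG1", "CD1"), {"CD1"}),
    ],
    "LEU": [
        (("N", "CA", "CB", "CG"), {"CG", "CD1", "CD2"}),
        (("CA", "CB", "CG", "CD1"), {"CD1", "CD2"}),
    ],
    "ASP": [
        (("N", "CA", "CB", "CG"), {"CG", "OD1", "OD2"}),
        (("CA", "CB", "CG", "OD1"), {"OD1", "OD2"}),
    ],
    "ASN": [
        (("N", "CA", "CB", "CG"), {"CG", "OD1", "ND2"}),
        (("CA", "CB", "CG", "OD1"), {"OD1", "ND2"}),
    ],
    "GLU": [
        (("N", "CA", "CB", "CG"), {"CG", "CD", "OE1", "OE2"}),
        (("CA", "CB", "CG", "CD"), {"CD", "OE1", "OE2"}),
        (("CB", "CG", "CD", "OE1"), {"OE1", "OE2"}),
    ],
    "GLN": [
        (("N", "CA", "CB", "CG"), {"CG", "CD", "OE1", "NE2"}),
        (("CA", "CB", "CG", "CD"), {"CD", "OE1", "NE2"}),
        (("CB", "CG", "CD", "OE1"), {"OE1", "NE2"}),
    ],
    "MET": [
        (("N", "CA", "CB", "CG"), {"CG", "SD", "CE"}),
        (("CA", "CB", "CG", "SD"), {"SD", "CE"}),
        (("CB", "CG", "SD", "CE"), {"CE"}),
    ],
    "LYS": [
        (("N", "CA", "CB", "CG"), {"CG", "CD", "CE", "NZ"}),
        (("CA", "CB", "CG", "CD"), {"CD", "CE", "NZ"}),
        (("CB", "CG", "CD", "CE"), {"CE", "NZ"}),
        (("CG", "CD", "CE", "NZ"), {"NZ"}),
    ],
    "ARG": [
        (("N", "CA", "CB", "CG"), {"CG", "CD", "NE", "CZ", "NH1", "NH2"}),
        (("CA", "CB", "CG", "CD"), {"CD", "NE", "CZ", "NH1", "NH2"}),
        (("CB", "CG", "CD", "NE"), {"NE", "CZ", "NH1", "NH2"}),
        (("CG", "CD", "NE", "CZ"), {"CZ", "NH1", "NH2"}),
    ],
    "HIS": [
        (("N", "CA", "CB", "CG"), {"CG", "ND1", "CD2", "CE1", "NE2"}),
        (("CA", "CB", "CG", "ND1"), {"ND1", "CD2", "CE1", "NE2"}),
    ],
    "PHE": [
        (("N", "CA", "CB", "CG"), {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
        (("CA", "CB", "CG", "CD1"), {"CD1", "CD2", "CE1", "CE2", "CZ"}),
    ],
    "TYR": [
        (("N", "CA", "CB", "CG"), {"CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"}),
        (("CA", "CB", "CG", "CD1"), {"CD1", "CD2", "CE1", "CE2", "CZ", "OH"}),
    ],
    "TRP": [
        (("N", "CA", "CB", "CG"),
         {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
        (("CA", "CB", "CG", "CD1"),
         {"CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    ],
}

_NO_CHI = {"GLY", "ALA", "PRO"}

CHI_TOPOLOGY: dict[str, list[ChiDefinition]] = {
    res: [ChiDefinition(res, i + 1, atoms, frozenset(rot))
          for i, (atoms, rot) in enumerate(entries)]
    for res, entries in _RAW_TOPOLOGY.items()
}


def chi_definitions(residue_type: str) -> list[ChiDefinition]:
    """Ordered chi definitions for a standard residue type.

    GLY and ALA return an empty list; PRO is excluded (its chi angles are
    ring-constrained and not scanned). Unknown types raise ``ValueError``.
    """
    rt = residue_type.upper()
    if rt in _NO_CHI:
        return []
    try:
        return CHI_TOPOLOGY[rt]
    except KeyError:
        raise ValueError(f"unknown residue type {residue_type!r}") from None


def _atom(residue: gemmi.Residue, name: str, altloc: str = "*") -> gemmi.Atom:
    atom = residue.find_atom(name, altloc)
    if atom is None:
        raise KeyError(f"atom {name} missing in {residue.name} {residue.seqid}")
    return atom


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees, in [0, 360)."""
    deg = math.degrees(gemmi.calculate_dihedral(p1, p2, p3, p4))
    return deg % 360.0


def measure_chi(residue: gemmi.Residue, chi: ChiDefinition, altloc: str = "*") -> float:
    pts = [_atom(residue, n, altloc).pos for n in chi.atoms]
    return measure_dihedral(*pts)


def set_chi(residue: gemmi.Residue, chi: ChiDefinition, angle: float,
            altloc: str = "*") -> None:
    """Rotate the distal atoms so that the chi dihedral equals ``angle``.

    The rotation is rigid about the bond between the 2nd and 3rd dihedral
    atoms: bond lengths and angles are untouched, only the dihedral changes.
    With ``altloc`` set, only atoms of that conformer (or blank) move.
    """
    current = measure_chi(residue, chi, altloc)
    delta = math.radians((angle - current) % 360.0)
    b = np.array(_atom(residue, chi.atoms[1], altloc).pos.tolist())
    c = np.array(_atom(residue, chi.atoms[2], altloc).pos.tolist())
    axis = c - b
    axis /= np.linalg.norm(axis)
    # Rodrigues rotation about the b->c axis through point c
    cos_t, sin_t = math.cos(delta), math.sin(delta)
    for atom in residue:
        if atom.name not in chi.rotating:
            continue
        if altloc != "*" and atom.altloc not in ("\0", altloc):
            continue
        v = np.array(atom.pos.tolist()) - c
        rotated = (v * cos_t + np.cross(axis, v) * sin_t
                   + axis * np.dot(axis, v) * (1.0 - cos_t))
        atom.pos = gemmi.Position(*(rotated + c))


def measure_chi_angles(residue: gemmi.Residue, altloc: str = "*") -> list[float]:
    """All chi angles of a residue, in degrees [0, 360)."""
    return [measure_chi(residue, chi, altloc)
            for chi in chi_definitions(residue.name)]


def apply_chi_angles(residue: gemmi.Residue, angles, altloc: str = "*") -> None:
    """Set chi1..chiN sequentially (proximal first, so frames stay valid)."""
    for chi, angle in zip(chi_definitions(residue.name), angles):
        set_chi(residue, chi, angle, altloc)
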