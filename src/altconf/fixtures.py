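"""Ground-truth synthetic fixtures: peptides with planted rotamer ensembles
and density maps computed from them.

The generator builds an extended-backbone peptide from ideal residue
geometry, poses chosen residues in 2-3 named rotamers at chosen occupancies,
and synthesizes a P1 density map as a sum of occupancy-weighted isotropic
atomic Gaussians (amplitude proportional to electron count), optionally with
seeded white noise, sigma-scaled. Every pipeline stage can then be tested
against known ground truth without any downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .chi import apply_chi_angles, chi_definitions
from .io import DensityMap, sigma_scale
from .rotamers import RotamerLibrary, load_rotamer_library

__all__ = ["FixtureSpec", "generate_fixture", "two_state_fixture"]

_BOND_C_N = 1.329
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_N_CA_C = 111.2
_PHI, _PSI, _OMEGA = -139.0, 135.0, 180.0  # extended beta backbone


@dataclass
class FixtureSpec:
    """Recipe for a synthetic peptide + map.

    ``planted`` maps 1-based residue positions to a list of
    (rotamer name, occupancy); occupancies per residue must sum to 1.
    ``noise_sd`` is the white-noise standard deviation relative to the
    noise-free map's sigma. The P1 box pads the model by ``padding``
    Angstroms on every side (at least twice the Gaussian width).
    """

    sequence: tuple[str, ...] = ("ALA", "SER", "ALA")
    planted: dict[int, list[tuple[str, float]]] = field(
        default_factory=lambda: {2: [("m", 0.6), ("p", 0.4)]})
    grid_spacing: float = 0.5
    gaussian_width: float = 0.9
    noise_sd: float = 0.0
    padding: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for idx, states in self.planted.items():
            if not 1 <= idx <= len(self.sequence):
                raise ValueError(f"planted residue {idx} outside sequence")
            total = sum(occ for _, occ in states)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"occupancies at residue {idx} sum to {total}, not 1")
        if self.padding < 2 * self.gaussian_width:
            raise ValueError("padding must be at least twice the Gaussian width")


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF extension: position of atom d given a-b-c and internal coords."""
    theta, phi = math.radians(angle), math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(theta),
                        bond * math.sin(theta) * math.cos(phi),
                        bond * math.sin(theta) * math.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_trace(n_res: int) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """(N, CA, C) positions for an extended peptide."""
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND_N_CA, 0.0, 0.0])
    virtual = np.array([0.0, 1.0, 0.0])  # fixes the first C's dihedral frame
    C = _place_atom(virtual, N, CA, _BOND_CA_C, _ANGLE_N_CA_C, _PHI)
    out = [(N, CA, C)]
    for _ in range(1, n_res):
        N1 = _place_atom(N, CA, C, _BOND_C_N, _ANGLE_CA_C_N, _PSI)
        CA1 = _place_atom(CA, C, N1, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        C1 = _place_atom(C, N1, CA1, _BOND_CA_C, _ANGLE_N_CA_C, _PHI)
        out.append((N1, CA1, C1))
        N, CA, C = N1, CA1, C1
    return out


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t with R @ p + t ~ q for paired points."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def _template_atoms(res_name: str) -> list[tuple[str, str, np.ndarray]]:
    """Heavy atoms (name, element, ideal position) from the CCD template."""
    import biotite.structure.info as info

    arr = info.residue(res_name)
    out = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        element = str(arr.element[i])
        if element == "H" or name == "OXT":
            continue
        out.append((name, element, np.asarray(arr.coord[i], dtype=float)))
    return out


def _build_peptide(sequence: tuple[str, ...]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synthetic peptide"
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    trace = _backbone_trace(len(sequence))
    for i, (res_name, (N, CA, C)) in enumerate(zip(sequence, trace), start=1):
        template = _template_atoms(res_name)
        coords = {n: p for n, _, p in template}
        P = np.array([coords["N"], coords["CA"], coords["C"]])
        Q = np.array([N, CA, C])
        R, t = _kabsch(P, Q)
        residue = gemmi.Residue()
        residue.name = res_name
        residue.seqid = gemmi.SeqId(i, " ")
        for name, element, pos in template:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*(R @ pos + t))
            atom.occ = 1.0
            atom.b_iso = 20.0
            residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _pose_states(residue: gemmi.Residue, states: list[tuple[str, float]],
                 library: RotamerLibrary) -> None:
    """Split a residue's mobile side-chain atoms into altloc states posed at
    the named rotamers' ideal chi means (descending occupancy -> A, B, ...)."""
    defs = chi_definitions(residue.name)
    mobile = set(defs[0].rotating)  # chi1 moves everything distal of CB
    original = {a.name: gemmi.Position(a.pos.x, a.pos.y, a.pos.z) for a in residue}
    ordered = sorted(states, key=lambda s: -s[1])
    poses = []
    for name, occ in ordered:
        entry = library.entry(residue.name, name)
        apply_chi_angles(residue, entry.chi_means)
        poses.append({a.name: gemmi.Position(a.pos.x, a.pos.y, a.pos.z)
                      for a in residue if a.name in mobile})
        for atom in residue:
            atom.pos = original[atom.name]
    template = [(a.name, a.element, a.b_iso) for a in residue]
    while len(residue) > 0:
        del residue[len(residue) - 1]
    for name, element, b_iso in template:
        if name not in mobile:
            atom = gemmi.Atom()
            atom.name, atom.element, atom.b_iso = name, element, b_iso
            atom.pos = original[name]
            atom.occ = 1.0
            atom.altloc = "\0"
            residue.add_atom(atom)
        else:
            for k, (rot_name, occ) in enumerate(ordered):
                atom = gemmi.Atom()
                atom.name, atom.element, atom.b_iso = name, element, b_iso
                atom.pos = poses[k][name]
                atom.occ = occ
                atom.altloc = chr(ord("A") + k) if len(ordered) > 1 else "\0"
                residue.add_atom(atom)


def _gaussian_map(st: gemmi.Structure, spec: FixtureSpec) -> DensityMap:
    positions, weights = [], []
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                positions.append(atom.pos.tolist())
                weights.append(atom.element.atomic_number * atom.occ)
    positions = np.array(positions)
    weights = np.array(weights)
    lo = positions.min(axis=0) - spec.padding
    extent = positions.max(axis=0) - lo + spec.padding
    cell = gemmi.UnitCell(*extent, 90, 90, 90)
    sizes = [max(8, math.ceil(e / spec.grid_spacing)) for e in extent]
    axes = [np.arange(sz) * (e / sz) + lo[i]
            for i, (sz, e) in enumerate(zip(sizes, extent))]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    dens = np.zeros(sizes)
    two_w2 = 2.0 * spec.gaussian_width ** 2
    for p, w in zip(positions, weights):
        r2 = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2
        dens += w * np.exp(-r2 / two_w2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dens = dens + rng.normal(0.0, spec.noise_sd * dens.std(), size=dens.shape)
    grid = gemmi.FloatGrid(dens.astype(np.float32), cell, gemmi.SpaceGroup("P1"))
    # the grid origin is the unit-cell origin: shift the model instead
    _translate(st, -lo)
    return sigma_scale(DensityMap(grid=grid))


def _translate(st: gemmi.Structure, shift: np.ndarray) -> None:
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                atom.pos = gemmi.Position(atom.pos.x + shift[0],
                                          atom.pos.y + shift[1],
                                          atom.pos.z + shift[2])


def generate_fixture(spec: FixtureSpec,
                     library: RotamerLibrary | None = None
                     ) -> tuple[gemmi.Structure, gemmi.Structure, DensityMap]:
    """Build (truth, single, map) from a fixture recipe.

    ``truth`` carries the planted altloc ensembles at the given occupancies;
    ``single`` keeps only the highest-occupancy conformer of each planted
    residue (the typical deposited single-conformer model); ``map`` is the
    sigma-scaled Gaussian density of the full truth ensemble. Identical
    specs (including seed) give bit-identical results.
    """
    lib = library or load_rotamer_library()
    truth = _build_peptide(spec.sequence)
    chain = truth[0][0]
    # non-planted chi-bearing residues sit in their most frequent rotamer
    for i, residue in enumerate(chain, start=1):
        defs = chi_definitions(residue.name)
        if not defs:
            continue
        if i in spec.planted:
            _pose_states(residue, spec.planted[i], lib)
        else:
            entry = max(lib.entries(residue.name), key=lambda e: e.frequency)
            apply_chi_angles(residue, entry.chi_means)
    density = _gaussian_map(truth, spec)  # also recenters truth in the box
    truth.cell = density.grid.unit_cell
    truth.spacegroup_hm = "P 1"

    single = truth.clone()
    for residue in single[0][0]:
        groups: dict[str, list[gemmi.Atom]] = {}
        for atom in residue:
            groups.setdefault(atom.name, []).append(atom)
        keep = []
        for atoms in groups.values():
            best = min(atoms, key=lambda a: (-a.occ, a.altloc or ""))
            best.altloc = "\0"
            best.occ = 1.0
            keep.append((best.name, best.element, best.b_iso,
                         gemmi.Position(best.pos.x, best.pos.y, best.pos.z)))
        while len(residue) > 0:
            del residue[len(residue) - 1]
        for name, element, b_iso, pos in keep:
            atom = gemmi.Atom()
            atom.name, atom.element, atom.b_iso = name, element, b_iso
            atom.pos = pos
            atom.occ = 1.0
            residue.add_atom(atom)
    return truth, single, density


def two_state_fixture(occ_major: float = 0.6, noise_sd: float = 0.0,
                      seed: int = 0, residue: str = "SER",
                      rotamers: tuple[str, str] = ("m", "p")) -> FixtureSpec:
    """Convenience recipe: Ala-X-Ala with X in two rotamers (default
    serine 60% 'm' / 40% 'p'), the canonical minor-conformation test case."""
    return FixtureSpec(
        sequence=("ALA", residue, "ALA"),
        planted={2: [(rotamers[0], occ_major), (rotamers[1], 1.0 - occ_major)]},
        noise_sd=noise_sd, seed=seed)
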