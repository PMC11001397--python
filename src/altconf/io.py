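"""Structure and density-map input/output.

Models are held as :class:`gemmi.Structure` (altloc labels and occupancies
faithful to the file); density maps are wrapped in :class:`DensityMap`, a
sigma-scaled periodic grid that supports trilinear interpolation at arbitrary
Cartesian points.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "MapCoefficients",
    "ParseError",
    "read_structure",
    "write_structure",
    "strip_alternate_conformations",
    "read_ccp4_map",
    "read_mtz_map",
    "map_from_coefficients",
    "sigma_scale",
    "interpolate",
]

#: MTZ amplitude/phase column-label pairs tried in order when none are given.
MTZ_LABEL_DIALECTS = [
    ("2FOFCWT", "PH2FOFCWT"),
    ("FWT", "PHWT"),
    ("FC", "PHIC"),
]


class ParseError(ValueError):
    """Raised when a model or map file cannot be parsed."""


@dataclass
class DensityMap:
    """A 3-D density grid with unit cell and symmetry.

    After :func:`sigma_scale` the voxel values are in sigma units (zero mean,
    unit standard deviation over the grid); ``mean`` and ``sd`` record the
    statistics of the raw grid that were divided out.
    """

    grid: gemmi.FloatGrid
    mean: float = 0.0
    sd: float = 1.0
    sigma_scaled: bool = False

    @property
    def array(self) -> np.ndarray:
        return np.array(self.grid, copy=False)


@dataclass
class MapCoefficients:
    """Amplitude/phase map coefficients (a 2Fo-Fc-style set).

    ``hkl`` is an integer array of shape (n, 3); amplitudes are >= 0 and
    phases are in degrees. Only the crystallographic asymmetric half-set is
    stored; Friedel mates are generated during Fourier synthesis.
    """

    hkl: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    cell: gemmi.UnitCell
    spacegroup: str = "P1"

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.amplitude = np.asarray(self.amplitude, dtype=float).ravel()
        self.phase = np.asarray(self.phase, dtype=float).ravel()
        if not (len(self.hkl) == len(self.amplitude) == len(self.phase)):
            raise ValueError("hkl, amplitude and phase must have equal length")
        keys = {tuple(r) for r in self.hkl}
        if len(keys) != len(self.hkl):
            raise ValueError("duplicate (h,k,l) in coefficient set")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be >= 0")


def read_structure(path: str | os.PathLike) -> gemmi.Structure:
    """Read a PDB or mmCIF model, preserving altlocs and occupancies.

    Format is auto-detected from extension and content. An unreadable or
    empty file raises :class:`ParseError` carrying gemmi's message, which
    names the offending record.
    """
    path = os.fspath(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if sum(len(ch) for model in st for ch in model) == 0:
        raise ParseError(f"{path}: no atoms found (empty or unrecognized file)")
    st.setup_entities()
    return st


def write_structure(st: gemmi.Structure, path: str | os.PathLike,
                    format: str | None = None) -> None:
    """Write a model as PDB or mmCIF (chosen by ``format`` or extension)."""
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "mmcif" if ext in (".cif", ".mmcif") else "pdb"
    if format == "pdb":
        st.write_pdb(path)
    elif format == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'pdb' or 'mmcif')")


def strip_alternate_conformations(st: gemmi.Structure) -> gemmi.Structure:
    """Return a single-conformer copy of the model.

    For every group of atoms sharing a name within a residue, the conformer
    with the highest occupancy is kept (ties broken by the altloc label
    earliest in the alphabet, a blank label sorting first); kept atoms get a
    blank altloc and occupancy 1.0. Altloc-free structures pass through
    unchanged, so the operation is idempotent.
    """
    out = st.clone()
    for model in out:
        for chain in model:
            for residue in chain:
                groups: dict[str, list[gemmi.Atom]] = {}
                order: list[str] = []
                for atom in residue:
                    if atom.name not in groups:
                        groups[atom.name] = []
                        order.append(atom.name)
                    groups[atom.name].append(atom)
                kept: list[gemmi.Atom] = []
                for name in order:
                    group = groups[name]
                    best = min(group, key=lambda a: (-a.occ, a.altloc or ""))
                    best.altloc = "\0"
                    best.occ = 1.0
                    kept.append(best)
                # rebuild atom list in original order
                while len(residue) > 0:
                    del residue[len(residue) - 1]
                for atom in kept:
                    residue.add_atom(atom)
    return out


def read_ccp4_map(path: str | os.PathLike, scale: bool = True) -> DensityMap:
    """Read a CCP4/MRC map, expanded to cover the whole unit cell."""
    m = gemmi.read_ccp4_map(os.fspath(path), setup=True)
    dm = DensityMap(grid=m.grid)
    return sigma_scale(dm) if scale else dm


def read_mtz_map(path: str | os.PathLike, labels: tuple[str, str] | None = None,
                 grid_spacing: float | None = None) -> DensityMap:
    """Fourier-synthesize a sigma-scaled map from MTZ map coefficients.

    Amplitude/phase column labels are auto-detected among the common
    2Fo-Fc dialects (``2FOFCWT/PH2FOFCWT``, ``FWT/PHWT``, ``FC/PHIC``)
    unless given explicitly. Grid spacing defaults to resolution/4.
    """
    mtz = gemmi.read_mtz_file(os.fspath(path))
    if labels is None:
        names = {c.label for c in mtz.columns}
        for pair in MTZ_LABEL_DIALECTS:
            if pair[0] in names and pair[1] in names:
                labels = pair
                break
        else:
            raise ParseError(
                f"{path}: no recognized map-coefficient columns "
                f"(tried {MTZ_LABEL_DIALECTS}); pass labels explicitly")
    d_min = mtz.resolution_high()
    sample_rate = 4.0 if grid_spacing is None else max(d_min / grid_spacing, 1.5)
    grid = mtz.transform_f_phi_to_map(labels[0], labels[1], sample_rate=sample_rate)
    return sigma_scale(DensityMap(grid=grid))


def map_from_coefficients(coeffs: MapCoefficients,
                          grid_spacing: float | None = None) -> DensityMap:
    """Inverse Fourier transform of a coefficient set, sigma-scaled.

    The grid spacing along each axis is at most ``grid_spacing``
    (default: resolution/4). A coefficient set whose synthesis is constant
    (e.g. F000 only) raises ``ValueError('constant map')`` at scaling.
    """
    if len(coeffs.hkl) == 0:
        raise ValueError("empty reflection list")
    cell = coeffs.cell
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup(coeffs.spacegroup)
    mtz.set_cell_for_all(cell)
    mtz.add_dataset("synth")
    mtz.add_column("FWT", "F")
    mtz.add_column("PHWT", "P")
    data = np.column_stack([coeffs.hkl.astype(float), coeffs.amplitude, coeffs.phase])
    mtz.set_data(data)
    if grid_spacing is None:
        d_min = mtz.resolution_high()
        grid_spacing = d_min / 4.0 if d_min > 0 and math.isfinite(d_min) else 1.0
    size = tuple(max(2, math.ceil(x / grid_spacing)) for x in (cell.a, cell.b, cell.c))
    grid = mtz.transform_f_phi_to_map("FWT", "PHWT", exact_size=size)
    return sigma_scale(DensityMap(grid=grid))


def sigma_scale(m: DensityMap) -> DensityMap:
    """Normalize a map to zero mean and unit standard deviation.

    Thresholds elsewhere in the pipeline (e.g. the 0.3-sigma peak cutoff)
    are expressed in these units. Idempotent; a constant grid is an error.
    """
    arr = m.array
    mean = float(arr.mean())
    sd = float(arr.std())
    # FFT round-off can leave ~1e-10 variance on a truly constant synthesis,
    # so near-constancy is judged relative to the grid's own scale
    if (sd <= 0 or not math.isfinite(sd)
            or sd < 1e-6 * max(abs(mean), abs(float(arr.max())))):
        raise ValueError("constant map: cannot sigma-scale a zero-variance grid")
    out_grid = gemmi.FloatGrid(((arr - mean) / sd).astype(np.float32),
                               m.grid.unit_cell, m.grid.spacegroup)
    return DensityMap(grid=out_grid, mean=mean, sd=sd, sigma_scaled=True)


def interpolate(m: DensityMap, point) -> float:
    """Trilinear map interpolation at a Cartesian point (Angstrom).

    The point is fractionalized and wrapped into the unit cell (mod 1), so
    any point related by a lattice translation gives an identical value.
    """
    if isinstance(point, gemmi.Position):
        pos = point
    else:
        pos = gemmi.Position(*point)
    return m.grid.interpolate_value(pos)
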