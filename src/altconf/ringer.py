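"""Ringer-style electron-density sampling around side-chain chi dihedrals.

Each chi of each side chain is rotated through a full turn in fixed angular
steps; at every step the sigma-scaled map is interpolated at the moving
(4th dihedral) atom. The resulting circular density trace reveals minor
conformations as secondary peaks. Input coordinates are restored exactly
after sampling.
"""

from __future__ import annotations

import csv
import logging
import os
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .chi import ChiDefinition, chi_definitions, set_chi
from .io import DensityMap, interpolate

__all__ = ["DihedralTrace", "sample_trace", "sample_residue", "sample_structure",
           "write_trace_csv", "read_trace_csv"]

logger = logging.getLogger(__name__)


@dataclass
class DihedralTrace:
    """Density samples around one chi, at angles 0, step, ..., 360-step."""

    chain: str
    seqid: str          # residue number + insertion code, e.g. "42" or "42A"
    residue_type: str
    chi: int
    step: float
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.step <= 0 or 360.0 % self.step != 0:
            raise ValueError(f"step {self.step} must divide 360")
        if len(self.densities) != round(360.0 / self.step):
            raise ValueError(
                f"{len(self.densities)} samples inconsistent with step {self.step}")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(len(self.densities)) * self.step

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.chain, self.seqid, self.chi)


def _seqid_str(residue: gemmi.Residue) -> str:
    icode = residue.seqid.icode.strip()
    return f"{residue.seqid.num}{icode}"


def sample_trace(residue: gemmi.Residue, density_map: DensityMap,
                 chain_name: str, chi: ChiDefinition,
                 step: float = 5.0) -> DihedralTrace:
    """Scan one chi through 360 degrees, reading map density at the moving atom.

    Original coordinates are restored bit-identically afterwards. The step
    must divide 360 (default 5 degrees, 72 samples).
    """
    if 360.0 % step != 0:
        raise ValueError(f"step {step} must divide 360")
    moving = residue.find_atom(chi.moving_atom, "*")
    if moving is None:
        raise KeyError(f"atom {chi.moving_atom} missing in "
                       f"{residue.name} {residue.seqid}")
    saved = {a.name: gemmi.Position(a.pos.x, a.pos.y, a.pos.z)
             for a in residue if a.name in chi.rotating}
    n = round(360.0 / step)
    densities = np.empty(n)
    try:
        for i in range(n):
            set_chi(residue, chi, i * step)
            densities[i] = interpolate(density_map, moving.pos)
    finally:
        for atom in residue:
            if atom.name in saved:
                atom.pos = saved[atom.name]
    return DihedralTrace(chain=chain_name, seqid=_seqid_str(residue),
                         residue_type=residue.name, chi=chi.index,
                         step=step, densities=densities)


def sample_residue(residue: gemmi.Residue, density_map: DensityMap,
                   chain_name: str, step: float = 5.0) -> list[DihedralTrace]:
    """Traces for every chi of a residue; [] if the type has no chis or
    side-chain atoms are missing (skipped with a warning, not rebuilt)."""
    try:
        defs = chi_definitions(residue.name)
    except ValueError:
        logger.warning("skipping non-standard residue %s %s",
                       residue.name, residue.seqid)
        return []
    if not defs:
        return []
    names = {a.name for a in residue}
    for chi in defs:
        if not set(chi.atoms).issubset(names):
            logger.warning("skipping %s %s%s: missing side-chain atoms for chi%d",
                           residue.name, chain_name, _seqid_str(residue), chi.index)
            return []
    return [sample_trace(residue, density_map, chain_name, chi, step)
            for chi in defs]


def sample_structure(st: gemmi.Structure, density_map: DensityMap,
                     step: float = 5.0) -> list[DihedralTrace]:
    """Traces for every chi of every side chain in the first model."""
    traces: list[DihedralTrace] = []
    for chain in st[0]:
        for residue in chain:
            traces.extend(sample_residue(residue, density_map, chain.name, step))
    return traces


def write_trace_csv(traces: list[DihedralTrace], path: str | os.PathLike) -> None:
    """Write traces as CSV: chain,resnum,icode,restype,chi,step,d0,d1,..."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        n = round(360.0 / traces[0].step) if traces else 72
        writer.writerow(["chain", "resnum", "icode", "restype", "chi", "step"]
                        + [f"d{i}" for i in range(n)])
        for t in traces:
            m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", t.seqid)
            num, icode = m.group(1), m.group(2)
            writer.writerow([t.chain, num, icode, t.residue_type, t.chi,
                             t.step] + [repr(float(v)) for v in t.densities])


def read_trace_csv(path: str | os.PathLike) -> list[DihedralTrace]:
    """Read a trace CSV (native layout, or the upstream Ringer layout where
    the identifying fields are a single joined label like ``SER A 42``)."""
    traces: list[DihedralTrace] = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        return traces
    header = rows[0]
    if header[:6] == ["chain", "resnum", "icode", "restype", "chi", "step"]:
        for lineno, row in enumerate(rows[1:], start=2):
            if not row:
                continue
            try:
                chain, num, icode, restype, chi, step = row[:6]
                dens = np.array([float(v) for v in row[6:]])
                traces.append(DihedralTrace(
                    chain=chain, seqid=f"{int(num)}{icode.strip()}",
                    residue_type=restype, chi=int(chi),
                    step=float(step), densities=dens))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row {lineno}: {exc}") from exc
        return traces
    # upstream layout: "RES CHAIN NUM", "chiN", [map label,] densities...
    for lineno, row in enumerate(rows, start=1):
        if not row:
            continue
        try:
            m = re.fullmatch(r"\s*([A-Z0-9]{1,3})\s+(\S+)\s+(-?\d+)([A-Za-z]?)\s*",
                             row[0])
            if m is None:
                raise ValueError(f"unrecognized residue label {row[0]!r}")
            restype, chain, num, icode = m.groups()
            cm = re.fullmatch(r"chi(\d)", row[1])
            if cm is None:
                raise ValueError(f"unrecognized chi field {row[1]!r}")
            rest = row[2:]
            if rest and not _is_float(rest[0]):
                rest = rest[1:]  # skip map-type label column
            dens = np.array([float(v) for v in rest])
            step = 360.0 / len(dens)
            traces.append(DihedralTrace(
                chain=chain, seqid=f"{int(num)}{icode}", residue_type=restype,
                chi=int(cm.group(1)), step=step, densities=dens))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed row {lineno}: {exc}") from exc
    return traces


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
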