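"""Building ranked rotamers into the model as alternate conformations.

Planned rotamers get altloc labels A, B, ... in decreasing order of
electron-density signal strength, equal starting occupancies summing to
exactly 1.00 at PDB precision, and side-chain coordinates regenerated from
the residue's own geometry with chi angles set to the ideal library means
(occupancy and exact angles are left to refinement). In ALL mode every atom
of the residue is duplicated (backbone copies start coincident, letting
refinement develop backbone heterogeneity); in SIDECHAIN mode alternates
start at the C-alpha atom and N, C, O remain shared with blank altloc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import pandas as pd

from .chi import apply_chi_angles, chi_definitions
from .io import DensityMap, strip_alternate_conformations
from .peaks import detect_peaks
from .ringer import DihedralTrace, sample_residue
from .rotamers import (RotamerCandidate, RotamerLibrary, enumerate_candidates,
                       load_rotamer_library, match_rotamer, rank_and_dedupe)

__all__ = ["AltConfPlan", "PipelineOptions", "make_plan", "build_alternates",
           "build_multi_conformer_model"]

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
#: in SIDECHAIN mode, atoms that stay shared (blank altloc)
SIDECHAIN_SHARED = {"N", "C", "O", "OXT"}


@dataclass
class AltConfPlan:
    """Ordered build plan for one residue: rotamers in descending signal."""

    chain: str
    seqid: str
    residue_type: str
    rotamers: list[tuple[str, tuple[float, ...], float]]  # (name, chi means, signal)
    mode: str = "ALL"
    max_alts: int = 3


@dataclass
class PipelineOptions:
    threshold: float = 0.3       # peak threshold, sigma units
    min_separation: float = 30.0  # circular peak separation, degrees
    tolerance: float = 30.0      # rotamer-matching tolerance, degrees
    max_alts: int = 3
    mode: str = "ALL"            # ALL | SIDECHAIN
    step: float = 5.0            # sampling step, degrees
    symmetry: bool = True        # 180-degree terminal-chi equivalence


def make_plan(ranked: list[RotamerCandidate], library: RotamerLibrary,
              max_alts: int = 3, mode: str = "ALL") -> AltConfPlan:
    """Truncate ranked candidates to the alternate-conformer cap.

    With one surviving candidate (or max_alts=1) no alternates are planned:
    the residue stays single-conformer with a blank altloc.
    """
    if mode.upper() not in ("ALL", "SIDECHAIN"):
        raise ValueError(f"unknown build mode {mode!r}")
    if max_alts < 1:
        raise ValueError("max_alts must be >= 1")
    top = [c for c in ranked if c.matched is not None][:max_alts]
    chain = top[0].chain if top else ""
    seqid = top[0].seqid if top else ""
    rtype = top[0].residue_type if top else ""
    rots = [(c.matched.name, c.matched.chi_means, c.signal) for c in top]
    if len(rots) <= 1:
        rots = []
    return AltConfPlan(chain=chain, seqid=seqid, residue_type=rtype,
                       rotamers=rots, mode=mode.upper(), max_alts=max_alts)


def _split_occupancies(n: int) -> list[float]:
    """Equal 1/n occupancies at 2-decimal precision, first conformer
    absorbing the rounding remainder so the group sums to exactly 1.00."""
    base = round(1.0 / n, 2)
    first = round(1.0 - base * (n - 1), 2)
    return [first] + [base] * (n - 1)


def _find_residue(st: gemmi.Structure, chain_name: str, seqid: str) -> gemmi.Residue:
    for chain in st[0]:
        if chain.name != chain_name:
            continue
        for residue in chain:
            icode = residue.seqid.icode.strip()
            if f"{residue.seqid.num}{icode}" == seqid:
                return residue
    raise KeyError(f"residue {chain_name} {seqid} not found")


def build_alternates(st: gemmi.Structure, plan: AltConfPlan,
                     in_place: bool = False) -> gemmi.Structure:
    """Realize an alternate-conformation plan in a (single-conformer) model.

    Requires the residue to have a complete backbone and the chi-defining
    atoms; a residue failing that is left untouched with a warning.
    """
    out = st if in_place else st.clone()
    if len(plan.rotamers) < 2:
        return out
    residue = _find_residue(out, plan.chain, plan.seqid)
    names = {a.name for a in residue}
    if not {"N", "CA", "C", "O"}.issubset(names):
        logger.warning("skipping %s %s: incomplete backbone", plan.chain, plan.seqid)
        return out
    n = len(plan.rotamers)
    occs = _split_occupancies(n)

    # pose each rotamer on a scratch copy of the residue, record positions
    poses: list[dict[str, gemmi.Position]] = []
    original = {a.name: gemmi.Position(a.pos.x, a.pos.y, a.pos.z) for a in residue}
    for name, chis, signal in plan.rotamers:
        apply_chi_angles(residue, chis)
        poses.append({a.name: gemmi.Position(a.pos.x, a.pos.y, a.pos.z)
                      for a in residue})
        for atom in residue:
            atom.pos = original[atom.name]

    shared = SIDECHAIN_SHARED if plan.mode == "SIDECHAIN" else set()
    template = [(a.name, a.element, a.b_iso) for a in residue]
    while len(residue) > 0:
        del residue[len(residue) - 1]
    for name, element, b_iso in template:
        if name in shared:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = element
            atom.pos = original[name]
            atom.occ = 1.0
            atom.b_iso = b_iso
            atom.altloc = "\0"
            residue.add_atom(atom)
        else:
            for k in range(n):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = element
                atom.pos = poses[k][name]
                atom.occ = occs[k]
                atom.b_iso = b_iso  # B inherited from the replaced atom
                atom.altloc = chr(ord("A") + k)
                residue.add_atom(atom)
    return out


def build_multi_conformer_model(
    st: gemmi.Structure,
    density_map: DensityMap | None,
    options: PipelineOptions | None = None,
    library: RotamerLibrary | None = None,
    traces: list[DihedralTrace] | None = None,
) -> tuple[gemmi.Structure, gemmi.Structure, pd.DataFrame]:
    """Run the full pipeline: strip -> sample -> peaks -> match -> rank -> build.

    Returns ``(multi, single, report)``: the multi-conformer model, the
    companion single-conformer model carrying only the strongest rotamer per
    residue, and a per-residue decision report. ``traces`` may supply
    pre-computed dihedral densities (e.g. from an OMIT map), in which case
    ``density_map`` may be None and the sampling stage is skipped.
    """
    opts = options or PipelineOptions()
    lib = library or load_rotamer_library()
    if density_map is None and traces is None:
        raise ValueError("either a density map or pre-computed traces are required")

    stripped = strip_alternate_conformations(st)
    multi = stripped.clone()
    single = stripped.clone()

    trace_index: dict[tuple[str, str], list[DihedralTrace]] = {}
    if traces is not None:
        for t in traces:
            trace_index.setdefault((t.chain, t.seqid), []).append(t)
        for v in trace_index.values():
            v.sort(key=lambda t: t.chi)

    rows = []
    for chain in stripped[0]:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid():
                continue
            try:
                defs = chi_definitions(residue.name)
            except ValueError:
                continue
            if not defs:
                continue
            seqid = f"{residue.seqid.num}{residue.seqid.icode.strip()}"
            if traces is not None:
                res_traces = trace_index.get((chain.name, seqid), [])
                if len(res_traces) != len(defs):
                    res_traces = []
            else:
                res_traces = sample_residue(residue, density_map, chain.name,
                                            opts.step)
            row = {"chain": chain.name, "seqid": seqid,
                   "residue": residue.name, "n_chi": len(defs),
                   "peaks_per_chi": "", "peak_angles": "", "n_candidates": 0,
                   "n_matched": 0, "built": "", "signals": "", "altlocs": "",
                   "outcome": ""}
            if not res_traces:
                row["outcome"] = "skipped (missing atoms or traces)"
                rows.append(row)
                continue
            peaksets = [detect_peaks(t, opts.threshold, opts.min_separation)
                        for t in res_traces]
            row["peaks_per_chi"] = "/".join(str(len(ps.peaks)) for ps in peaksets)
            row["peak_angles"] = ";".join(
                ",".join(f"{p.angle:g}" for p in ps.peaks) for ps in peaksets)
            candidates = enumerate_candidates(chain.name, seqid, residue.name,
                                              peaksets)
            row["n_candidates"] = len(candidates)
            if not candidates:
                row["outcome"] = "no peaks on every chi"
                rows.append(row)
                continue
            matched = [match_rotamer(c, lib, opts.tolerance, opts.symmetry)
                       for c in candidates]
            ranked = rank_and_dedupe(matched)
            row["n_matched"] = len(ranked)
            if not ranked:
                row["outcome"] = "no library match within tolerance"
                rows.append(row)
                continue
            plan = make_plan(ranked, lib, opts.max_alts, opts.mode)
            top = ranked[0]
            # single-state model: strongest rotamer, blank altloc
            apply_chi_angles(_find_residue(single, chain.name, seqid),
                             top.matched.chi_means)
            if plan.rotamers:
                build_alternates(multi, plan, in_place=True)
                row["built"] = ",".join(r[0] for r in plan.rotamers)
                row["signals"] = ",".join(f"{r[2]:.3f}" for r in plan.rotamers)
                row["altlocs"] = ",".join(chr(ord("A") + k)
                                          for k in range(len(plan.rotamers)))
                row["outcome"] = f"built {len(plan.rotamers)} alternates"
            else:
                apply_chi_angles(_find_residue(multi, chain.name, seqid),
                                 top.matched.chi_means)
                row["built"] = top.matched.name
                row["signals"] = f"{top.signal:.3f}"
                row["outcome"] = "single rotamer"
            rows.append(row)
    report = pd.DataFrame(rows)
    return multi, single, report
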