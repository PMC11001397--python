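"""Rotamer-library matching and candidate ranking.

Per-chi density peaks are assembled into candidate rotamers (Cartesian
product of peaks across chis), validated against an ideal rotamer library
(every chi within a circular tolerance, default 30 degrees), named after the
matching entry, and ranked by signal strength — the sum of the relative peak
intensities across chis.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

from .chi import chi_definitions
from .peaks import PeakSet

__all__ = [
    "RotamerLibraryEntry", "RotamerCandidate", "RotamerLibrary",
    "load_rotamer_library", "circular_difference", "enumerate_candidates",
    "match_rotamer", "rank_and_dedupe", "SYMMETRIC_CHI",
]

#: Terminal chis of 2-fold symmetric groups, compared modulo 180 degrees.
SYMMETRIC_CHI: frozenset[tuple[str, int]] = frozenset({
    ("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2),
})


@dataclass(frozen=True)
class RotamerLibraryEntry:
    residue_type: str
    name: str
    chi_means: tuple[float, ...]
    frequency: float


@dataclass
class RotamerCandidate:
    """One peak combination for a residue, possibly matched to the library.

    ``signal`` is the sum of the per-chi relative peak intensities, in
    (0, n_chi]; the candidate built from the tallest peak of every trace
    scores exactly n_chi.
    """

    chain: str
    seqid: str
    residue_type: str
    angles: tuple[float, ...]
    relative_intensities: tuple[float, ...]
    matched: RotamerLibraryEntry | None = None
    max_deviation: float | None = None

    @property
    def signal(self) -> float:
        return sum(self.relative_intensities)


class RotamerLibrary:
    """Ideal rotamer library: named chi-mean tuples with survey frequencies."""

    def __init__(self, entries: list[RotamerLibraryEntry]):
        self._by_type: dict[str, list[RotamerLibraryEntry]] = {}
        for e in entries:
            self._by_type.setdefault(e.residue_type, []).append(e)

    def residue_types(self) -> list[str]:
        return sorted(self._by_type)

    def entries(self, residue_type: str) -> list[RotamerLibraryEntry]:
        try:
            return self._by_type[residue_type.upper()]
        except KeyError:
            raise KeyError(f"residue type {residue_type!r} not in rotamer library") from None

    def entry(self, residue_type: str, name: str) -> RotamerLibraryEntry:
        for e in self.entries(residue_type):
            if e.name == name:
                return e
        raise KeyError(f"no rotamer {name!r} for {residue_type}")

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_type.values())


def load_rotamer_library(path=None) -> RotamerLibrary:
    """Load a rotamer library CSV (packaged default if no path is given).

    Expected columns: residue, rotamer, chi1..chi4 (blank for unused chis),
    frequency. Validates name uniqueness per residue type and that each
    entry's chi count matches the type's chi topology.
    """
    if path is None:
        with importlib.resources.files("altconf.data").joinpath(
                "rotamer_library.csv").open("r") as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"residue", "rotamer", "chi1", "frequency"}
    if not required.issubset(df.columns):
        raise ValueError(f"rotamer library missing columns {required - set(df.columns)}")
    entries: list[RotamerLibraryEntry] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        rt = str(row["residue"]).upper()
        name = str(row["rotamer"])
        if (rt, name) in seen:
            raise ValueError(f"row {i + 2}: duplicate rotamer ({rt}, {name})")
        seen.add((rt, name))
        means = []
        for k in ("chi1", "chi2", "chi3", "chi4"):
            v = row.get(k)
            if v is None or pd.isna(v):
                break
            means.append(float(v) % 360.0)
        n_expected = _expected_chi_count(rt)
        if len(means) != n_expected:
            raise ValueError(
                f"row {i + 2}: {rt} {name} has {len(means)} chi means, "
                f"expected {n_expected}")
        freq = float(row["frequency"])
        if not 0 < freq <= 1:
            raise ValueError(f"row {i + 2}: frequency {freq} outside (0, 1]")
        entries.append(RotamerLibraryEntry(rt, name, tuple(means), freq))
    return RotamerLibrary(entries)


def _expected_chi_count(residue_type: str) -> int:
    # proline carries library entries (ring pucker, parameterized by chi1)
    # even though the sampler excludes it as ring-constrained
    if residue_type == "PRO":
        return 1
    return len(chi_definitions(residue_type))


def circular_difference(a: float, b: float, period: float = 360.0) -> float:
    """Smallest absolute difference between two angles on a circle."""
    d = abs(a - b) % period
    return min(d, period - d)


def chi_deviation(residue_type: str, chi_index: int, angle: float,
                  mean: float, symmetry: bool = True) -> float:
    """Circular deviation of one chi from a library mean.

    Terminal chis of 2-fold symmetric groups (Asp chi2, Glu chi3,
    Phe/Tyr chi2) are compared modulo 180 degrees when ``symmetry`` is on,
    so an aromatic ring flipped by 180 degrees is the same rotamer.
    """
    period = 180.0 if symmetry and (residue_type, chi_index) in SYMMETRIC_CHI else 360.0
    return circular_difference(angle, mean, period)


def enumerate_candidates(chain: str, seqid: str, residue_type: str,
                         peaksets: list[PeakSet]) -> list[RotamerCandidate]:
    """All peak combinations across chis (Cartesian product), unmatched.

    A residue yields candidates only when every chi trace has at least one
    peak; otherwise the list is empty and the residue gets no alternates.
    """
    if not peaksets or any(len(ps.peaks) == 0 for ps in peaksets):
        return []
    combos = itertools.product(*(ps.peaks for ps in peaksets))
    return [
        RotamerCandidate(
            chain=chain, seqid=seqid, residue_type=residue_type,
            angles=tuple(p.angle for p in combo),
            relative_intensities=tuple(p.relative_intensity for p in combo),
        )
        for combo in combos
    ]


def match_rotamer(candidate: RotamerCandidate, library: RotamerLibrary,
                  tolerance: float = 30.0,
                  symmetry: bool = True) -> RotamerCandidate:
    """Validate a candidate against the library within a per-chi tolerance.

    An entry matches iff every chi deviates by at most ``tolerance`` degrees
    (circularly, with 180-degree periodicity for symmetric terminal chis).
    Among multiple matches the entry with the highest survey frequency wins
    — the rotamer that occurs most often is the one built. No match leaves
    ``matched`` as None.
    """
    if not candidate.angles:
        return replace(candidate, matched=None)
    best: RotamerLibraryEntry | None = None
    best_dev = None
    for entry in library.entries(candidate.residue_type):
        devs = [chi_deviation(candidate.residue_type, i + 1, a, m, symmetry)
                for i, (a, m) in enumerate(zip(candidate.angles, entry.chi_means))]
        if max(devs) > tolerance:
            continue
        if best is None or (entry.frequency, entry.name) > (best.frequency, best.name):
            # frequency tie broken by name so the choice is deterministic
            best, best_dev = entry, max(devs)
    return replace(candidate, matched=best, max_deviation=best_dev)


def rank_and_dedupe(candidates: list[RotamerCandidate]) -> list[RotamerCandidate]:
    """Order matched candidates for building: strongest signal first.

    Candidates mapping to the same rotamer name collapse to the
    highest-signal instance. Ties are broken by descending library
    frequency, then rotamer name.
    """
    best_by_name: dict[str, RotamerCandidate] = {}
    for c in candidates:
        if c.matched is None:
            continue
        prev = best_by_name.get(c.matched.name)
        if prev is None or c.signal > prev.signal:
            best_by_name[c.matched.name] = c
    return sorted(best_by_name.values(),
                  key=lambda c: (-c.signal, -c.matched.frequency, c.matched.name))
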