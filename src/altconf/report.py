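"""Flexibility census and model-to-model comparison summaries.

A residue is "flexible" when any of its atoms carries two or more distinct
altloc labels. The flexibility fraction uses standard amino-acid residues
as the denominator (waters, ligands and ions are excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import pandas as pd

__all__ = ["FlexibilityCensus", "OverlapSummary", "census", "compare"]

ResidueKey = tuple[str, int, str]  # (chain, seqid number, insertion code)


@dataclass
class FlexibilityCensus:
    counts: dict[ResidueKey, int]          # conformers per protein residue
    flexible: frozenset[ResidueKey]        # residues with >= 2 conformers
    n_protein_residues: int

    @property
    def flexible_fraction(self) -> float:
        if self.n_protein_residues == 0:
            return 0.0
        return len(self.flexible) / self.n_protein_residues

    def count_histogram(self) -> dict[int, int]:
        """How many residues have 1, 2, 3, ... conformers."""
        hist: dict[int, int] = {}
        for c in self.counts.values():
            hist[c] = hist.get(c, 0) + 1
        return hist

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"chain": k[0], "resnum": k[1], "icode": k[2], "conformers": v,
              "flexible": k in self.flexible}
             for k, v in sorted(self.counts.items())])

    def to_json(self) -> str:
        return json.dumps({
            "n_protein_residues": self.n_protein_residues,
            "n_flexible": len(self.flexible),
            "flexible_fraction": self.flexible_fraction,
            "count_histogram": {str(k): v for k, v in
                                sorted(self.count_histogram().items())},
            "flexible_residues": [f"{c}{n}{i}" for c, n, i in sorted(self.flexible)],
        }, indent=2)


@dataclass
class OverlapSummary:
    """Which residues are flexible in both models, or only one (Venn-style)."""

    shared: frozenset[ResidueKey]
    only_a: frozenset[ResidueKey]
    only_b: frozenset[ResidueKey]


def census(st: gemmi.Structure) -> FlexibilityCensus:
    """Per-residue conformer counts for the first model of a structure.

    A residue's conformer count is the number of distinct altloc labels on
    its atoms (blank-only residues count 1).
    """
    counts: dict[ResidueKey, int] = {}
    for chain in st[0]:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid() or residue.name == "UNK":
                continue
            key = (chain.name, residue.seqid.num, residue.seqid.icode.strip())
            labels = {a.altloc for a in residue if a.altloc != "\0"}
            counts[key] = max(counts.get(key, 1), len(labels) or 1)
    flexible = frozenset(k for k, v in counts.items() if v >= 2)
    return FlexibilityCensus(counts=counts, flexible=flexible,
                             n_protein_residues=len(counts))


def compare(a: FlexibilityCensus, b: FlexibilityCensus) -> OverlapSummary:
    """Overlap of two models' flexible-residue sets (same numbering space)."""
    return OverlapSummary(
        shared=a.flexible & b.flexible,
        only_a=a.flexible - b.flexible,
        only_b=b.flexible - a.flexible,
    )
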