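"""Optional trace plots: density vs chi angle with threshold line and peaks."""

from __future__ import annotations

import os

from .peaks import PeakSet
from .ringer import DihedralTrace

__all__ = ["plot_trace"]


def plot_trace(trace: DihedralTrace, peakset: PeakSet | None = None,
               threshold: float = 0.3, path: str | os.PathLike | None = None):
    """Plot one dihedral density trace (matplotlib required).

    Marks the sigma threshold as a dotted line and detected peaks as stars.
    Saves to ``path`` if given, else returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(trace.angles, trace.densities, lw=1.2, color="#1f77b4")
    ax.axhline(threshold, ls=":", color="gray", label=f"{threshold}σ")
    if peakset is not None and peakset.peaks:
        ax.plot([p.angle for p in peakset.peaks],
                [p.height for p in peakset.peaks],
                "r*", ms=10, label="peaks")
    ax.set_xlabel(f"χ{trace.chi} angle (°)")
    ax.set_ylabel("density (σ)")
    ax.set_title(f"{trace.residue_type} {trace.chain}{trace.seqid} χ{trace.chi}")
    ax.set_xlim(0, 360)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
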