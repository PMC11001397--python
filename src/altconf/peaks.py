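"""Circular peak detection on dihedral density traces.

A sample is a peak iff it is at or above the sigma threshold and is a strict
local maximum on the circularly wrapped trace (a plateau counts once, at its
leftmost sample). Peaks closer than the minimum circular separation are
thinned greedily, tallest first, so that two peaks can never fall into the
same rotamer well. The wrap is handled natively — no padding — so bumps
straddling the 0/360 seam are found exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ringer import DihedralTrace

__all__ = ["Peak", "PeakSet", "detect_peaks"]


@dataclass(frozen=True)
class Peak:
    angle: float          # degrees in [0, 360)
    height: float         # sigma units, >= detection threshold
    relative_intensity: float  # height / tallest surviving peak, in (0, 1]


@dataclass
class PeakSet:
    chain: str
    seqid: str
    residue_type: str
    chi: int
    peaks: list[Peak]     # sorted by descending height


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def detect_peaks(trace: DihedralTrace, threshold: float = 0.3,
                 min_separation: float = 30.0) -> PeakSet:
    """Find density peaks above ``threshold`` (sigma units) in a trace.

    Returns peaks sorted by descending height with relative intensities
    normalized to the tallest surviving peak. An empty peak list is a valid
    result (no density well above the threshold).
    """
    d = np.asarray(trace.densities, dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("empty trace")
    step = trace.step

    # run-start detection: i opens a plateau iff the previous value differs
    prev = np.roll(d, 1)
    run_start = d != prev
    candidates: list[tuple[float, float]] = []  # (angle, height)
    if run_start.any():
        for i in np.nonzero(run_start)[0]:
            if d[i] < threshold:
                continue
            # walk left/right to the nearest distinct values on the circle
            j = (i - 1) % n
            while d[j] == d[i]:
                j = (j - 1) % n
            k = (i + 1) % n
            while d[k] == d[i]:
                k = (k + 1) % n
            if d[i] > d[j] and d[i] > d[k]:
                candidates.append((i * step, float(d[i])))
    # else: constant trace, no strict local maximum anywhere

    # greedy circular non-maximum suppression, tallest first (tie: smaller angle)
    candidates.sort(key=lambda ah: (-ah[1], ah[0]))
    kept: list[tuple[float, float]] = []
    for angle, height in candidates:
        if all(_circular_distance(angle, ka) >= min_separation for ka, _ in kept):
            kept.append((angle, height))

    peaks: list[Peak] = []
    if kept:
        tallest = kept[0][1]
        peaks = [Peak(angle=a, height=h, relative_intensity=h / tallest)
                 for a, h in kept]
    return PeakSet(chain=trace.chain, seqid=trace.seqid,
                   residue_type=trace.residue_type, chi=trace.chi, peaks=peaks)
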