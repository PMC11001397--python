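"""Ringer scan: density around a chi dihedral, and its detected peaks.

Rotates the serine OG through 360 degrees in 5-degree steps, interpolating
the sigma-scaled map at each pose, then finds circular local maxima above
the 0.3-sigma threshold.
"""

import numpy as np

from altconf import detect_peaks, generate_fixture, sample_residue, two_state_fixture

_, single, density = generate_fixture(two_state_fixture())
trace = sample_residue(single[0][0][1], density, "A")[0]

print(f"{trace.residue_type} {trace.chain}{trace.seqid} chi{trace.chi}: "
      f"{len(trace.densities)} samples, step {trace.step} deg")
peaks = detect_peaks(trace, threshold=0.3)
for p in peaks.peaks:
    print(f"  peak at {p.angle:5.1f} deg  height {p.height:.2f} sigma  "
          f"relative intensity {p.relative_intensity:.2f}")
print()
print("Two wells: the tall peak near 295 deg is the major 'm' rotamer")
print("(chi1 mean -65), the second near 60 deg is the minor 'p' state that a")
print("single-conformer model would miss.")
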