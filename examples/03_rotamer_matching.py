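"""Candidate assembly and rotamer-library validation.

Peaks from each chi trace are combined (Cartesian product), each combination
is checked against the ideal rotamer library (every chi within 30 degrees,
highest-frequency entry wins), and survivors are ranked by signal strength —
the sum of relative peak intensities across chis.
"""

from altconf import (Peak, PeakSet, enumerate_candidates, load_rotamer_library,
                     match_rotamer, rank_and_dedupe)

library = load_rotamer_library()
print(f"library: {len(library)} rotamers across "
      f"{len(library.residue_types())} residue types")
print("THR rotamers:", [(e.name, e.chi_means[0], e.frequency)
                        for e in library.entries("THR")])

# a leucine with two chi1 wells and one chi2 well
chi1 = PeakSet("A", "5", "LEU", 1, [Peak(295.0, 2.0, 1.0), Peak(180.0, 1.2, 0.6)])
chi2 = PeakSet("A", "5", "LEU", 2, [Peak(175.0, 1.8, 1.0)])
candidates = [match_rotamer(c, library)
              for c in enumerate_candidates("A", "5", "LEU", [chi1, chi2])]
for c in rank_and_dedupe(candidates):
    print(f"  angles {tuple(round(a) for a in c.angles)} -> rotamer "
          f"{c.matched.name!r} (freq {c.matched.frequency:.2f}), "
          f"signal {c.signal:.2f}")
print()
print("(295, 175) matches 'mt' (chi1 -65, chi2 175) and outranks the weaker")
print("(180, 175) combination; both would be built, strongest first.")
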