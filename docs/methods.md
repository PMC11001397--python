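# Methods

## Model and procedure

`altconf` treats alternate side-chain conformations as a discrete model
selection problem over rotamers. The evidence is a σ-scaled electron-density
map (voxels normalized to zero mean, unit standard deviation over the grid);
the hypothesis space is the ideal rotamer library; the link between them is
the Ringer scan: for a χ dihedral defined by atoms (a₁, a₂, a₃, a₄), the
moving atom a₄ and everything distal to the a₂–a₃ bond is rigidly rotated
through 360°, and the map is interpolated trilinearly at a₄ after each step.
Genuine conformers appear as peaks of this circular trace; their relative
heights track relative occupancy, which is why candidates are ranked by the
sum of per-trace relative peak intensities and built in that order.

The pipeline enforces a single-conformer starting model: existing altlocs
are collapsed to the highest-occupancy conformer (ties: alphabetically
earliest label) before sampling, so that the scan always starts from one
well-defined geometry and pre-existing alternates must re-earn their place
from the density.

Built conformers use the matched library entry's ideal χ means rather than
the detected peak angles: detected peaks are step-quantized and skewed by
background density from neighboring atoms, while ideal rotamers are the
correct prior geometry for refinement to polish. Peak angles are preserved
in the decision report. A corollary is that the input conformation is not
specially protected — it re-emerges only if its well has a peak.

## Key parameters

| parameter | default | unit | notes |
|---|---|---|---|
| peak threshold | 0.3 | σ | minimum trace density for a peak |
| sampling step | 5 | ° | must divide 360; 72 samples per χ |
| peak separation | 30 | ° | circular non-maximum suppression radius |
| matching tolerance | 30 | ° | per-χ, circular; symmetric terminal χ mod 180° |
| max alternates | 3 | — | per residue, after signal ranking |
| build mode | ALL | — | duplicate whole residue; SIDECHAIN starts at Cα |
| starting occupancy | 1/n | — | first conformer absorbs rounding so Σ = 1.00 |

The 30° peak separation deliberately equals the matching tolerance: two
peaks closer than that would necessarily map to the same library well, so
the shorter one carries no extra information. The threshold and separation
are exposed because real maps vary in noise level; the defaults are the
working values for ordinary 2Fo−Fc maps at ≤ 2 Å.

In ALL mode, backbone copies are created coincident; they are not meant to
differ at build time, but giving each conformer its own backbone lets
refinement develop genuine backbone heterogeneity where the density wants
it. SIDECHAIN mode labels Cα and outward; N, C, O stay shared.

## Peak detection semantics

A sample is a peak iff it is ≥ threshold and a strict local maximum on the
circularly wrapped trace, comparing against the nearest *distinct* values on
either side; a plateau counts once, at its leftmost sample (leftmost =
the sample whose predecessor differs). Suppression is greedy tallest-first
(tie: smaller angle). The wrap is handled natively rather than by padding,
so a bump straddling 0°/360° yields exactly one peak. A constant trace has
no strict maximum and yields none. These semantics are frozen by a
brute-force reference implementation that the test suite compares against
on a thousand random traces, including plateau-heavy and seam-straddling
ones.

## Rotamer library

The packaged table (`altconf/data/rotamer_library.csv`) follows the
penultimate rotamer library convention: per residue type, named rotamers
(p/t/m concatenations, or the survey's descriptive names for terminal
angles), mean χ values at the canonical gauche+/trans/gauche− wells, and
survey population frequencies. It is a curated transcription of the
canonical well positions and commonly cited frequencies, not a verbatim
copy of any distribution file; frequencies need not sum to 1 because rare
rotamers are omitted. Proline carries ring-pucker entries for completeness
although the sampler excludes it (its χ is ring-constrained); glycine and
alanine have no χ. All 18 χ-bearing types are covered. The library is
user-overridable (`--rotamer-lib`), with validation of name uniqueness,
χ-count consistency and frequency range.

Terminal χ of 2-fold symmetric groups (Phe/Tyr χ2, Asp χ2, Glu χ3) are
compared modulo 180°, since a flipped ring or carboxylate is the same
conformer; this is switchable (`symmetry=False`) for comparison with tools
that do not fold the symmetry.

## Synthetic fixtures

The generator builds an extended-backbone peptide (NeRF extension with
standard bond lengths/angles, φ = −139°, ψ = 135°) from ideal residue
templates, poses chosen residues in named rotamers at chosen occupancies,
and computes a P1 map as a sum of occupancy-weighted isotropic Gaussians,
amplitude proportional to the element's electron count, shared width 0.9 Å,
on a grid of ≤ 0.5 Å spacing padded 6 Å from the model. Optional white
noise (expressed relative to the signal map's σ) is added before σ-scaling;
everything is seeded and bit-reproducible.

What this emulates: the geometry of overlapping conformer density, relative
peak heights tracking occupancy, and threshold behavior. What it does not:
true scattering factors and B-factor falloff, resolution-dependent series
termination, phase error, solvent and lattice-neighbor density, and
anisotropy. Passing the recovery tests therefore demonstrates the
decision logic is correct given density whose peaks sit at the right angles
with occupancy-ordered heights — not that any particular real map is that
clean. The default two-state fixture (Ala-Ser-Ala, Ser 60% `m` / 40% `p`,
noise 0.2σ for the Monte-Carlo variant) is the smallest case exercising
every stage.

"Recovery" in the noisy Monte-Carlo experiment means both planted rotamers
are rebuilt with altloc A assigned to the major state. Noise can
additionally promote a weak background maximum (e.g. the unoccupied `t`
well, which sits on ~1.9σ background in this fixture) past the 0.3σ
threshold, adding a third low-signal alternate; that is the documented
behavior of a low threshold, not a recovery failure — raising the threshold
removes it, which the threshold-semantics test exercises directly.

## Numerical choices

- Interpolation is trilinear on the wrapped fractionalized coordinate
  (gemmi); adequate at working resolutions, exact on grid nodes, and
  lattice-periodic to machine precision. Tricubic was considered and
  rejected as untestable by a simple closed form.
- σ-scaling is idempotent; a grid whose standard deviation is ≤ 1e-6 of its
  own scale (catching FFT round-off on constant syntheses) is rejected as a
  constant map.
- Chi rotations use Rodrigues' formula about the a₂→a₃ axis; set-then-
  measure round-trips to < 1e-6° and preserves all intra-side-chain
  distances to < 1e-9 Å. Sampling snapshots and restores coordinates
  exactly (bitwise).
- Map-coefficient synthesis picks the grid as ⌈cell/spacing⌉ per axis
  (default spacing: resolution/4); MTZ column labels are auto-detected
  among 2FOFCWT/PH2FOFCWT, FWT/PHWT, FC/PHIC, overridable. If both a map
  file and an MTZ are supplied, the map file wins.
- Occupancy splitting rounds 1/n to PDB precision with the first conformer
  absorbing the remainder (3 → 0.34/0.33/0.33). B factors are inherited
  from the atoms being replaced.
- Ties are deterministic everywhere: altloc-strip ties → earliest label;
  suppression ties → smaller angle; matching frequency ties → name order;
  ranking ties → higher library frequency, then name.

## Problem sizes

The test suite and the acceptance script run entirely on generated
fixtures: 3-residue peptides with maps of ~5 × 10⁴ voxels, 1000-trace and
18 × 1000-tuple oracle comparisons, and a 20-seed noise study — a few
seconds end to end. These sizes were chosen as the smallest that exercise
every code path and give stable Monte-Carlo rates.

## Known limitations

- Only side-chain χ dihedrals are scanned; backbone φ/ψ heterogeneity
  arises (in ALL mode) only through downstream refinement.
- Branched residues are measured at the IUPAC-priority branch atom only
  (Val CG1, Thr OG1, Ile CG1); a tool measuring both branches may detect
  peaks this implementation attributes to the partner atom.
- Candidate assembly requires a peak on *every* χ; long side chains with
  one noisy trace yield no alternates rather than partial ones.
- No occupancy refinement, clash resolution or solvent remodeling; outputs
  are starting points for crystallographic refinement.
- Residues with missing side-chain atoms are skipped, not rebuilt.
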