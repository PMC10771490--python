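# Methods

This note documents the models and procedures implemented in `septkit`, the
parameters that matter, the numerical choices behind them, and what the
synthetic fixtures do and do not establish.

## Coordinate model and numbering

Structures are held as ordered chains of ordered residues with explicit
atoms; parsing and serialisation go through gemmi. Author residue numbering
(as deposited) is the only numbering scheme: septin residue labels in the
literature (V13, F297, Q281, …) are author numbers, and re-indexing would
silently break every cross-reference. Consequences:

- residues are ordered by (residue_number, insertion_code) within a chain;
- sequence extraction returns (sequence index, author number, one-letter
  code) triples so motif positions can be anchored to coordinates;
- where altlocs conflict, the highest-occupancy conformer is kept, ties
  broken alphabetically — a deterministic policy, since the source studies
  do not state one;
- nonstandard residues map to 'X' and are excluded from motif scanning;
  selenomethionine is not silently read as methionine (an explicit
  `mse_as_met` flag enables the conversion). Determinism is preferred over
  convenience here: a silent MSE→M conversion changes scan results
  depending on crystallisation chemistry.

Subunit identity in a multi-chain file is established by sequence (alignment
identity), never by chain order, because chain labelling conventions vary
between depositions.

## Superposition and RMSD-Cα

Residue pairing precedes superposition because the compared chains are
often homologs (different proteins) rather than copies. `by_number` pairs
identical author numbers; `by_alignment` globally aligns the one-letter
sequences with match +1 / mismatch 0 / gap −1 (no affine gap model) and
pairs the aligned non-gap columns. The simple scoring is deliberate: the
compared chains are high-identity homologs, and a fixed scheme keeps
pairings reproducible. Fewer than 3 pairs is an error (the rigid transform
would be underdetermined).

The optimal rigid transform is the closed-form Kabsch solution: SVD of the
cross-covariance of centred point sets, with the smallest singular
direction sign-flipped whenever the raw optimum is a reflection, so the
returned rotation always has determinant +1. Collinear input degenerates
gracefully (warning; the least-squares proper rotation is still returned).
All CA pairs enter the fit; there is no outlier rejection or trimming. RMSD
values computed by different packages can therefore differ at the 0.1 Å
level depending on their pairing and rejection heuristics; comparisons with
externally reported RMSD-Cα values should allow roughly ±0.15 Å for that
procedural spread.

The per-residue profile applies the global transform once and reports each
pair's CA deviation; the RMS of the profile equals the global RMSD-Cα by
construction (asserted to 1e-9 relative in tests). The profile is the tool
for localising conformational change (e.g. a displaced C-terminal
β-meander) rather than summarising it.

### Grafting

`assemble_by_grafting` builds larger complexes from two partial structures
sharing one subunit: the addon is rigidly moved so its copy of the shared
chain superposes onto the base's copy (all-CA, alignment pairing), the
shared addon copy is dropped, and remaining addon chains join under fresh
IDs. Grafting refuses chains below 90% aligned identity — the operation is
only meaningful through two copies of the same protein. The result reports
the graft RMSD-Cα and a steric-clash count (heavy-atom pairs < 2.2 Å
between chains that did not coexist in either input). Clashes are counted,
never resolved: a grafted octamer model is a rigid composition of its
inputs, not an energy-minimised structure, and the slight curvature such
models show is a feature of the inputs, not something to relax away.

## Solvent accessibility

Shrake–Rupley with a golden-spiral point lattice: each heavy atom's sphere
is expanded by the probe radius, sampled at `sphere_points` quasi-uniform
points, and the accessible fraction (points outside every neighbour's
expanded sphere) scales the full sphere area. Defaults: probe 1.4 Å
(water), 960 points per atom, van der Waals radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å. At 960 points the isolated-sphere value is exact to well
under 1% and doubling the density moves atom areas by < 1%. Hydrogens are
always excluded: crystal structures carry none, and mixed conventions would
make complex/chain comparisons incoherent.

Relative SASA divides a residue's summed atom area by its theoretical
maximum in an extended Gly-X-Gly tripeptide (Tien et al. 2013 theoretical
values), in percent. Values above 100% occur for highly extended or
terminal residues and are reported as-is. The burial bands are: buried
≤ 7% (the deep-burial band characteristic of crest key residues packed into
the partner subunit's hydrophobic cleft), exposed ≥ 25% (a common
convention; the source analyses define only the buried band), intermediate
between. Published relative-SASA percentages computed with other tools and
unstated normalisation references should be compared with ±3 percentage
points of slack; if a published value cannot be reproduced under any
standard reference table the discrepancy should be recorded, not tuned
away with bespoke radii.

## The hydrophobic-crest motif

The NC-interface's lower part is stabilised by a ridge of hydrophobic
residues spanning the hook loop, the α0-helix and the first β1 residue. The
19-position consensus constrains positions {1, 2, 3, 6, 7, 9, 10, 15, 19};
the six key positions {1, 3, 6, 10, 15, 19} carry the buried ridge.
Hydrophobicity ('h') is evaluated against a pluggable scale; the packaged
default is the Eisenberg normalized consensus scale with threshold 0.5,
under which the hydrophobic set is exactly {I, F, V, L} (a test guards the
transcription).

Real septins violate individual soft constraints — a threonine at position
7, an arginine at position 10 — so strict matching would reject canonical
instances. The default scan mode is therefore *scored*: hard anchors
{1, 3, 19} must hold and at least half of the remaining constrained
positions must pass (`min_score` 0.5). *Strict* requires every constraint;
*anchored* evaluates one stated window with no thresholding, which is the
correct mode when the anchor residue is known and the question is "which
constraints does this instance satisfy". Unknown residues ('X') fail any
constrained position they occupy.

Key-position arithmetic is closed-form: with the anchor at author residue
a, key positions 1/3/6/10/15/19 sit at a, a+2, a+5, a+9, a+14, a+18
(contiguous numbering assumed; a supplied non-contiguous numbering map is
used instead, with a warning). The inverse mapping recovers the anchor from
any single key position.

Column conservation (degree 0–10) is round(10 × dominant
physicochemical-class frequency) with classes (ILVM) (FWY) (C) (AG) (ST)
(NQ) (DE) (KR) (H) (P); gaps form a non-scoring class, so all-gap columns
score 0. This is an approximation documented as such — published 0–10
conservation tracks from alignment viewers use unstated formulas, and this
implementation does not claim digit-for-digit agreement with any of them.
Consensus frequencies exclude gaps from the denominator (gap fraction
reported separately); ties resolve to the alphabetically first residue and
are flagged. Multiple alignments are consumed, never computed.

## Disulfide screening

Candidate crosslink sites across an interface are residue pairs whose
beta-carbons could plausibly be bridged by cysteines: CB–CB within
3.0–5.5 Å around the 4.0 Å disulfide ideal, CA–CA ≤ 7.5 Å as a backbone
sanity filter, ranked by |CB–CB − 4.0| with a deterministic (chain,
residue) tie-break. The window is deliberately wide because pre-mutation
side chains are not cysteines and the post-mutation geometry will relax.
Glycines are screened via a virtual CB placed at ideal tetrahedral geometry
from N, CA and C (1.53 Å bond, ~54.75° out-of-plane tilt on the proper
side of the backbone plane); reconstruction accuracy against ideal residue
geometry is ~0.1 Å and tested to < 0.35 Å under arbitrary rigid placements.
The screen is purely geometric recall — no machine-learned crosslink
probability, no χ-dihedral modelling, no mutant structure generation. Its
contract is that genuinely engineerable pairs appear in the list, not that
the list is short.

## Nucleotide quantification

Peak areas are trapezoidal integrals of (absorbance − baseline) over
user-supplied windows; the default baseline linearly interpolates between
the absorbances at the window edges (`flat` uses zero). Windows are never
auto-detected — species are identified by calibrated retention volumes, so
window placement is an input; a maximum-finding helper exists for
interactive placement but is never applied silently. Net-negative areas
clip to zero with a warning.

Calibration fits a least-squares line through the origin per species
(response = Σc·A / Σc², r² reported): Beer–Lambert proportionality with no
intercept term, requiring ≥ 2 standards. Concentration is area/response.

The per-subunit content corrects the protein concentration for the 280 nm
absorbance of the bound nucleotides themselves: the apparent complex
concentration c_app overstates protein by ε_g·([GDP]+[GTP])/ε_s, so

    content = ([GDP]+[GTP]) · ε_s / ( n · (ε_s·c_app − ε_g·([GDP]+[GTP])) ).

All constants are parameters with the tetrameric yeast septin complex's
values as defaults (ε_s 113 570 M⁻¹cm⁻¹, ε_g 7 720 M⁻¹cm⁻¹, c_app 15 µM,
n = 4), so the operation transfers to other stoichiometries. With ε_g = 0
it reduces to the uncorrected molar ratio; the correction is always ≥ the
uncorrected value and strictly increasing in total nucleotide over its
valid domain (ε_s·c_app > ε_g·total; beyond that the implied protein
concentration is nonpositive and the input is rejected as physically
inconsistent).

## Synthetic fixtures: what they are and are not

All fixtures are seed-deterministic and carry truth dictionaries sufficient
to predict every assertion made on them.

- **Ideal helix**: poly-alanine, rise 1.5 Å/residue, twist 100°/residue,
  CA radius 2.3 Å, ideal-geometry residue template (full backbone + CB).
  Consecutive CA distances land at 3.83 Å.
- **Transformed pair**: rigid copy (intrinsic xyz Euler angles +
  translation) with optional isotropic Gaussian coordinate noise. For noise
  sd σ the expected recovered RMSD is ≈ σ√3; tests accept [0.8, 1.2]·σ√3.
- **Interface dimer**: a 36-residue helix packed against a flipped copy of
  its middle third, translated until the closest cross-chain CB–CB pair
  sits at exactly 4.0 Å (root-found, so the planted disulfide candidate has
  penalty 0). Truth lists contact residues (< 4.5 Å to the partner),
  far residues (> 10 Å) and the planted pair.
- **Motif sequences**: uniform-random backgrounds with consensus-conforming
  crest instances at stated offsets; backgrounds are resampled in the
  vanishingly rare case a spurious strict match appears, so strict-scan
  recovery of the planted offsets is exact by construction.
- **Chromatograms**: sums of Gaussians with area = concentration ×
  response on a zero baseline plus Gaussian detector noise. The emulated
  regime follows the biological setting the quantification was built for: a
  GDP-dominated pool (fraction drawn from 0.6–0.95 around the ~87% GDP
  observation for the tetramer) totalling 30–60 µM, as released by a 15 µM
  four-subunit complex, with noise sd 0.002 AU. In this regime the
  endpoint-interpolated baseline recovers the GDP fraction within ±0.02;
  with far smaller minor peaks (≲ 2% of a ≲ 20 µM pool) the baseline
  uncertainty becomes comparable to the peak area and that tolerance no
  longer holds — a limitation of endpoint baselines, not of the integrator.

What passing on fixtures shows: the geometry, scanning, integration and
algebra are correct against independent oracles (dense-sampling surface
integration, regular-expression scanning, brute-force pair enumeration,
closed-form arithmetic) under known ground truth. What it does not show:
agreement with numbers computed from deposited coordinate sets, which
depend additionally on the depositor's model (altlocs, gaps, B-factors) and
on the comparison tool's pairing/normalisation conventions. Analyses of
real structures consume those files as inputs and inherit the tolerance
notes above (±0.15 Å on RMSD-Cα, ±3 points on relative SASA).

## Problem sizes and numerical tolerances

Property tests use 1000 random point sets (Kabsch propriety), 500 random
sequences (scanner ≡ regex), 100 random structures (I/O round-trip, ≤ 3
chains × 8 residues), 50 seeded chromatograms (fraction recovery) and
≤ 50-atom clusters (SASA convergence) — sizes at which each property is
already fully exercised. Fixed tolerances: rotation orthonormality 1e-8;
round-trip coordinates 1e-3 Å (PDB 8.3 fields); profile-RMS vs global RMSD
1e-9 relative; SASA vs dense oracle 2% of the isolated-sphere scale;
Gaussian area 0.5%.

## Known limitations

- No flexible or sequence-independent structural alignment; superposition
  is rigid over an explicit pairing.
- SASA is accessible-surface only (no molecular surface, no per-atom
  depth); the exposed ≥ 25% threshold is a convention, not a measurement.
- The conservation degree approximates, but does not reproduce, any
  specific alignment viewer's score.
- The disulfide screen models no side-chain dihedrals and assigns no
  probabilities.
- Peak integration does not fit peak shapes or deconvolve overlaps; badly
  overlapping windows are flagged by the generator, not resolved.
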