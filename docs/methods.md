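# Methods

This note records the models, conventions and numerical choices behind
`protosym`, in the order the pipeline applies them.

## Coordinate model and membrane frame

Structures are reduced to Cα traces (`gemmi` handles PDB/mmCIF parsing;
first model only, alternate locations resolved by highest occupancy then
label order, nonstandard amino acids mapped to a parent letter where a
tabulated parent exists and to `X` otherwise).  All geometry lives in a
*membrane frame*: a unit normal pointing to the extracellular (EC) side and
an offset placing the membrane mid-plane at signed depth 0.  Inputs oriented
by the OPM convention (mid-plane = the z = 0 plane, EC at z > 0) use the
identity frame.  For other inputs `orient_fallback` averages the
transmembrane helix axes (sign-flipped into a common hemisphere) to get the
normal and centres the mid-plane on the mean helix midpoint; which membrane
side is EC cannot be inferred from geometry alone, so a user flag states
the side on which the first helix starts.  The frame's core half-width
defaults to 15 Å, a standard hydrophobic-slab half-thickness.

Projections "viewed from the EC side" use an in-plane right-handed basis
(e₁, e₂) with e₁×e₂ = normal; in those 2D coordinates a positive signed
area is counterclockwise for an observer on the EC side looking down.

## TM segments and hydrophobic centers

A TM segment is a maximal run of ≥ 12 residues that is locally helical
(Cα i→i+3 distance in [4.5, 5.7] Å for ≥ 70 % of the run; unmarked gaps of
≤ 2 residues are bridged to tolerate proline kinks) and that either crosses
the mid-plane or spans ≥ 80 % of the core width.  Runs are delimited by
chain breaks — a jump in author numbering or consecutive Cα further than
6 Å apart.  Two antiparallel helices joined by a one- or two-residue
modelled turn could in principle merge into one run; reentrant half-helices
(aquaporin/FocA TM2a/2b) are deliberately kept as single segments.

The *hydrophobic center* h of a segment is the residue with |depth|
minimal; ties break toward the N-terminus (the convention is needed for
determinism; depth ties are otherwise arbitrary).  Segment direction
(up/down) is the sign of the depth change N→C; the helix axis is the
leading principal axis of the centered Cα cloud, oriented N→C.

A sliding-window hydropathy predictor (`predict_tm_hydropathy`,
Kyte–Doolittle scale by default, a von-Heijne-style biological scale as an
alternative; window 19, threshold 1.6) provides sequence-only TM regions for
mfta-style annotation.  Runs above threshold merge when separated by < 3
residues and are normalized to 17–25 residues; runs longer than 25 are split
by repeatedly carving a 21-residue window centered on the hydropathy
maximum.  Structure-derived segments always take precedence over predicted
ones when both exist.

## Protodomain alignment

The published analyses optimized protodomain superpositions interactively;
reproducibility requires an algorithm, so the aligner is a deterministic
seed/refine/trim procedure:

1. **Seed.**  Helix k of protodomain A pairs with helix k of protodomain B;
   within a helix pair, residues pair by signed rank relative to the
   hydrophobic centers, truncated to the shorter side.  Because helical
   alignments are ambiguous under whole-turn translations, the seed register
   is probed at shifts of 0 and ±4 residues and each candidate is carried
   through refinement independently; the lowest final RMSD wins.
2. **Refine.**  Up to 10 rounds: Kabsch fit on the current pairs, then a new
   correspondence per helix pair by dynamic programming on the inter-Cα
   distance matrix.  The DP maximizes Σ (d_cut − d) over matched pairs
   (matches only under d_cut = 6 Å) minus a penalty of 3 Å-equivalents per
   *interior* skipped residue; residues outside the matched span of a helix
   (its boundaries) are free.  Iteration stops when the RMSD changes by
   < 0.01 Å.
3. **Trim.**  Pairs with residual > 5 Å are dropped and the fit repeated;
   fewer than 9 surviving pairs is an alignment failure.

All five constants (d_cut, trim, gap penalty, iterations, convergence) are
config-exposed.  Correspondences are order-preserving within a protodomain;
cross-topology comparisons (e.g. a transporter's helices 1-6-7 against
another family's 1-2-3) are expressed by constructing an explicitly
reordered protodomain definition, never by non-monotone matching.  Multiple
alignment to a reference merges pairwise alignments through the reference's
residues (insertions relative to the reference are dropped from the merged
view; the per-entry pairwise alignments keep them).

## Symmetry detection

Internal symmetry: for order 2, the first ⌊n/2⌋ helices form block one and
block two slides over all legal offsets (allowing a skipped linker helix,
as in TM123 vs TM567 with TM4 between); each candidate pair is aligned and
the minimum-RMSD candidate whose rotation angle is within 15° of 180° and
whose RMSD is under 4.0 Å wins.  Order 3 (helix-pair triplication) checks
consecutive blocks under the same rules and requires consistent axes.  A
user-supplied split bypasses the search — the escape hatch for structures
where automated detection fails, which is common for GPCRs.  No candidate
→ an order-1 ("no symmetry") result, not an exception.

The axis/normal angle classifies topology: < 45° parallel, otherwise
inverted.  Quaternary detection groups chains by sequence identity ≥ 0.9
(difflib ratio), superposes the first chain of the largest group onto every
other, and accepts Cn when the rotations share an axis within 20° and their
signed angles hit distinct multiples of 360/n within 15°.  Point groups:
tertiary C2 ⊥ quaternary Cn → Dn; parallel axes or a single level → Cn; two
perpendicular internal C2 axes alone → D2 (the domain-duplicated,
MFS-like case).  All tolerances are config keys.

## Topology-conformation/assembly codes

For 3TMH protodomain pairs, viewed from the EC side:

- **Chirality** — `c` when traversing protodomain 1's projected helix
  centroids in label order 1→2→3 turns clockwise, `cc` otherwise;
  undefined (error) when the triangle area is ≤ 1 Å².  Negating the frame
  normal (viewing from the IC side) flips c↔cc, as it must.
- **Arrangement** — the digit string places the *apex* helix (the helix of
  protodomain 1 whose projected centroid lies farthest from protodomain 2's
  projected centroid) in the middle, flanked by the two interface helices,
  smaller label first.  A purely triangle-intrinsic reading (walking the
  perimeter from helix 1) cannot work: it ties the digit order to the
  chirality letter one-to-one, while the four reference folds realize all
  four arrangement × chirality combinations.  Anchoring the string on the
  assembly interface makes the two parts independent and reproduces the
  reference codes (132c, 123c, 123cc, 132cc with their s-codes) on
  schematic geometries; the walk direction the original notation intended
  was never stated, so this convention is the package's own.
- **Assembly** — for every inter-protodomain helix pair that is
  mutual-nearest in projection with centroid distance < 12 Å, a code
  `sXY` + `p`/`a` from the sign of the axis dot product.  The C2 operation
  makes contacts come in mirrored pairs (s21/s12); each unordered pair is
  written once, larger label first, codes sorted.

The 12 Å contact cutoff and mutual-nearest rule define "helices in
contact" at Cα resolution; both are config keys.  Codes are only defined
for 3-helix protodomains (4-helix codes are out of scope).

## Synthetic data

The generator is the test bed standing in for deposited structures.  Ideal
helices use textbook α-helix geometry (1.5 Å rise and 100° per residue,
2.3 Å Cα radius).  A domain takes one protodomain of vertical helices at
specified membrane-plane positions (defaults: a triangle beside the
symmetry axis for parallel mode; a triangle above the in-plane axis for
inverted mode), duplicates it by a 180° rotation about the normal
(parallel) or the in-plane x-axis (inverted), optionally inserts a
TM4-like linker helix, numbers helices with loop-sized gaps, and adds
i.i.d. isotropic Gaussian noise (seeded; bit-reproducible).  Oligomers are
rings of 360/n° rotated copies at a 25 Å radius.  The emitted ground truth
(protodomain ranges, axes, topology code, hydrophobic centers) is computed
from the specification by independent 2D arithmetic, not by the analysis
pipeline, so recovery tests are non-circular.

What the generator does *not* emulate: helix tilt and curvature, kinks,
loops with real geometry, side chains, sequence–structure correlation, and
membrane energetics.  Passing recovery tests therefore demonstrate the
correctness and noise tolerance of the detection logic, not performance on
real crystallographic idiosyncrasies (GPCR proline kinks are the known hard
case).  Synthetic MSAs are star topologies: each row mutates an ancestor
independently, per-site substitution probabilities are controllable
(uniform replacement among the other 19 letters), no indels; gap handling
is tested by explicit gap injection.  Recovery conditions used by the test
suite: noise σ ∈ {0, 0.2, 0.4} Å (σ = 0.8 is exercised but outside the
guaranteed band), 25 seeds per condition, ring orders {2, 3, 5}; the
EC/IC-ordering suite uses 10 sequences × 63 columns with EC/IC substitution
rates 0.5/0.1 over 20 seeds; the odds-ratio null uses 500 rows × 50 seeds.
These sizes keep the whole suite under a minute while leaving the Monte
Carlo margins wide.

## Divergence scoring

The similarity percentage is 100 × (sum of pair scores)/(number of
comparisons) over all within-column unordered row pairs, with the piecewise
BLOSUM62 remapping (≥ 4 → 1; 3/2/1/0 → 0.75/0.5/0.25/0.125; negative → 0).
The BLOSUM62 integers are embedded in the source (single, checksummable
source of truth) and unit-tested against Biopython's published copy.
Choices the formula's description leaves open, fixed here: pairs involving a
gap are excluded from numerator *and* denominator (so absolute percentages
can shift slightly against figures produced with other gap conventions);
pairs involving `X` score 0 but count; the hydrophobic-center column belongs
to neither the EC nor the IC half.  Per-sequence TM maps must agree on the
TM index set; column ranges are taken from the first (reference) sequence,
mirroring the consensus-based workflow the statistic comes from.  TM lengths
across the two protodomains are deliberately not equalized.  Protodomain
aggregates are unweighted means of the constituent per-TM percentages.

## Odds ratios

Motif queries are alignment columns plus expected letters (wildcards
allowed); rows with a gap at any queried column are dropped and reported.
OR = n11·n00/(n10·n01); a zero cell with the Haldane–Anscombe option adds
0.5 to every cell, otherwise a zero denominator is reported as +∞.  A Woolf
log-standard-error is available; confidence machinery beyond that, and any
automated scan over column pairs, is out of scope.  Published per-family OR
values depend on specific curated sequence sets that are not distributed
with this package, so they are not regression targets; the statistic is
validated by its exact symmetry/inversion identities and a simulated
independence null.

## Degenerate inputs and tie-breaks

Identity rotations have an undefined axis (flagged, never NaN).  Chains
with < 4 TM segments skip tertiary detection.  Single chains yield
order-1 quaternary results.  All-gap column ranges yield an undefined
(NaN) similarity flagged by `n_comparisons == 0`.  Equal-RMSD split
candidates resolve to the first enumerated (lowest offset); equal-score DP
matchings resolve to the traceback-first path — both deterministic.
Reports serialize with sorted keys and no timestamps, so identical inputs
give byte-identical output.

## Known limitations

- The chirality/arrangement convention reproduces the reference codes on
  schematic geometries but could not be validated against deposited
  coordinates within this repository (they are not redistributed); the
  apex-by-distance rule may be sensitive for nearly-equidistant helices.
- Broken/reentrant helices are treated as single segments; no
  sub-segmentation.
- Manual gap edits used in some published alignments (e.g. the rhodopsin
  TM7 retinal-attachment gap) are not reproduced.
- The hydropathy predictor is a transparent moving-average method, not a
  reimplementation of any published proprietary predictor.
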