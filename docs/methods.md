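# Methods

This note documents the models implemented in `hexablock`, the defaults
and their rationale, the synthetic data the tests run on, and known
limitations.

## Residue encodings

**Physicochemical table.** Twenty standard amino-acid types × six
properties: hydrophobicity (H), side-chain volume (VSC, Å³), polarity
(P1), polarizability (P2), solvent-accessible surface area (SASA) and net
charge index of side chains (NCISC).  Each property column is z-scored
over the 20 types.  The standard deviation is the *population* SD
(divisor 20): the 20 types are the complete population of the alphabet,
not a sample from it.  A `ddof=1` flag switches to the sample convention.
A constant column is an error (zero SD).

**PSSM.** Two routes produce an L×20 position specific scoring matrix:

1. *Constructed*: a per-position frequency profile ω (rows sum to 1) is
   projected through a 20×20 substitution matrix,
   `scores[i, j] = Σ_k ω(i, k)·D(k, j)`.  The packaged D is the PAM250
   log-odds dialect of the Dayhoff family (taken from Biopython's
   substitution-matrix collection and remapped to the internal alphabet
   order A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y); any finite 20×20
   matrix may be substituted.
2. *Parsed*: the standard PSI-BLAST ASCII layout.  The first 20 columns
   (log-odds block) are the default; a flag extracts the percent-frequency
   block (columns 21-40) divided by 100 as a frequency profile instead.
   Columns are remapped from the file's own header order; trailing
   statistics lines are ignored.

Normalisation is min-max over the *whole* matrix (global min and max, not
per column), mapping the extreme entries exactly to 0 and 1.  A constant
matrix cannot be normalised and raises.

Non-standard residue codes map to their nearest standard type (B→N, Z→Q,
U→C, O→K, J→L, X→column means); strict mode rejects them.

## Local feature extractors

Both extractors compute *block means* over a window of profile rows: for
block k with B_k present rows, the feature is the column-wise mean
`(1/B_k) Σ_i M_k(i, j)`.  Six blocks (A-F) per extractor × 20 profile
columns give 120 components each.  An empty block (no present rows)
yields zeros plus an explicit emptiness flag rather than being dropped —
the downstream regression needs fixed-length vectors.  Windows are
clipped at chain termini (no padding); B_k counts only present rows.

**Sequential (MLAB) window** — slots 0..10 for R⁻⁵..R..R⁺⁵.  Default
scheme: A = all 11 slots; bisection B = slots up to and including R
(0-5), C = R onward (5-10), overlapping at the target; trichotomy
D = 0-3, E = 4-7, F = 8-10 (disjoint, covering).  Because the exact slot
membership of the blocks is a design degree of freedom, the scheme is a
first-class object (`BlockScheme`), validated for coverage, and its
fingerprint is serialised with any trained model — loading a model under
a different scheme is an error, never a silent re-map.

**Hexagon window** — slot 0 is the target residue, slots 1-6 its spatial
sector neighbours.  The residue frame places C_α at the origin, C_β on
the +y axis and N in the x-y half-plane with x > 0; azimuth is measured
in the x-z plane from +x toward +z, and sector s covers [60(s−1)°, 60s°),
half-open so boundary directions deterministically fall in the lower
sector.  Within each sector the nearest non-local C_α inside the cutoff
is selected.  Defaults and rationale:

* *cutoff* 10.0 Å — encloses the first structural shell beyond covalent
  neighbours; configurable.
* *non-local* = |Δ seq_index| ≥ 4 within the same chain ("separated by at
  least three residues" read as three strictly intervening residues);
  residues of other chains are always non-local.  Both the separation and
  the cross-chain eligibility are configurable, since the alternative
  readings (|Δ| ≥ 3; same-chain only) are also defensible.
* *glycine / missing C_β*: a virtual C_β is constructed from N, C_α, C
  with the ideal tetrahedral geometry (1.53 Å bond, 110.5° angles,
  L-chirality), keeping every residue frame-capable.  Residues missing
  backbone atoms yield an invalid window that degrades to flagged zero
  features instead of aborting the pose.
* default hexagon scheme: A = all 7 slots; B = {0,1,2,3}, C = {0,4,5,6}
  (half-spaces, each containing the target); D = {1,2}, E = {3,4},
  F = {5,6} (adjacent sector pairs).  The trichotomy deliberately
  excludes the target slot — it is a decomposition of the *neighbourhood*
  — so scheme validation exempts a designated center slot from the
  D∪E∪F coverage requirement.

A deliberate identification property, used in tests: with a constant
profile, both extractors are constant regardless of geometry, so profile
signal and geometry signal are separable.

## CAPRI metrics

Contacts use the strict rule: a residue pair (one residue per subunit) is
in contact iff its minimum inter-atomic distance is *below* 6 Å.
F_nat = |predicted ∩ native| / |native|;
F_non-nat = |predicted \ native| / |predicted|, *undefined* (not 0 or 1)
when the predicted pose has no contacts — undefined values are excluded
from averages.  I_rmsd determines interface residues on the native
complex (6 Å, matching the contact rule; the 10 Å convention used
elsewhere is available via the cutoff argument), collects backbone atoms
(N, C_α, C, O) of those residues from both structures in identical order
(atoms missing on either side are dropped pairwise), superposes them with
a proper-rotation Kabsch fit, and reports the residual RMSD.

The printed quality bands (Incorrect F_nat<10% or I_rmsd>4 Å; Acceptable
10-30% and 2-4 Å; Medium 30-50% and 1-2 Å; High ≥50% and ≤1 Å) are
mutually exclusive on both axes and leave gaps — F_nat 63% with I_rmsd
3 Å fits none.  Default semantics therefore treat the F_nat thresholds as
lower bounds and assign the best class whose I_rmsd upper bound is met,
which makes the classification total and monotone in both arguments and
matches common usage.  A strict-verbatim mode reproduces the printed
bands and returns `Unclassified` in the gaps.

## Pose features and SVR ranking

Per-residue vectors are pooled over the pose's interface residues (both
units) by element-wise mean — permutation-invariant and size-normalised;
sum and max pooling are available for ablations.  A pose with no
contacts pools to the zero vector with an emptiness flag; the flag is
layout metadata, so the sub-vector length stays exactly 120 per
extractor.  MLAB vectors depend only on sequence position and are cached
per complex; hexagon vectors are recomputed per pose for interface
residues only.

Energy terms are plug-ins: `(pose, context, contacts) → fixed-length
vector` with a group id 1-7.  Groups 6 (MLAB) and 7 (hexagon) are the
package's own contribution.  A simplified amino-acid contact-propensity
term (sum of a 20×20 table over contact pairs, plus the contact count)
ships as the reference plug-in for group 1; its default table is a
synthetic hydrophobicity outer product, adequate for exercising the
contract but not a fitted statistical potential.

The SVR uses the radial-basis kernel with C = 1.0, ε = 0.1, kernel width
γ = 1/d (d = feature dimension), and features standardised with training
statistics.  No hyperparameters are tuned: these are the conventional
defaults, serialised with the model together with the block-scheme and
alphabet fingerprints.  Responses are I_rmsd values, so low predictions
play the role of low energies; ranking is ascending with ties broken by
pose id (stable), and the top 10 are selected.  Consensus binding
residues are those on the interface of at least `min_votes` of the
selected poses (default: strict majority).

The ablation harness retrains on feature-group subsets (e.g. contact
term alone, groups {6,7}, all) with a common shuffled train/test split
and reports held-out MAE, Spearman rank correlation and the mean true
I_rmsd of the top-10 selected poses per subset.

## Synthetic data

The generators emulate the *shape* of a docking benchmark, not its
physics:

* Chains are ideal helices (2.3 Å radius, 100° twist, 1.5 Å rise per
  residue → 3.83 Å C_α-C_α distance) or extended strands, with backbone
  + C_β atoms at fixed internal offsets and residue types cycling through
  the alphabet.  Two chains are placed by bisection so the closest
  inter-unit atom distance hits a target (default 4 Å) within 0.01 Å.
* Decoy ladders perturb the ligand unit by an exact-angle rotation about
  a uniformly random axis through its centroid plus an exact-norm
  translation in a uniformly random direction.  The default magnitudes —
  (1°, 0.5 Å), (2°, 1 Å), (5°, 2 Å), (10°, 4 Å), (20°, 8 Å) — were chosen
  so a ladder spans near-native (sub-Å I_rmsd, High) through clearly
  incorrect (> 4 Å) poses.  True CAPRI labels are computed on the fly.
* Profiles are symmetric Dirichlet rows (concentration 1/sharpness,
  default sharpness 2 → moderately peaked positions), pushed through the
  packaged substitution matrix and min-max normalised.

All generators are pure functions of (arguments, seed); per-generator
streams derive from SHA-256 of (seed, generator name, call index), so
adding a generator never shifts another's draws, and derived seeds stay
below 2³¹.

What passing tests on this data do **not** show: performance on real
complexes.  The synthetic chains have no side chains beyond C_β, no
packing, no conformational change on binding, and profiles carry no real
evolutionary signal; ranking-recovery results demonstrate that the
pipeline extracts and exploits the information present in its inputs,
not that the features are competitive on crystallographic benchmarks.

## Problem sizes and numerical choices

The test suite and acceptance script use 30+30-residue complexes, decoy
ladders of 5 magnitudes × 100 decoys for training and 100 replicate
ladders of 25 decoys for selection experiments — large enough for stable
rank statistics on a single CPU while keeping the full run in tens of
seconds.  Superposition rejects < 3 points and collinear point clouds
(rank-deficient within 1e-9 relative); residual RMSD is computed directly
from the aligned coordinates rather than from the solver's reported
residual, which loses precision near exact fits.  Rigid transforms are
validated to be orthonormal and proper within 1e-9.  Contact detection
uses a k-d tree with an explicit strict-inequality distance check, and is
oracle-tested against full pairwise enumeration.

## Known limitations

* Energy items 1-5 of the full published scoring function (statistical
  contact, secondary-structure, structural-neighbourhood, dihedral and
  π-π terms) are represented only by the plug-in contract and the
  simplified propensity reference term.
* No mmCIF parsing, hydrogen handling, symmetry expansion, pose
  enumeration or flexible refinement.
* PSI-BLAST itself is never run; profiles are inputs (parsed files,
  user-supplied frequency matrices, or synthetic).
* The PDB writer emits minimal ATOM/TER records (coordinates at format
  precision, 1e-3 Å round-trip).
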