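# Methods

## Model and scope

The package quantifies, per frame of a conformational ensemble, whether the
aggregation-prone C-terminal hexapeptide of a tau-derived peptide forms an
antiparallel beta hairpin with its N-terminal arm, and in which registry.
Ensemble-level fractions of even- and odd-registry hairpins feed the xHAT
nucleation score `S = f_odd * f_even^2`, motivated by a trimeric
transition-state complex of two even hairpins plus one registry-shifted
monomer.  The pipeline consumes ensembles (multi-model PDB or synthetic
fixtures); it never generates molecular-dynamics samples, and free-energy
calculations are out of scope.

## Hairpin classification

A frame is classified from its backbone hydrogen bonds alone.

**Hydrogen bond.**  Backbone amide N (donor) to backbone carbonyl O
(acceptor), heavy-atom N–O distance ≤ 3.5 Å inclusive, sequence separation
|i−j| ≥ 2.  No angular term by default (an optional N–H⋯O angle filter
exists for sensitivity analysis); adjacent-residue contacts are
covalent-geometry artifacts and excluded.

**Criterion 1 (span).**  At least two hexapeptide-side residues must carry
cross-arm bonds, and the scored hexapeptide (306–310; the mobile termini
295 and 311 are never considered) must lie inside the hairpin span.  The
span is the interval of bonded hexapeptide residues extended by one ladder
position on each side (`span_extension=1`): in an antiparallel ladder the
non-hydrogen-bonded positions flanking a bonded rung are still part of the
strand, and without this extension an odd hairpin bonded at 305/307/309
could never satisfy the criterion even though it is a textbook hairpin.
An alternative any-5-of-6 reading is available (`span_mode="any5"`).

**Criterion 2 (registry and geometry).**  Cross-arm bonds count in either
donor orientation (antiparallel ladders alternate direction).  Registry is
even (odd) when bonded hexapeptide residues are ≥ 2 members of the even
(odd) parity set and none of the other; mixed parity returns `none`
(`min_parity_bonds` and `allow_mixed` are configurable).  Arm partners must
strictly decrease as the hexapeptide index increases; ties or inversions
return `none` — hairpins are antiparallel by definition.  Residue 305 may
carry an odd-registry bond but is not required to.

**Orthogonality.**  The random-coil metric counts hexapeptide residues
with secondary-structure code "C", summed over frames and divided by
6 × (total frame weight).  Frames classified as hairpins contribute zero to
this count regardless of their codes, so no fold is counted as both
hairpin and coil; the pre-zeroing count is retained for diagnostics.

## Secondary structure

A Kabsch–Sander-style assigner: the electrostatic hydrogen-bond energy
`27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with cutoff −0.5
defines n-turns (codes T/G/H/I via consecutive-turn patterns) and
bridges/ladders (B/E).  Amide hydrogens absent from the input are placed
1.0 Å from N opposing the bisector of C(i−1)–N and CA–N (prolines and the
N-terminus get none).  Residues in runs of three or more extended-basin
(φ ∈ [−180°, −45°], ψ ≥ 45° or ψ ≤ −135°; undefined terminal dihedrals do
not disqualify) are additionally labelled "E" without requiring a partner
strand.  This dihedral rule mirrors dihedral-aware assigners such as
STRIDE and is essential to the bookkeeping: a fully extended monomer is
beta, not coil, so it is excluded from the coil fraction and counted by
the hexapeptide beta-content metric (`f_beta_hex`, all six hexapeptide
residues "E").  On hydrogen-bond-patterned geometries (ideal helix, paired
hairpin strands, random coils) the assigner agrees with DSSP as
implemented in mdtraj at the H/E/C level; divergence on borderline
residues of irregular geometries is an acknowledged approximation.

## SASA, RMSD

Shrake–Rupley with a deterministic golden-spiral quadrature (960 points,
no RNG — bit-reproducible), probe 1.4 Å, fixed radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å, hydrogens ignored.  Boundary points count as buried
only against lower-index atoms so exactly coincident spheres expose one
surface.  Superposition RMSD uses the Kabsch SVD solution with the
determinant correction for proper rotations.

## Repeat-domain (k18) statistics

The four-repeat fragment (residues 244–372) carries hexapeptides at
275–280, 306–311, 337–342 and 369–374; the last overruns the chain
terminus and is clipped to 369–372 with a warning.  Local hairpin
probability Hk applies the hairpin classifier to segment k with a region
map mirroring the peptide conventions: bond-eligible window
[start−1, end−1], scored span [start, end−1], parity sets by author-number
parity, and an arm running from the previous hexapeptide (exclusive) to
start−2 — the published 5-residue flank extended upstream, since hairpin
arms can extend beyond the flank box.  Any registry counts as a local
hairpin.  Inter-hexapeptide pairing i–j requires ≥ 2 backbone hydrogen
bonds between the two hexapeptides in a frame (`min_bonds=2`; one bond is
too noise-prone to call a sheet, and the matrix is monotone in this
threshold).  Segment beta totals add the local probability and
caller-selected pairings; totals above 1 are possible when events overlap
within a frame and produce a warning, not an error.  SASA differentials
are weighted ensemble means, sign positive where the first ensemble is
more exposed.

## ThT kinetics

Blank wells are averaged per timepoint and subtracted from every
replicate.  Aggregation curves are fitted with the 4-parameter logistic
`y = baseline + (plateau − baseline)/(1 + exp(−slope (t − T_half)))` —
T_half at the inflection is well defined regardless of the exact sigmoid
family — by least squares with a 3×3 multistart over inflection-time and
slope guesses.  A well is a no-aggregation call (`converged=False`, speed
0) when the fitted amplitude does not exceed 4× the residual standard
deviation; a T_half outside the observed time range is flagged.
Replicates are fitted per well and the median-T_half fit reported
(mean-curve fitting is available behind a flag).  Aggregation speed is
1/T_half in 1/h.  Correlations: Spearman is the headline statistic (the
comparison is between rankings); Pearson, optionally on average ranks, is
also emitted.  Non-aggregators are excluded from correlations by default.

## Synthetic generators

The generators produce *geometric fixtures with exact labels*, not
thermodynamic samples — no force field, no realistic basin weights.  What
passing tests show is that the analysis stages recover constructed truth
exactly (zero noise) and robustly (Gaussian coordinate noise); they say
nothing about force-field accuracy or real conformational distributions.

* **Strand-pair template.**  Antiparallel strands are laid on a flat
  pleated template (CA step 3.65 Å along-strand, pleat ±0.4 Å, strand
  separation 5.83 Å).  Ladder-rung residues point their amide and carbonyl
  at the partner with enlarged lateral offsets so intended cross-strand
  N–O pairs sit at 2.80 Å while every unintended pair stays beyond
  ~4.3 Å.  With i.i.d. coordinate noise σ = 0.2 Å an intended bond is
  essentially never lost in both directions at once and spurious bonds
  are >2.8σ away, which is what makes ≥99% classification recovery at
  that noise level a property of the construction rather than luck.
  Turns and linkers are circular arcs with uniform 3.8 Å CA chords,
  bulging out of the sheet plane; loop carbonyls point outward to keep
  them clear of the bond-eligible strand atoms.
* **Dihedral chains.**  Extended strands use (φ, ψ) = (−120°, 120°)
  (a flat two-fold ribbon, verified free of internal H-bonds); random
  coils draw per-residue dihedrals from sterically allowed coil basins
  (PPII-like capped at runs of two, alpha fringe, left-handed alpha) and
  are rejected on heavy-atom clashes < 2.5 Å, on any backbone H-bond, or
  on a non-coil hexapeptide assignment, making coil frames exact coil
  counters.  Ideal bond lengths/angles (N–CA 1.458, CA–C 1.525, C–N
  1.329 Å); backbone atoms only, since every metric here is
  backbone-driven (SASA on synthetic fixtures is backbone SASA).
* **k18 events.**  Requested local hairpins and pairings become strand
  modules connected by arc linkers; the builder verifies closed-loop that
  the realized hydrogen-bond events equal the request and raises
  otherwise.  Overlapping event footprints are rejected.
* **ThT plates.**  Quadruplicate 4PL wells plus blank wells; Gaussian
  noise scaled to each mutant's amplitude; scans every 30 min over 100 h
  by default; fully seeded.

## Default study conditions

Composition-recovery checks use 2000-frame ensembles at coordinate noise
σ = 0.05 Å (non-degenerate but below the 0.2 Å robustness level, which is
tested separately), recovering each constructed fraction within
3·√(p(1−p)/n).  Classifier robustness uses 300 perturbed copies per
registry at σ = 0.2 Å.  Kinetics recovery uses 100 seeded plates at 2%
amplitude noise, T_half = 40 h on a 0–100 h grid.  The sign-property
library uses 8 synthetic mutants with hairpin content 0.1–0.7 made
monotone with aggregation speed (T_half 80→15 h), 60 frames each.  These
sizes were chosen so the whole suite runs in minutes on one CPU while
keeping binomial error bars well below the effect sizes being checked.

## Numerical choices and edge cases

* H-bond cutoff boundary is inclusive (a 3.50 Å pair is a bond).
* Chains shorter than 3 residues are all-coil.
* Ranking: rank 1 is the largest value; ties get average ranks.
* `xhat_score` rejects inputs off the simplex; its maximum on
  f_even + f_odd = 1 is 4/27 at (2/3, 1/3).
* Ensembles are weight-aware throughout; equal weights reproduce raw
  frame counts, and duplicating frames changes nothing.
* PDB I/O preserves author numbering via a single additive offset
  (internal residues are 1-based contiguous); coordinates round-trip to
  PDB precision (10⁻³ Å).

## Known limitations

* The secondary-structure assigner is not STRIDE; only the H/E/C level is
  validated against an independent DSSP implementation.
* Synthetic conformers carry no side chains beyond the backbone, so
  absolute SASA values on fixtures are not comparable to all-atom SASA;
  differentials and monotonicity properties are.
* The published million-microsecond MD statistics (ensemble hairpin
  fractions per mutant, k18 probabilities from 2000 folding simulations)
  are not recomputable here without the deposited trajectories; the
  pipeline is validated on labelled synthetic ensembles instead, and the
  segment-total arithmetic is checked against the published component
  probabilities directly.
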