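# Methods

## The model

Triterpenoid synthases commit their substrate to one of a few *reaction
channels*: ordered cascades of carbocationic intermediates whose
stereochemistry is fixed early — the fold of the 6,6-bicyclic cation I1 and
the 6,6,6,5-tetracyclic cation I2 — and then transmitted downstream by the
limited rotational freedom of the active-site cavity. The working
assumption of multi-intermediate docking is that the binding site's ability
to stabilize each cation (approximated by an MM/GBSA-style docking score,
kcal/mol, more negative = better) is informative about which cascade runs
and where it stops. The package implements the decision layer over such
scores; it does not compute MM/GBSA itself.

The bundled channel library covers Channel A (hopene; four intermediates,
terminating in the hopanyl cation A-I4), Channel B (lupeol/dammarenyl; the
mandatory I1/I2 with further intermediates loadable from the channel file,
whose composition beyond B-I2 is not settled in the literature we encode),
Channel C (lanosterol/protosteryl; nine intermediates, with lanosterol
indexed under C-I6, parkeol under C-I7, cycloartenol under C-I8,
cucurbitadienol under C-I9), and a sesquarterpenoid (C35) Channel D that is
represented by its two representatives but disabled by default: its
intermediates differ so much in size and shape from the C30 channels that
scores are not comparable, and no reliable structural template exists. A-I1
and B-I1 are chemically identical conformers; the library keys them by
channel and records the shared identity in a `chemical_id` field. Product →
precursor lookups are unique by construction (each product is indexed under
exactly one cation), while endpoint analysis works with precursor *sets*
(lanosterol can arise from C-I6 or C-I7).

## Decision rules and their parameters

**Two-round channel ranking.** Round 1 orders enabled channels by the
rank-1 representative score; channels within `tie_threshold` (default
1.0 kcal/mol — the scale at which two binding energies are
indistinguishable for this kind of scoring) of the best form a tie group,
re-ordered in round 2 by the rank-2 representative. "Better binding
affinity" maps to "more negative score" throughout. Ties surviving round 2
are broken by the better round-1 score, then by the summed representative
scores, then by channel label, and the prediction is flagged `ambiguous`;
if every representative of every channel failed to dock there is no best
channel. This makes the output total and deterministic while preserving an
honesty flag for undecidable inputs.

**Failed dockings.** NO_POSE is a distinct state, not a number. It sorts
strictly worse than any numeric score, never participates in arithmetic,
and maps to +100 or −10 kcal/mol only in plots (two conventions exist in
the field's figures; both are provided, neither is consumed by ranking).

**Endpoint rule.** The putative precursor is the score minimum over
indices ≥ 2 (I1 is excluded: it is near-universally well-bound and carries
no discrimination). `binder_threshold` defaults to 0.0 kcal/mol — any net
unfavorable score counts as a non-binder, the softer alternative to
requiring NO_POSE; both readings are supported through the parameter. The
first non-binder after the precursor terminates the channel and everything
downstream of the termination point is ruled out. The rise check
(some downstream intermediate strictly worse than the precursor) guards
against profiles that improve monotonically to the channel end, which carry
no endpoint signal.

**Mutant classification.** `destabilization_threshold` defaults to
5.0 kcal/mol: comparisons of mutant and wild-type docking scores fluctuate
by a few kcal/mol for chemically silent substitutions, while genuinely
blocked steps shift by tens; 5 is the smallest round value separating the
two regimes in the bundled mutant table. Tables are either absolute or
relative-to-wild-type; the mode is table metadata and mixing modes is an
error. A pose *gained* by a mutant (wild-type NO_POSE, mutant numeric) has
no numeric delta and is reported as `unaffected`.

**Conformer check.** The signed torsion Φ(C16–C17–C18–H18) classifies an
I1 pose as A-like (Φ > 0) or B/C-like (Φ < 0) under the IUPAC convention.
Classification is refused within 1° of 0° or ±180°, where the sign is
inside coordinate noise. Note that the signed torsion is *invariant* under
reversing the four-atom chain; it is mirror reflection that negates it —
the property tests assert exactly this.

**Geometry.** Pose-vs-reference RMSD defaults to in-place heavy-atom RMSD
over a user-supplied correspondence (poses and reference ligand share the
receptor frame after induced-fit docking); Kabsch superposition is
available and is verified against a quaternion eigen-decomposition oracle.
The core restraint passes a pose whose named core atoms are within
1.0 Å in-place RMSD (inclusive boundary) of the reference placement; the
core is an explicit atom-name correspondence rather than a SMARTS pattern,
avoiding a cheminformatics dependency in the core pipeline.

## Toy docking

The toy engine stands in for the induced-fit docking/rescoring stage at
desk scale; it makes no attempt to reproduce real MM/GBSA magnitudes.
Receptors are point-site pockets (position, partial charge, LJ radius, well
depth); the score is a 12-6 Lennard-Jones term (minimum at the sum of
contact radii, geometric-mean well depth) plus Coulomb electrostatics with
the distance-dependent dielectric ε(r) = 4r, so E_coul = 332.0636·q₁q₂/(4r²)
kcal/mol. Pair distances under 0.05 Å are a clash error.

Pose search samples uniform random rigid placements (quaternion rotations;
translations either in a box around the catalytic-anion anchor or, when a
core reference is given, seeded from the core — half the samples perturb
the core-implied orientation, and translations align the core centroid to
the reference before jittering within the tolerance, the toy analogue of
core-restrained initial docking). A placement is *accepted* only if (i) the
cationic head lies within `anchor_max_dist` (default 2.5 Å) of the anchor,
(ii) the core restraint holds, and (iii) the score is at most `max_score`
(default 0.0 kcal/mol: a pose must be net non-repulsive). The energy
criterion is deliberately part of the constraint set: a purely electrostatic
perturbation — flipping the anchor charge to +1, the toy analogue of a
Lys-for-Leu charge-reversal mutation — then abolishes all poses (NO_POSE)
exactly as geometric criteria alone could not. The best survivors are
polished by derivative-free rigid-body minimization (Nelder–Mead over the
6-DOF pose), the analogue of the pose-minimization stage of induced-fit
protocols; results are deterministic given the seed. Receptor flexibility
is not modeled; softening via a reduced `vdw_scale` (e.g. 0.5) emulates it
crudely. No solvation term is included — toy systems are charge-dominated,
and this is a documented gap relative to real MM/GBSA.

## Sequence similarity networks

Pairwise local alignment is exact Smith–Waterman (affine gaps: a gap of
length k costs `gap_open + k·gap_extend`, defaults 11/1; BLOSUM62 with the
X row/column zeroed) via Biopython's pairwise aligner, verified in tests
against an exhaustive enumeration over all monotone position matchings for
short sequences. Raw scores convert to bits with the published ungapped
BLOSUM62 Karlin–Altschul parameters (λ = 0.3176, K = 0.134) and
E = m·n·2^(−bit) with raw sequence lengths and no finite-size correction.
These E-values are internally consistent but *not* numerically
interchangeable with BLAST's (gapped parameters, length corrections), so
E-value cutoffs quoted for BLAST-based networks are treated as qualitative
regimes, not transferable constants. Edges connect pairs with E ≤ cutoff;
relaxing the cutoff never removes edges nor splits components (tested).
Purity statistics exclude unannotated (`unknown`) nodes; global purity is
the labeled-node-weighted mean of per-component majority-label fractions.

## Synthetic data

The generators define the study conditions for all statistical tests.

*Score profiles* (`gen_profiles`): the planted channel's representatives are
drawn `representative_gap` g (default 3 kcal/mol) better than every
competitor's, with i.i.d. Gaussian noise σ (default 1 kcal/mol) on all
numeric scores — the simplest testable error model, since no empirical one
is available. Along the planted channel the profile follows the shape
characteristic of lanosterol-synthase-like enzymes: I1 highly favorable
(−60 kcal/mol anchor), I2 penalized by +15, linear improvement to a minimum
at the precursor index (−10 below the I2 level, default index 6), a
+5/step rise after it, and NO_POSE at the chosen downstream indices
(default {8}). Under these defaults the two-round rule recovers the planted
channel in ≈99% of enzymes (≥95% asserted); at σ = 0 recovery is exact.
Scores are independent across intermediates, enzymes and channels — real
docking errors are correlated along a cascade, so these rates bound the
method's behavior under the stated noise model only, not on real enzymes.

*Sequence families* (`gen_sequences`): uniform point substitutions, no
indels, so percent identity is targeted exactly in expectation. Members
mutate a fraction m of positions solving (1−m)² + m²/19 = within-identity;
family ancestors retain a fraction k of a master sequence solving
k² + (1−k²)/20 = between-identity (the 1/20 term is the random-match
floor). Defaults 90%/25% give families that separate cleanly at a
within-family E-value cutoff. Real protein families have indels, rate
heterogeneity and composition bias; these fixtures test graph mechanics and
threshold behavior, not biological realism.

*Toy complexes* (`gen_toy_complex`): a four-bead cationic ligand with graded
charges (+0.7/+0.25/+0.1/−0.05 — the gradation breaks orientational
symmetry), an anchor anion ~2.2 Å from the head bead, two
orientation-selective charged contacts, and ~11 neutral contact sites at
near-optimal LJ distances. The planted pose is defined as the best
constrained pose found by a thorough seeded search around the constructed
geometry (so "recovery" means re-finding the constrained global optimum,
not an arbitrary construction), and the complex's constraints take that
pose as core reference.

All generators are bit-reproducible given their seed.

## Problem sizes

The statistical checks run at: 10,000 random score tables for the
ranking-oracle comparison; 1,000 enzymes for noisy planted-channel
recovery and 200 for the noiseless case; 1,000 random quadruples for the
dihedral dual-formula bound (10⁻⁹ degrees); exhaustive local-alignment
enumeration for all pairs up to length 4 over a two-letter alphabet plus
100 seeded pairs up to length 8 over a five-letter alphabet (the
enumeration oracle is O(C(16,8)) per pair, which sets the practical length
bound); 2,000 docking samples per toy complex; and 4-family × 4-member
sequence sets at length 200 for the network checks.

## Known limitations

* The decision layer is only as good as its input scores; with real docking
  scores the published experience is qualitative agreement, not
  quantitative product distributions, and this package inherits that.
* Branch points off the main chain are not ranked (by design); promiscuity
  beyond "several plausible precursors" is out of scope.
* The per-enzyme docking-score tables of the published 54-enzyme
  homology-model benchmark are distributed only as binary supplementary
  material; the corresponding success-rate reproduction is therefore not
  runnable from bundled data (the test encoding it fails with an
  explanatory message rather than being skipped).
* The toy docking engine shares the *structure* of induced-fit docking
  (constraints, core restraint, minimization) but none of its physics
  beyond LJ + screened Coulomb; absolute scores are meaningless outside the
  toy system.
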