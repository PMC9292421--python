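# Methods

This note records the models, conventions and parameter choices behind
`camqa`, the reasoning where the design was genuinely open, and what the
synthetic test bed does and does not establish about real data.

## Contact areas

The geometric substrate is the additively weighted Voronoi (power) diagram
of the probe-expanded atoms.  The contact area between atoms *i* and *j* is
the area of the power-cell face they share, clipped to the intersection of
the two expanded spheres; the solvent area of an atom is the part of its
expanded sphere inside its own power cell.  Exact constrained tessellations
are intricate; `camqa` instead uses a convergent sampling estimator with a
documented tolerance:

* **Contact faces.**  The face between *i* and *j* lies in their radical
  plane.  The candidate region is the disc in which the plane intersects
  both expanded spheres (radius `ρ`, `ρ² = R_i² − h²` with `h` the distance
  from center *i* to the plane).  The disc is covered with a deterministic
  sunflower (golden-angle) lattice; a sample point survives if its power
  distance to the pair is no larger than its power distance to every third
  atom.  The area estimate is `πρ² ×` (surviving fraction).  For two
  isolated spheres this is exact for any lattice size — the two-ball bridge
  `π(r² − d²/4)` is reproduced to machine precision — and by symmetry of
  the construction `A_ij = A_ji` holds identically.
* **Solvent areas.**  Each expanded sphere is covered with a Fibonacci
  lattice (seed-rotated); a point is solvent-accessible when it lies inside
  no other expanded sphere, which on the sphere boundary is exactly the
  power-cell condition.  Estimate: `4πR² ×` (exposed fraction).
* Atom pairs enter only if their centers are within
  `r_i + r_j + 2·probe` (the exact support of the construction).  Contacts
  between sequence-adjacent residues are kept; no bonded-pair exclusion is
  applied.
* Defaults: probe 1.4 Å (water probe convention), `n_samples` 1024 for
  interactive use.  The test suite and experiments use 96–128 samples per
  disc/sphere, which keeps every fixture area within a few percent of its
  converged value; convergence and rigid-motion invariance are asserted in
  the suite at 5% tolerance.
* Because the per-pair faces and the spherical solvent patches are the
  boundary of the convex body (power cell ∩ expanded ball), the per-atom
  total of contact plus solvent area can never exceed the expanded-sphere
  area — a useful sanity invariant that the suite checks.

The `seed` only rotates/phases the lattices; identical inputs give
bit-identical outputs.

## CAD-score family

For residue-level contact maps `T` (target) and `M` (model),

```
CAD = 1 − min(1, Σ_{(i,j)∈G} |T_ij − M_ij| / Σ_G T_ij),   G = {pairs with T_ij > 0}.
```

The score is target-referenced: model-only contacts are ignored, so an
identical model scores exactly 1 and a contact-free model exactly 0, and
scaling both maps by a common factor changes nothing.  The local variant
restricts the sum to pairs containing one residue; the interface variant
restricts to inter-chain pairs; the binding-site variant compares each
residue's *total* inter-chain area with partner identity ignored.  The
binding-site definition is this package's convention (the variant is used
in the field but rarely written out); it is designed so that a subunit
spun in place — same patch, different cross-pairs — keeps a high
binding-site score while the interface score collapses, and the suite
asserts exactly that behavior on a constructed fixture.

Model/target residue correspondence is by author numbering within mapped
chains — never by sequence alignment.  For homomers, all chain
permutations within equal-length classes (at most 8 per class) are
enumerated and the mapping with the best interface CAD wins, ties broken
lexicographically.  Interface CAD was chosen as the matching objective
because the package's emphasis throughout is interface accuracy.

## Interface metrics and accuracy categories

ICS is the F1-score over sets of cross-chain residue pairs, a pair being in
contact when any heavy-atom distance is strictly below 5.0 Å (the CASP
assessment convention).  IPS is the Jaccard coefficient of interface
residue sets.  Externally supplied QS-scores map onto accuracy categories
with the standard thresholds: high ≥ 0.7, medium in [0.3, 0.7), low in
[0.1, 0.3), incorrect below 0.1.  The QS weighting formula itself is not
re-implemented; only the category mapping operates here.

## Contact potential

Observed contact area `O(a,b)` is accumulated over reference structures by
coarse atom class — backbone N/C/O, CA, CB, side-chain C/N/O, S, plus a
solvent pseudo-type (nine classes instead of a fine-grained vocabulary:
coarse classes stay statistically estimable from fixture-scale reference
sets).  The null model is quasi-independence — `E(a,b) = u_a u_b (2−δ_ab)`
with weights fitted to the observed endpoint margins by iterative
proportional scaling, the solvent–solvent cell being structurally absent —
and the potential is

```
e(a,b) = −ln[(O(a,b) + pc) / (E(a,b) + pc)] − c,
```

with pseudocount `pc` = 1 Å² and `c` chosen so the observed-area-weighted
mean energy is zero.  The centering makes the reference set itself score
neutrally (the reference-state convention) and makes the self-consistency
property — re-scoring the references gives mean per-atom energy ≈ 0 — hold
exactly rather than approximately.  Under this construction a reference
world whose contacts mix independently gives identically zero energies,
which the suite verifies on an analytic table.

The pseudo-energy of a structure is `Σ area × e` over its contacts plus
solvent terms, each contact split half/half between its two atoms; the
interface pseudo-energy keeps cross-chain atomic contacts only (lower =
more favorable).  The bounded "light" global score is
`1/(1 + exp(k·ē))` with `ē` the mean per-atom energy density and `k` = 1 —
a calibration of this package, monotone in the energy; its absolute values
are not comparable to any published score.

## Learned per-residue quality (dark score)

A feed-forward network (one tanh hidden layer of 20 units, sigmoid output)
maps 18 per-residue features — contact/solvent areas, same- vs cross-chain
split, per-class area sums, residue pseudo-energy and energy density,
area-weighted neighbor energy, burial fraction, and side-chain solvent
exposure — to the residue's local CAD-score.  Inputs are standardized with
stored training statistics; training is full-batch Adam (rate 0.02, 1000
iterations by default) on squared error, bit-deterministic given the seed.
The global dark score is the arithmetic mean of the per-residue
predictions, exactly — the suite asserts equality to machine precision.

The side-chain solvation feature deserves a note: in the fixture world (and
in real proteins) the tell-tale of a broken interface is hydrophobic
side-chain area that has fallen out of contact into solvent.  Without this
feature a residue that lost its interface is indistinguishable from one
that never had any, and ladder recovery degrades.

Default training data: rigid-body decoy sets (12 decoys each) of four
amphipathic dimer targets of lengths 14–22, labels from local CAD against
each target.  Evaluation uses a graded decoy ladder — perturbation bounds
ramping linearly from zero to interface-breaking — of a fifth, disjoint
target; the package's recovery experiment reports the Spearman correlation
between the global dark score and the ground-truth interface CAD.

## Ranking and selection

Pairwise comparison: if two global (dark) scores differ by more than the
tolerance (default 0.02), the higher global wins; otherwise the lower
interface pseudo-energy wins; exact ties fall back to global, then model
id.  A full round-robin aggregated by win counts (Copeland ranking) is
deterministic and independent of input order; round-robin was chosen over
bracket schemes for exactly that reason.  In the limits the ranking
degenerates to a plain global-score sort (tolerance 0) or a plain
interface-energy sort (tolerance larger than the score spread), both
asserted in the suite.

Diverse selection clusters models greedily in rank order: a model joins the
first cluster whose leader it resembles at or above the interface-CAD
threshold (default 0.65), else founds one; the first k leaders are
selected.  Leader-linkage was chosen as the cheapest scheme that delivers
a diverse set; the threshold and k (default 5) are configuration.

## Coaxial two-ring docking

The ring axis is the gyration-tensor eigenvector with the smallest
eigenvalue — well-posed for flat rings; a spectrum with
`λ_min > 0.5 λ_mid` is rejected as ambiguous.  Both rings are aligned on
z; ring B starts at the largest axial offset with any cross-ring atom pair
within contact range (evaluated at rotation 0) and moves inward in 1 Å
steps while at least one rotation at the offset passes the clash rule;
rotations cover `[0, 360°/n)` of ring B's cyclic order n in 2° steps.  The
clash rule — at most 0.1% of cross-ring atom pairs closer than 0.6 × the
radius sum — is this package's feasibility gate standing where a physical
relaxation step would otherwise be.  Surviving poses are ranked by
cross-ring interface pseudo-energy; contact-free poses score 0 and rank
last.  Only the two stated degrees of freedom (axial push, axial spin) are
scanned; tilt and lateral offset are out of scope.

## Synthetic fixtures

Fixtures are idealized helices: rise 1.5 Å/residue, twist 100°/residue,
backbone N/CA/C/O plus CB, with a small seeded coordinate jitter
(σ = 0.05 Å).  With an oriented hydrophobic face, residues whose side
chain points within 60° of the face are leucines (CG, CD1, CD2), residues
pointing away are serines (OG), the rest alanines.  This amphipathic
pattern is the essential modeling choice of the test bed: contact
potentials detect compositional clustering (the hydrophobic effect), and a
poly-alanine world has none — its interfaces cannot be distinguished from
its surfaces by any observed-vs-expected statistic.  With the pattern, the
native dimer interface buries leucine side chains and scores a clearly
negative interface pseudo-energy, while decoys that lose or misplace the
interface score near zero or positive.

Dimers place two such helices with facing hydrophobic sides at 11.5 Å
axis separation.  Rings place subunits tangentially in the xy-plane (flat,
so the gyration axis is the symmetry axis).  The two-ring complex stacks a
ring and its z-mirror image at 11 Å — mirror symmetry makes the stacking
faces exactly complementary, giving the assembly a sharp packing optimum
at rotation 0, the property a recoverable docking target needs.  Decoys
perturb one chain rigidly (uniform magnitudes up to the bounds, uniform
random axis/direction) plus optional i.i.d. coordinate noise, and carry
ground-truth interface CAD computed with the same estimator settings.

What the fixtures do *not* emulate: real side-chain rotamers and packing
detail, backbone flexibility, electrostatics and hydrogen-bonding
chemistry, sequence diversity beyond the three-letter LEU/ALA/SER
alphabet, and experimental-structure artifacts.  Passing the recovery
experiments therefore demonstrates that the machinery — estimator, scores,
potential derivation, learning, ranking, enumeration — is internally
consistent and recovers planted signal at desk scale; it does not
establish accuracy on real protein complexes, and none of the published
numerical score values of any real-world method are reproduction targets.

## Experiment sizes and numerical choices

The recovery experiments run at deliberately small scale: 128 lattice
samples per disc/sphere (96 for pose scoring), dimer targets of 14–22
residues per chain, decoy sets of 8–16, rings of 8 × 12 residues, 50
enrichment trials.  These sizes keep each experiment in the
seconds-to-minutes range while leaving all asserted effects far from their
decision boundaries.  Tie-breaks are everywhere lexicographic and
documented; degenerate inputs (monomers where an interface is required,
targets with no contacts, isotropic blobs in ring-axis detection) raise
typed errors rather than returning sentinel values, except interface
energy of a monomer, which is 0 with a warning because a batch pipeline
must keep going.

## Known limitations

* The estimator is Monte-Carlo-grade at small `n_samples`; areas carry a
  few percent noise and downstream scores inherit it.  All documented
  tolerances account for this.
* The binding-site CAD variant is a local convention; other software may
  define it differently.
* Chain matching enumerates permutations; more than 8 interchangeable
  chains is a hard error rather than a heuristic search.
* The dark model is trained per-package on fixture ladders; its weights
  are not transferable to real structures.
* The two-ring enumerator assumes both inputs are individually flat rings;
  it does not handle tilted or laterally shifted assemblies.
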