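# Methods

## Model

The package implements a family of coarse-grained elastic network models
built on one node per residue, placed at the C-alpha position, with unit
masses and no mass weighting.  Normal modes are the eigenpairs of the
analytic Hessian of a potential expanded around the input (native)
geometry; the six smallest-eigenvalue modes of any 3D model are rigid-body
motions and are identified by count, never by thresholding.

The Go-like four-term potential used by the STeM-family models is, for a
conformation `X` with native reference `X0`:

```
V = sum_bonds     a1 (r - r0)^2
  + sum_angles    a2 (theta - theta0)^2
  + sum_dihedrals a3 [(1 - cos(phi - phi0)) + 1/2 (1 - cos 3(phi - phi0))]
  + sum_{|i-j|>=2} k_ij [5 (r0/r)^12 - 6 (r0/r)^10 + 1]
```

Bonds are virtual C-alpha pseudo-bonds between consecutive residues of a
chain; angles and dihedrals follow the chain likewise.  The non-bonded
5-12/6-10 well is anchored at each pair's native distance, so the reference
geometry is an exact minimum and `V(X0) = 0`; its curvature at the minimum
is `120 k_ij / r0^2`, giving every residue pair an effective spring that
decays with native distance.  The long-range pair list is all residue pairs
separated by at least two positions in sequence.

The models differ only in `k_ij`:

* **STeM**: `k_ij = a4` (geometry only).
* **ENCoM**: `k_ij = a4 (1 + beta_ij)` where `beta_ij` sums, over all
  heavy-atom pairs (a in residue i, b in residue j), the surface area in
  contact between the two atoms weighted by an 8x8 atom-type interaction
  matrix.  The `1 +` baseline keeps the STeM-like distance-decaying spring
  for non-contacting pairs (so remote pairs get a weak, closer pairs a
  slightly stronger baseline) while residue pairs with real side-chain
  interfaces are stiffened in proportion to the weighted interface area.
* **ENCoM_ns**: ENCoM with every interaction weight set to 1; `beta` is
  then the plain contact area, sensitive to side-chain orientation but
  blind to chemistry.
* **ANM**: Hookean springs of equal strength between all C-alpha pairs
  within an 18 A cutoff.
* **GNM**: the isotropic N x N Kirchhoff variant (10 A contact cutoff by
  default); magnitudes only, one rigid mode.

Because every term contributes `c * g g^T` with `c >= 0` and `g` the exact
gradient of an internal coordinate, the Hessian is positive semidefinite by
construction and carries the six rigid-body vectors in its null space to
machine precision.  Multiplying all four weights by a constant multiplies
every eigenvalue by that constant and changes no eigenvector; b-factor
correlations, overlaps and entropy ratios are therefore invariant under a
common rescaling, and only the ratios of the `a` weights matter.

## Surfaces in contact

Each atom's sphere is inflated by a solvent probe (1.4 A, configurable);
two atoms are in contact when their inflated spheres intersect.  Every
point of an atom's inflated surface covered by at least one neighbour is
assigned to the neighbour with the smallest power distance (the
radical-plane / power-diagram criterion), and the directed contact area of
a neighbour is the area of its cell; the symmetric surface in contact is
the sum of the two directed areas.  Cell areas are computed exactly by
Gauss-Bonnet over the boundary arcs of spherical-cap intersections; a
region's component count is recovered from the fact that candidate areas
differ by multiples of the full sphere.  A uniform sphere-sampling
estimator of the same partition (Fibonacci lattice under a seeded random
rotation) ships alongside as oracle and fallback; the two routes agree to
about 1% on protein-like geometry and to much better than 5% on arbitrary
two- and three-sphere configurations.

Atomic radii are a fixed per-element table (C 1.70, N 1.55, O 1.52,
S 1.80 A).  All heavy atoms of both residues enter the beta sum by default
(side-chain-only aggregation is available for sensitivity analyses).

## Atom types and the interaction matrix

Heavy atoms are classified into eight classes in the Sobolev style:
hydrophilic (donor+acceptor oxygens/nitrogens such as Ser OG or His ring
nitrogens), acceptor, donor, hydrophobic carbon, aromatic carbon, neutral
carbon (bonded to a polar atom), and weakly polar neutral-donor /
neutral-acceptor (thiol and thioether sulfur, proline backbone N).  The
(residue, atom) table is rule-built and bundled; unknown pairs are flagged
and treated as neutral.

The 8x8 interaction matrix shipped as default is a **reconstruction**, not
a fitted quantity: complementary hydrogen-bonding classes get weight 3,
apolar packing 2, weak-polar pairings 1.5-2, mismatched pairings (like
charges, polar against hydrophobic) 0.5, everything else 1.  Both the
matrix and the typing table are plain TSV/config-overridable; the all-ones
matrix defines the non-specific variant.

## Force-constant defaults

The four weights default to `(1e3, 1e4, 1e4, 1e-2)`.  This is a
**reconstruction** of the overlap/mutation-optimal regime -- strong bond
and angle constraints, non-bonded weight well below 1 -- chosen once and
labelled as such; it is not a fitted optimum.  The slot for a
b-factor-optimal set is filled analogously with `(1, 1, 1, 10)` (non-bonded
weight above 1 rigidifies the network, which favours crystallographic
b-factor agreement and penalizes overlap).  STeM uses the classic Go-model
weights `(100, 20, 1, 1)`.  ANM/GNM use the bond weight as their uniform
spring constant.  All are overridable per run.

## Observables

* **b-factors**: `b_i = sum over internal modes of |v_n,i|^2 / lambda_n`
  (3x3 block traces of the Hessian pseudoinverse); GNM uses the Kirchhoff
  pseudoinverse diagonal.  Shape only -- the scale is arbitrary.
* **Overlap**: the target conformation is first rigidly superposed onto the
  start over the residues shared by the two structures (matched by chain,
  residue number and insertion code; the network is expected to be rebuilt
  on the common subset when they differ, which the command-line layer does
  automatically).  Then `O_n = |v_n . dr| / (|v_n||dr|)` per internal mode,
  and the best overlap is the maximum over the 10 slowest internal modes.
  Superposing first matters: overlap is meant to measure internal motion
  only.
* **Vibrational entropy / ddG**: in the classical harmonic limit each
  internal mode contributes `-1/2 ln lambda` plus constants that cancel
  between two same-size structures, so
  `dS = 1/2 sum ln(lambda_a / lambda_b)` over paired sorted internal
  modes, reported in units of k_B (no absolute calibration is attempted;
  the through-origin regression slope absorbs scale and units).  The
  mutation score is `-dS(wt -> mutant)`: a stiffened mutant loses
  folded-state entropy, is destabilized, and scores positive.
* **delta-B profiles**: per-structure z-scored predicted b-factors,
  differenced and sign-inverted so rigidity gain in the mutant is positive,
  tracking NMR order-parameter (S^2) differences.  The z-score + sign-flip
  convention is this package's documented interpretation of "inverse
  normalized".  Note that when the two profiles have very different
  variances the z-scoring distorts relative amplitudes; for the small toy
  networks here a genuinely local perturbation also delocalizes across the
  structure, so localization claims are tested on constructed spectra, not
  on the toy networks.

## Evaluation machinery

Regression between predicted and experimental ddG is through the origin
(`k = sum xy / sum x^2`): a protein compared to itself must predict zero,
which an intercept would violate.  RMSE is the RMS residual of that fit.
Mutations classify as stabilizing (ddG < -0.5 kcal/mol), neutral (closed
interval [-0.5, 0.5]) or destabilizing (> 0.5).  Bootstrap resampling
(10000 replicates by default, seeded, bit-reproducible) supplies spreads
for every statistic; resamples that draw only zero predictions fall back
to the slope-zero limit of the through-origin RMSE.

Self-consistency of forward/back mutation predictions is measured against
the line y = -x: with per-pair deviation `d = fwd + rev`, the bias is
`mean(d)/sqrt(2)` (signed distance from the line) and the error
`sqrt(mean(d^2))/sqrt(2)` (RMS distance).  This diagnostic is usually
described geometrically; the sqrt(2)-normalized formulas are the package's
documented choice, and error >= |bias| always.

Two-predictor combination rescales each model's predictions through the
origin onto the experimental scale, fits a two-coefficient zero-intercept
model by SVD least squares per bootstrap sample, and reports the RMSE
difference against a random model (a seeded permutation of the
experimental values used as predictions) plus the coefficient ratio.  The
combined fit contains each rescaled single model as a special case, so on
the training sample it is never worse than the better single model.

The parameter search enumerates integer log10 exponents for the four
weights.  Stage one Z-scores (across the grid population) the
bootstrapped-median through-origin RMSE on the stabilizing and
destabilizing subsets and keeps the best fraction (default half;
the staging fraction is exposed because the two stages' population sizes
are a tunable of the procedure); stage two Z-scores mean best overlap on
domain-type and loop-type tasks within the surviving population and ranks
by overlap Z minus RMSE Z.  All bootstrap draws reuse one seed so that
parameter sets differing only by a common scale factor produce
bit-identical metrics, as the scale invariance demands.

## Synthetic data

The fixture generator covers three geometries: collinear bead chains
(3.8 A spacing), ideal alpha-helices (rise 1.5 A, twist 100 degrees,
radius 2.28 A, reproducing the 3.8 A virtual bond), and a two-domain hinge
(two helical halves bent 50 degrees at the junction).  Side chains are
single pseudo-CB spheres at 1.53 A radial offset, keeping contact areas
near closed-form two-sphere values.

Toy mutations alter one side-chain sphere: radius scaling and/or type
relabel in memory, or residue renaming (e.g. ALA to SER) when the pair
must survive a PDB round trip, since radii and types are rederived from
element and residue name on reading.  Conformer pairs displace along the
slowest internal mode (best overlap 1 by construction), bend the hinge, or
apply a seeded random displacement.

The generative mutation benchmark injects experimental ddG values as
`slope_true * dds + N(0, sigma)` with `dds` the entropic score under the
true parameter set, default noise sigma 0.1 kcal/mol.  The slope is chosen
so the noiseless values have a 1.5 kcal/mol spread -- entropic scores live
in small model units and the regression absorbs scale exactly as with real
data -- which spreads cases across all three stability classes; mutation
direction alternates (small-to-big and big-to-small side chains) because
contact loss saturates and pure shrinking cannot produce strongly
stabilizing cases.  With zero noise the through-origin slope recovers the
injected constant to machine precision and RMSE vanishes, which is the
package's end-to-end consistency check.

What the toys do not emulate: real side-chain chemistry and rotamers,
crystal packing, solvent, missing residues/disorder in real PDB files, and
mutant side-chain repacking (mutant structures are consumed as pre-built
models with near-identical backbones).  Passing tests therefore establish
internal correctness of the potential, spectra, observables and
statistics -- not prediction accuracy on experimental benchmarks, which
requires external structure sets and mutation databases.

## Numerical choices and edge cases

* Full dense symmetric eigendecomposition (`scipy.linalg.eigh`); problem
  sizes are a few hundred residues at most, so no sparse solvers.
* Degenerate internal coordinates (collinear angle/dihedral geometry) are
  skipped with a warning; on a perfectly collinear chain the bond terms
  alone reproduce the classic triatomic spring eigenvalues.
* Eigenvalues below `-1e-8 * lambda_max` raise; rigid modes are counted,
  not thresholded.
* Contact geometry tolerances: coincident atoms (distance < 1e-6 A) are an
  error; cap-intersection bookkeeping uses 1e-7..1e-9 tolerances on
  cosines and vertex matching.
* Altloc policy: highest occupancy wins; NMR files default to model 1; MSE
  maps to MET; other non-standard residues are dropped with a warning.
  These are documented package choices -- benchmark-set curation rules are
  not published for the reference workflow.
* Benchmark runs accept an explicit exclusion-list file (one mutation or
  pair id per line) instead of hard-coding dropped cases.

## Known limitations

* The interaction matrix and default force-constant weights are labelled
  reconstructions (see above); absolute entropic scores are in model units
  and only meaningful through the regression slope.
* The analytic surface engine assumes spheres in generic position;
  pathological tangencies fall back to slightly perturbed bookkeeping and
  the numeric sampler is always available as the oracle.
* Overlap against a target with a different residue inventory requires
  rebuilding the network on the common subset; the library-level `overlap`
  refuses silently mismatched decompositions rather than guessing.
* Problem sizes in the test-suite and the acceptance script are toy scale
  (5-30 residues, 10-20 mutations, grids up to 3^4), chosen so the whole
  verification pipeline stays lightweight while every code path is
  exercised at full depth.
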