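# Methods

This note records the models and numerical choices behind `confenum`, the
assumptions they rest on, and what the synthetic tests do and do not show.

## Torsion boxes from likelihood maps

A per-residue likelihood grid over the 324 Ramachandran voxels (18 x 18 of
20 deg x 20 deg; voxel (0,0) starts at (-180, -180), centers at
-170 + 20k) is normalized to sum to one; voxels with probability strictly
above a threshold (default 0.01) are selected.  Boxes are the axis-aligned
bounding rectangles of the 8-connected components of the selected voxels,
with both angles treated periodically across +-180 (a component hugging
the map edge yields bounds exceeding +180 on the upper side; the
enumerator interprets torsions modulo 360).  Manual box tables in the same
text format are accepted unchanged, and a residue with no usable map can
copy a neighbor's boxes via an explicit `copy_boxes` directive — never
silently.  Auto-extracted boxes never extend beyond the component's
bounding rectangle; practitioners who prefer looser manual boxes can
supply them by file.

## Geometry and parameters

Bond lengths, bond angles, improper targets and van-der-Waals radii are a
small table of standard protein heavy-atom geometry (Engh–Huber-type
values), fully overridable through a plain-text parameter file.  The
algorithm, not the constants, is the point; any internally consistent
parameter set works.  Defaults: N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å,
C-O 1.231 Å, CA-CB 1.530 Å; radii C 1.70, N 1.55, O 1.52 Å.  Two impropers
are defined per residue — CA chirality (dihedral CB-N-CA-C, target
measured once on an ideally built L-residue, about -122.6 deg) and
carbonyl planarity (dihedral O-CA-C-N(i+1), target 180 deg) — with a
configurable tolerance of 5 deg.  The peptide omega torsion is fixed trans
(180 deg); cis-proline is not modeled.  Nonbonded pairs separated by two
bonds or fewer are excluded from clash checks.

The phi/psi <-> distance equivalence is computed in closed form:
d^2 is affine in cos(tau), implemented in the half-angle form
d^2 = d(0)^2 + (d(180)^2 - d(0)^2) sin^2(tau/2) so that the inverse
round-trips exactly at the interval ends (the round-trip error is below
1e-9 deg on a 0.25-deg grid; inverting through a distance cannot resolve
sub-millidegree angles near 0, where d'(tau) -> 0).

## Branch-and-prune enumeration

Each fragment carries one dummy alanine per terminus so that the first
inner residue has a phi and the last a psi; dummy torsions are fixed at
180 deg.  The dummies take part in building and pruning and are stripped
from saved coordinates.  The build order per residue is N, CA, C with
carbonyl O and CB placed constructively (exact internal coordinates: O in
the sp2 plane, CB by the tetrahedral two-angle solve with the L branch);
hydrogens are not built.  Interval-torsion atoms (N via the preceding
psi, C via phi) are placed by trilateration: the torsion box maps to a
|tau| range, hence a distance interval, which is widened by the 0.05 Å
tolerance and discretized into at most 4 samples no finer than 0.1 Å
(midpoints of equal sub-intervals).  Each sampled distance yields up to
two mirror candidates (+tau / -tau); a candidate is kept only if its
realized dihedral lies in the box (with the angular slack implied by the
distance tolerance at the interval edges).  Branch order is ascending in
distance, positive dihedral first — a determinism convention only.

A completed leaf is compared to the *most recently saved* conformation
(best-fit CA RMSD) and saved only if it differs by more than the gate
(default 2 Å); a `gate_mode="all"` variant compares against all saved
conformations.  Traversal stops at the save cap (default 10^9) and the
result's completeness flag records whether the cap ever bound.

The enumerator is verified against an independent oracle that builds every
sampled torsion combination directly in Cartesian space (chain extension,
no trilateration) and applies the same pruning and gating: on fragments of
up to three residues the two saved sets are bijective to 1e-6 Å.

## SOM clustering

The covariance encoding treats the rows of the CA-CA distance matrix as
observations: C[i,j] = (1/n) sum_k (d[i,k]-dbar_i)(d[j,k]-dbar_j).  Its
four largest eigenvalues and eigenvectors form the input vector of length
4(n+1); eigenvector signs are fixed by forcing the largest-magnitude
component positive.  The encoding is exactly invariant under rigid motion
and blind to chirality (distances only).  Eigenvectors of nearly
degenerate eigenvalues are numerically unstable — irrelevant for
clustering (such directions carry little variance) but worth knowing when
comparing encodings bitwise.

The Kohonen map is toroidal; neurons are initialized uniformly over the
per-coordinate input range; one step updates the best-matching unit and
its Gaussian neighborhood; the learning rate decays linearly (0.5 -> 0.05)
and the radius exponentially (max(rows, cols)/2 -> 1) over the schedule.
Library defaults are 100 x 100 and 2 epochs; the desk-scale tests use
20 x 20, 5 epochs, final radius 0.7, which reliably forms one U-matrix
basin per planted cluster at 100 members per cluster.  Representative
extraction takes, for each *occupied* strict local minimum of the U-matrix
(toroidal 8-neighborhood; <= all neighbors and < at least one), the first
conformation assigned to it, falling back to the global minimum among
occupied neurons when no occupied minimum exists.  With sparse occupancy
(few inputs on a large map) basin minima can fall on unoccupied neurons
and a cluster can go unrepresented; across random seeds the planted-
cluster recovery rate at the test condition is 90–100%.  Reduction
triggers only when a set is strictly larger than the threshold (default
1000).

## Assembly and domain attachment

Fragment merging superposes the backbone atoms (N, CA, C, O where present)
of the three shared residues, switches chains at the overlap atom whose
two copies are closest (ties toward the earlier atom in build order), and
rejects merged chains with any non-bonded CA pair (residues not adjacent
in sequence) closer than 1 Å.  Step counters obey
N_saved = N_trials - N_clashes with N_trials the all-vs-all product; the
merged set then passes through the clustering gate.

Domain attachment searches a lattice (default spacing 2 Å) spanning the
linker CA bounding box padded by the domain's radius of gyration,
keeping points strictly closer than R_g to the downstream anchor CA and
strictly farther than 2 Å from every linker CA.  At each point the domain
is rotated by the minimal rotation aligning its anchor-to-anchor CA
vector with the linker's — this leaves a free spin about the aligned
axis, sampled at a configurable count (default 8) — then translated by
the mean anchor displacement.  A pose is accepted when fewer than 3 cross
CA pairs are under 1 Å and the mean of the two anchor CA-CA distances is
under 6 Å; all accepted poses are kept.  The second domain rides a
reference complex superposed over a stated backbone range and is
translated by the bridge-residue CA displacement; fewer than 50 atom
clashes (all atoms, strict) accepts.  The downstream molecular-dynamics
relaxation and energy filtering of full-scale studies are out of scope;
an optional steric-only filter stands where they would run, and knotted
models are not detected.

## Observable models and population fitting

The scattering predictor is the plain Debye sum over CA atoms with unit
form factors, I(q) = sum_ij sinc(q r_ij) (q in nm^-1): rotation-invariant,
I(0) = n^2, and deliberately coarse — no solvation layer, no real form
factors — adequate for synthetic benchmarks and relative-shape questions,
not for absolute comparison with measured curves.  The PRE model is the
single-constant ratio exp(-c / r^6) from the probe-site CB (CA when
absent) to each amide N, c = 1e8 Å^6 putting the midpoint near 23 Å: a
declared stand-in for a relaxation-matrix back-calculation, used for
synthetic profiles and qualitative comparison.  RDC prediction is not
reimplemented; precomputed per-conformer RDC tables are averaged and
scored.  The Q factor is rms(calc - obs)/rms(obs), the common NMR
normalization.

Population inference minimizes chi^2/2 - theta*S over the simplex with
S = -sum_i w_i ln(w_i/w0_i) (so S <= 0 away from the reference w0, and
chi^2 at the optimum never exceeds chi^2(w0)).  Weights are
parameterized by a softmax and optimized with L-BFGS using the analytic
gradient; random simplex starts are Dirichlet(1) draws from a stated
seed.  sigma comes from the observed profile when given, else 1; theta
defaults to 10 with the benchmark runs using 0.05 (a log-spaced theta
scan is a one-line loop for the caller).  As theta -> 0 the solution
approaches the simplex-constrained least-squares fit, which the tests
verify against an independent SLSQP oracle.  The two-round protocol (ten
random-start fits, keep conformers with summed population > 0.01, ten
more fits on the kept set, report mean +- sd with the mean renormalized)
is as described above.

Greedy subset growth maximizes the equal-weight ensemble Pearson R at
each step and emits the full RMS/R/Q trajectory; the caller picks the
subset size.  The R trajectory is not guaranteed monotone on arbitrary
inputs (adding the second of three complementary curves can lower R
before the third restores it), so the trajectory — not a stopping rule —
is the contract.

## Synthetic data: what it emulates, what it does not

The generator plants per-residue torsion preferences as wrapped-Gaussian
mixtures on the torus (defaults centered on the helical and extended
basins), integrates them over voxels to fake predictor output, builds
conformers by direct chain extension from sampled torsions, and mixes
per-conformer curves under known weights with relative Gaussian noise.
It emulates the *shape* of real inputs, not their failure modes: no
chemical-shift noise model, no systematically misassigned residues, no
solvation effects in the curves, no sidechains beyond CB.  Passing tests
therefore demonstrate algorithmic correctness and recoverability under
clean conditions, not field performance on measured data.

The population-recovery benchmark uses 30-residue chains (25 conformers:
5 true at weights 0.35/0.25/0.20/0.12/0.08 plus 20 decoys), 60 q-points
in [0.05, 5] nm^-1 and 1% relative noise.  Chain length matters: members
must differ in global shape for a scattering curve to constrain their
populations, which is the regime tandem-domain ensembles live in — with
much shorter chains even the constrained least-squares oracle cannot
reach the 0.05 mean-absolute-error mark, i.e. the limit is informational,
not algorithmic.  At the benchmark condition the mean absolute error of
the recovered population vector is about 0.04–0.05 across seeds.  Exact
support identification is *not* reliable here: a true member's curve can
be reproduced by a linear combination of the others (mixture
collinearity), in which case its mass is redistributed without hurting
the aggregate error — the same degeneracy that prevents resolving
individual compact conformations from a single scattering curve in real
studies.

## Scale of the shipped computations

Tests and the acceptance script run at desk scale by design: fragments of
2–6 residues with one to three distance samples per torsion, 20 x 20
maps, 25-member ensembles.  These sizes exercise every code path —
branching, mirror pruning, gating, toroidal wraparound, clustering,
two-round fitting — while each suite finishes in seconds to a few
minutes on one CPU.  Production-scale settings (10^9-leaf caps,
100 x 100 maps, thousand-member sets) are the library defaults and
change no logic, only runtime.
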