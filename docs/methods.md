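# Methods

`chromolink` implements a minimal coarse-grained model of nucleosome arrays
and the analysis pipeline needed to study how internucleosomal linker
length controls fiber conformation, inter-fiber stacking, and liquid-liquid
phase separation (LLPS) of chromatin, together with a closed-form model of
linker twist energetics and a stochastic model of ISWI-family nucleosome
remodeling.  Units throughout: Angstrom, kcal/mol, degrees, femtoseconds;
`1 timestep = 100 fs`.

## The model

**Resolution.**  Five DNA base pairs form one spherical rigid bead; each
histone octamer is a single core bead.  A 147-bp nucleosome is therefore
~30 particles: 29 wrapped-DNA beads rigidly fixed to the core on a
left-handed superhelix (1.65 turns, radius 41.8 A, pitch 25.4 A — the
canonical nucleosome dimensions, giving a disc ~110 A across and ~55-60 A
high), plus the core bead at the wrap centroid.  Linker DNA beads are free
and connected by bonds.  Every bead carries a position and a unit
quaternion (scalar-first); the core bead's +z axis is the disc (face)
normal.

**Bonded DNA energetics.**  Consecutive DNA beads interact through a
rigid-base-pair harmonic potential in the six helical step parameters
(shift, slide, rise, tilt, roll, twist), `E = 1/2 dphi^T K dphi`, with the
step evaluated in the mid-step frame convention: rotations are the
components of the rotation vector of `R_i^T R_j`, translations the
displacement expressed in the half-way frame.  The equilibrium step is
pure rise 16.45 A and twist 172 deg per bead (3.29 A and 34.4 deg per bp),
and the stiffness matrix is diagonal,
`K_diag = (0.301, 0.235, 1.56, 0.00614, 0.00515, 0.00724)` in kcal/mol per
(A or deg)^2.  The twist deviation is wrapped to (-180, 180] before the
quadratic form.  Nucleosomal-DNA steps internal to one rigid group carry
no bonded energy; linker steps and linker/nucleosome junction steps do.

**Pair interactions.**  Nonbonded beads interact through shifted-truncated
Lennard-Jones potentials, `E(r) = E_LJ(r) - E_LJ(r_c)` for `r < r_c` and 0
beyond, continuous at the cutoff.  DNA-DNA interactions are purely
repulsive (WCA-truncated at the potential minimum), a mean-field stand-in
for screened electrostatic repulsion between phosphate backbones; DNA-core
and core-core interactions are attractive, standing in for the attraction
between DNA and the positively charged histone surface.  Bonded neighbors
and same-rigid-group pairs are excluded.

**Calibration of the pair table.**  The three class-pair parameters at the
150 mM monovalent reference are tuned (Nelder-Mead, implemented in
`chromolink.forcefield.calibrate_pair_table`) against idealized
nucleosome-pair scans: two mononucleosomes in a fixed relative orientation,
inter-particle energy scanned over center-center distance.  Anchors:
face-to-face minimum ~60 A at ~-4.8 kcal/mol, face-to-side ~75 A at
~-4.2 kcal/mol, side-to-side ~110 A at ~-0.8 kcal/mol.  The frozen
parameters reproduce all three minimum *locations* to ~1% (60.0, 76.0,
109.1 A) and the face-to-face/face-to-side depths to ~0.05 kcal/mol; the
side-to-side depth saturates at ~-0.46 kcal/mol, a geometric limit of the
three-class isotropic-bead representation (at an edge-on contact the
attraction comes only from LJ tails), and is documented rather than forced.
The depth ordering face-to-face < face-to-side < side-to-side is preserved.
Salt enters as a monotone multiplier on the attractive well depths
(tabulated at 50-250 mM, linearly interpolated): higher monovalent salt
screens DNA-DNA repulsion, which at this resolution is equivalent to deeper
net internucleosome attraction.  Only the well depths vary with salt; the
geometry (sigma, cutoffs) does not.

## Fiber construction

A fiber is specified by the number of nucleosomes, per-linker bp lengths
(any integers), and the bp of bare DNA flanking the terminal nucleosomes.
The whole fiber is tiled into 5-bp beads from the entry end; a trailing
remainder of fewer than 5 bp is discarded; a bead takes the class of its
central base pair.  This makes the DNA bead count exactly
`floor(total_bp / 5)` and, importantly, preserves the per-bp twist
bookkeeping for linkers that are not multiples of five: every bead step
spans exactly 5 bp, so the relative rotation of successive nucleosomes is a
faithful function of linker length (~34.4 deg per bp at equilibrium).

The `extended` initial conformation places every free step exactly at the
equilibrium helical parameters (zero bonded energy by construction;
junction steps are anchored at equilibrium).  For 10N-class linkers this
equilibrium-step build stacks nucleosome discs into steric overlap — the
compact zig-zag geometry — so dynamics is seeded from an *opened* build
instead: a deterministic grid search adds a few degrees of tilt/roll/twist
per linker step (at <1 kcal/mol per step of bonded cost) and picks the
lowest-energy clash-free variant (`open_conformation`).  The `relaxed` mode
additionally removes residual overlaps by capped steepest descent with
soft-core staging (pair sigmas ramped 0.5 -> 1.0) and runs a short seeded
Langevin equilibration.

## Dynamics

Rigid-body Langevin dynamics with a BAOAB stochastic-splitting integrator:
deterministic half-kicks and drifts around an exact Ornstein-Uhlenbeck
velocity update, applied to body translations and rotations.  Rotational
inertia is isotropic (the mean principal moment plus a small per-bead
sphere term), which removes gyroscopic terms; in the overdamped regime used
here this only rescales short-time rotational kinetics.  LJ forces are
analytic (cell-list neighbor search via a periodic k-d tree with a 10 A
Verlet skin, refreshed every 20 steps); bonded forces use analytic
translational gradients and central finite differences (h = 1e-5 rad) in
rotation-vector coordinates for the torques.  The default timestep is
100 fs; the friction coefficient is exposed in the configuration (default
0.01 fs^-1; the slab and diffusion studies below use 2e-4 fs^-1, i.e. a
~5 ps damping time, so that fiber center-of-mass motion is observable at
desk scale — friction rescales kinetics, not thermodynamics).

Temperature replica exchange uses a geometric 300-600 K ladder with
neighbor swaps every 100 steps (alternating pair parity), the Metropolis
criterion on total potential energy including any umbrella bias, velocity
rescaling by sqrt(T_new/T_old) on exchange, and analysis restricted to the
coldest replica.  `autosize_ladder` grows the replica count until the
measured mean acceptance reaches ~0.3.

Direct-coexistence systems pack fibers with random orientations into the
central third of an elongated periodic box (production geometry
1200 x 1200 x 5000 A with 125 twelve-nucleosome arrays; reduced boxes for
desk-scale work), rejecting placements with inter-fiber core distances
below a threshold, followed by minimization.  The center of mass can be
fixed during production.

## Free energy

Umbrella sampling biases a collective variable (inter-fiber center-of-mass
distance, or the end-to-end extension of one fiber) with a harmonic
potential; the production protocols are 16 equally spaced windows over
0-600 A at k = 0.002 kcal/mol/A^2 (inter-fiber) and 20 windows over
0-950 A at k = 0.0005 (intra-fiber).  Each window runs its own
replica-exchange simulation; windows never exchange with each other.  PMFs
are reconstructed with standard single-temperature binned WHAM (default
200 bins, tolerance 1e-6 kcal/mol, up to 1e5 iterations); a disconnected
pooled histogram raises an error naming the gap.  Well locations and
depths are read off by quadratic interpolation around the discrete
minimum, with depth measured against the large-separation plateau; a
monotone profile reports "no bound state" rather than failing.  The WHAM
solver is validated against an exact-distribution rejection sampler from
declared 1-D potentials (`make_wham_oracle`): a double-well is recovered
within 0.2 kcal/mol, and the single-unbiased-window case reduces exactly
to Boltzmann inversion.

## Phase analysis

Density profiles along the long box axis are COM-centered per frame and
converted to g/L (molar mass per volume).  Coexistence densities come from
plateau estimators: the central 60% of the detected slab (dense branch)
and the 20% of the box farthest from the slab center (dilute branch); a
relative contrast below 0.2 is reported as single-phase, a valid outcome.
The critical point is fitted jointly to the 3-D Ising gap law
`(rho_h - rho_l)^3.06 = d (1 - c/c_c)` (exponent fixed, prefactor `d` a fit
parameter) and the law of rectilinear diameter
`(rho_l + rho_h)/2 = rho_c + s (c_c - c)`, with parameter errors from the
least-squares Jacobian.  On noiseless synthetic binodals the fit inverts
the generator exactly; under 1% density noise the critical salt is
recovered within 2%.

## Structure metrics

Nucleosome contacts use the core-bead centers and face normals with a
120 A distance cutoff and a single 45 deg angular threshold.  Because the
three printed definitions overlap, classification is an exclusive decision
tree: face-to-face if the axis-axis angle is below 45 deg (axes folded to
[0, 90] deg — discs are two-sided); otherwise face-to-side if exactly one
axis is within 45 deg of the center-center direction; otherwise
side-to-side.  The zig-zag fraction counts (i, i+2) intra-fiber contacts
normalized by nucleosomes-per-fiber times frames; inter-fiber valence
counts distinct neighboring fibers per fiber.

dRMSD between two structures is the root-mean-square difference of their
intramolecular nucleosome-center distance matrices — symmetric, zero iff
the distance matrices agree, and invariant under rigid transforms of
either structure (reference-free).  Clustering runs k-means in dRMSD space
with medoid centers (dRMSD embeds in no Euclidean space; assignment and
medoid updates are both non-increasing in the objective), seeded random
initialization, default 20 clusters and up to 1000 iterations.

Diffusion coefficients come from time-averaged MSD curves of fiber centers
of mass, D = slope/6 over a configurable lag window (default excluding the
shortest quarter of lags), with uncertainties from block averaging over
contiguous trajectory segments; values are reported per timestep and
normalized to a reference linker length where comparisons are made.

## Linker twist-deformation model

Enforcing a parallel (stacking-compatible) orientation across an L-bp
linker twists it away from the nearest integral number of helical turns by
`Delta(L) = min_m |L*theta - 360 m|` degrees.  Treating the linker as L
torsional springs in series gives `E(L) = k/(2L) * Delta(L)^2`.  The two
constants are over-determined by the six published 25-30 bp energies
(21, 20, 12, 6, 2, 0.3 kcal/mol); least-squares calibration (grid over the
helical repeat, then refinement) gives theta = 35.302 deg/bp (an effective
repeat of ~10.2 bp/turn, absorbing wrap-end effects) and
k = 0.0397 kcal/mol/deg^2, with residuals below 0.17 kcal/mol per point.
The defaults are these calibrated values; the calibration reruns in
seconds and is part of the test suite.

## Remodeling Monte Carlo

One cycle models a single ISWI-family enzyme processing one fiber chosen
uniformly at random: (1) pick the fiber; (2) push the terminal nucleosomes
to the fiber ends, absorbing all flanking DNA into the terminal linkers;
(3) pick an internal nucleosome (2..11 of 12) at random; (4) equalize its
entry and exit linkers, assigning the odd base pair (if any) to a random
side; (5) propagate the equalization outward to both neighbors
alternately (lower index first) until the ends are reached.  Terminal
nucleosomes have a single linker and are not equalized — equalizing
against an empty flank would leak DNA back out of the linkers.  Total DNA
per fiber is conserved exactly by every cycle, so the converged mean is
fixed by composition: eleven 25-bp linkers plus 52 bp of flanks gives
327/11 = 29.7 bp, and the 30-bp start gives 382/11 = 34.7 bp.  Convergence
is declared when every linker lies within +-1 bp of its fiber mean (the
integer-parity floor) and no flanks remain.  Snapshots at any cycle are
exportable as fiber-builder inputs, enabling phase-diagram runs at
intermediate remodeling stages.

## Synthetic data generators

All analyses are testable without external data: idealized stacked
nucleosome pairs (`make_stacked_pair_fixture`) realize each contact class
by construction; `make_synthetic_binodal` inverts the critical-scaling
laws exactly (plus optional seeded noise); `make_wham_oracle` draws
exact-distribution biased samples by rejection; `make_slab_profile_fixture`
builds two-plateau density profiles with tanh interfaces.  These emulate
the *structure* of simulation output, not its correlations: real
trajectories have correlated frames and anisotropic noise, so passing
these tests validates the estimators, not the sampling.

## Problem sizes and scaled-down studies

The production protocol of the modeled study (125 twelve-nucleosome
fibers, 1e8-step coexistence runs, 16-replica T-REMD per umbrella window)
is far beyond a desk run.  The package's own validation uses reduced
systems chosen once: pair scans with mononucleosomes (deterministic,
seconds); WHAM and critical-point fits on synthetic oracles (seconds);
slab-retention and condensed-phase diffusion comparisons with
four-nucleosome fibers (8 and 6 fibers respectively) in reduced boxes at
friction 2e-4 fs^-1, a few thousand steps.  At these sizes the
slab-retention comparison probes the *initial stability* of the dense
phase (whether inter-fiber cohesion holds the slab against thermal and
repulsive stress), not full evaporation-condensation equilibrium; the
diffusion comparison probes short-time mobility ordering, not the
converged long-time D of the production model.

Two emergent orderings of the full-scale study are not reproduced at
these sizes, and their tests are expected to fail until run at production
scale.  Dispersal of a slab requires fiber-scale transport
(COM diffusion here is ~4e-4 A^2/step even at the low-friction setting),
so a short-linker slab merely holds its density slightly better
(retention ~1.00 vs ~0.98 at 50-75 mM) instead of the long-linker system
actually dispersing.  Short-time condensed-phase diffusion is dominated
by how each system happens to pack (the more compact long-linker fibers
acquire more weak contacts and move *slower*), inverting the
published mobility ordering, which arises from orientationally
equilibrated inter-fiber stacking that desk-scale sampling cannot reach.

## Known limitations

- The side-to-side pair-well depth is ~-0.46 kcal/mol against the
  ~-0.8 kcal/mol calibration anchor (geometric limit of isotropic beads).
- No explicit ions and no divalent cations; salt acts only through the
  attraction multiplier.
- Isotropic rotational inertia and finite-difference bonded torques are
  numerical simplifications; the equipartition and zero-friction energy
  tests bound their effect.
- Equilibrium-step ("extended") builds of 10N-linker fibers are sterically
  frustrated by construction; dynamics must be seeded from opened builds.
- Full binodals at production scale (e.g. the 65 mM critical salt of the
  15-bp system) require cluster-scale compute and are out of desk scope.
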