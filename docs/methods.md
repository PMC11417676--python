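# Methods

`solvshell` implements, at desk scale, the complete workflow for training
machine-learning interatomic potentials (MLPs) for metal ions in explicit
solvent: similarity-driven active learning on solvated clusters, a trainable
potential with analytic forces, molecular dynamics with cluster restraints,
umbrella sampling with WHAM free-energy reconstruction, and solvation-shell
structural analysis.  Every component is exercised against an analytic
classical reference potential, so the whole pipeline is testable without an
electronic-structure code.

Internal units are kcal/mol, Å, fs and K throughout; meV appears only in
validation reports (1 eV = 23.0605 kcal/mol, so 1 kcal/mol = 43.3641 meV).
All constants live in `solvshell.units`.

## The classical reference potential

The "ground truth" role normally played by density-functional calculations is
filled by an analytic classical force field:

* **Water-like solvent** — a flexible 3-site model in the SPC/Fw family:
  qO = −0.82 e, qH = +0.41 e, σO = 3.1655 Å, εO = 0.1554 kcal/mol, harmonic
  bonds (k = 1059.162 kcal/mol/Å², r₀ = 1.012 Å, in the ½k(r−r₀)² convention)
  and angle (k = 75.90 kcal/mol/rad², θ₀ = 113.24°).
* **Divalent cation** — a bare +2 charge with 12-6 Lennard-Jones
  σ = 1.644 Å, ε = 0.875 kcal/mol.  These values were verified by direct MD
  before being frozen: 50 ps of the ion in 100 waters at 300 K gives an
  octahedral first shell (coordination number 6, Mg–O peak at ≈ 2.1 Å),
  matching the known solution structure of Mg²⁺.
* **Nitrile-like solvent** — a linear united-atom Me–C–N molecule (charges
  +0.269/+0.129/−0.398 e, two stiff bonds, a stiff harmonic angle at 180°,
  evaluated through the stable (π−θ)/sin θ limit) plus a +2 palladium-like
  cation, used for the square-planar complex fixtures.

Electrostatics use damped shifted-force (DSF) Coulomb (α = 0.2 Å⁻¹) and the
Lennard-Jones term is shifted-force as well; both are continuous in energy
and force at the cutoff (min(9 Å, L/2) under periodic boundary conditions),
which is why plain-cutoff microcanonical dynamics conserves energy (measured
drift < 0.4 kcal/mol over 10 ps for a 100-molecule box; the acceptance bound
is 1 kcal/mol).  Combination rules are Lorentz–Berthelot.  All forces are the
exact negative gradient of the energy, verified by central differences to
1e-5 kcal/mol/Å.  Only orthorhombic cells are supported.

This surrogate preserves the *physics* the workflow must handle (a strongly
bound octahedral first shell, solvent exchange, liquid structure) but not the
quantitative values of any electronic-structure surface: dissociation
barriers, absolute energies and MADs here are properties of the surrogate,
not reproductions.

## SOAP descriptors and the similarity selector

Each atom's neighbour density (Gaussians of width σ_atom = 0.5 Å on every
neighbour within r_cut = 5 Å, including the atom itself, weighted by a cosine
switch over the outer 1 Å) is expanded per neighbour species in n_max = 6
orthonormalized Gaussian radial functions times real spherical harmonics up
to l_max = 4.  The rotation-invariant power spectrum p_{nn'l} is the per-atom
descriptor; the global structure descriptor is the average over atoms,
L2-normalized.  Radial integrals use Gauss–Legendre quadrature with an
exponentially scaled modified spherical Bessel evaluation (series below
x = 8, recurrence above), accurate to machine precision against
`scipy.special.spherical_in` and validated against brute-force 3D quadrature
of the smeared density (relative agreement better than 1e-4).

Structure similarity is k(p, p') = |p·p'|^ζ with ζ = 4.  A candidate is
selected for the training set iff max over the training set of k is strictly
below the threshold k_T; an empty training set always selects.  A kernel
value within 1e-12 of 1 is snapped to exactly 1 so that a self-match can
never pass a threshold ≤ 1.  The global descriptor averages per-atom
descriptors (rather than averaging per-atom kernels); both conventions are
common and the choice only rescales thresholds.

## The linear invariant-feature potential

The trainable potential is linear ridge regression over per-atom invariant
features: a constant per element, 2-body sums of 32 Gaussian radial functions
× a smooth cosine cutoff per neighbour species, and 3-body sums over
neighbour pairs of coarse radial products × cos^p θ (p = 0..5) per unordered
species pair, all inside r_cut = 6 Å.  Forces are the exact analytic
negative gradient, so the model satisfies the same calculator contract as the
classical surrogate and drives the MD engine directly.  Energy is a sum of
per-atom terms, hence exactly size-extensive.

Fitting minimizes
Σ_c (E_pred − E_ref)²/N_c + w_F Σ |F_pred − F_ref|² + structured ridge,
with w_F = 0.1, by a deterministic normal-equations solve.  Three choices
here matter and were made after measuring failure modes on the end-to-end
task (they are defaults, exposed in `FeatureSpec`/`fit`):

* **Feature resolution.** 16 radial functions with cos powers 0..3 fit
  point-wise energies well but produced potentials whose 50 ps dynamics
  collapses the solvation shell; 32 radial functions with cos powers 0..5 are
  the smallest set we found whose trained potentials reproduce the reference
  first-shell structure robustly across random seeds.
* **Block (structured) Tikhonov regularization.** Ridge 1e-4 on the constant
  and 2-body weights, 0.1 on the 3-body block.  On fixed-composition training
  sets the 3-body basis is strongly collinear, and an unpenalized solve picks
  huge, arbitrary weights whose off-manifold extrapolation destroys dynamics;
  the stronger 3-body penalty bounds that freedom at negligible cost to the
  fit (held-out MAD stays sub-meV/atom).
* **Core-repulsion guard.** A fixed cubic repulsive wall
  U = A((r_c−r)/r_c)³, A = 5000 kcal/mol, switched on per species pair below
  r_c = 0.8 × the smallest distance of that pair seen in the training data.
  It is exactly zero on every training configuration (the fit is unchanged)
  and only prevents the linear model's unconstrained extrapolation below the
  sampled range from fusing atoms — the standard inner-cutoff/core-repulsion
  practice for linear body-ordered potentials.

An in-span sanity property holds exactly: data labelled by any potential in
the model's own function class is interpolated to < 1e-6 kcal/mol/atom as the
ridge vanishes.

## MD engine

Velocity-Verlet with dt = 0.5 fs.  NVT uses stochastic velocity rescaling
(CSVR): the kinetic energy relaxes toward N_f k_B T/2 over τ = 100 fs with
Gaussian/χ² noise terms whose stationary distribution is the canonical
Gamma(N_f/2) law (verified by a Kolmogorov–Smirnov test on the iterated
map and by equipartition of long runs).  Initial velocities are
Maxwell–Boltzmann at the target temperature with the run's seed, net momentum
removed and N_f = 3N − 3.  Identical seeds and inputs reproduce trajectories
bit-for-bit.

Restraints use the biasing-library convention **U = k·Δ² (no ½)**: the
flat-bottom sphere (zero inside the onset radius, harmonic outside, with the
reaction force on the centre atom so momentum is conserved) and harmonic
restraints on collective variables.  The WHAM unbiasing uses the same
convention constant; that consistency, not the convention itself, is what
correctness requires.  Non-finite energies truncate a run and flag it
unstable — the active-learning driver treats that as a signal, not an error.

## Active learning

One cycle: propagate n_parallel (default 10) trajectories from the same
start with seed-varied velocities for n³ + 2 fs (n = run index, from 0),
screen sampled frames chronologically with trajectories interleaved
round-robin, label accepted frames with the reference calculator, append and
retrain.  If a cycle selects nothing, n increments and a longer run is tried;
a phase ends at the cycle cap or when a full cycle at the maximum AL time
selects nothing.  The dataset only grows, every accepted structure was
dissimilar (max K < k_T) to the dataset at its acceptance moment, and the
cubic schedule guarantees termination.  Retraining re-solves the accumulated
normal equations (identical result to a from-scratch fit, O(D³) per cycle).
A manual-injection hook adds externally chosen structures as a logged,
first-class operation.

Labelled candidates whose maximum reference force exceeds 150 kcal/mol/Å are
rejected (logged per cycle).  Such collision states carry residuals hundreds
of kcal/mol above the rest of the data and would dominate the squared loss,
warping the bonding region; screening them out is the quantitative form of
the workflow rule that overly distorted structures should not enter training.

The end-to-end study conditions (also the default demonstration): bootstrap
with 10 random-displacement structures (σ = 0.05 Å per Cartesian component)
of the octahedral complex; phase 1 at 400 K, k_T = 0.999, max AL time 3 ps,
flat-bottom 500 kcal/mol/Å² at 8 Å; phase 2 at 600 K, k_T = 0.9999, max
3 ps, restraint tightened to 7.5 Å.  The hotter second phase makes the
model's own dynamics visit partial-dissociation states during training, which
is what makes the final potential hold the first shell together over 50 ps.
Under these conditions the trained potential reproduces the surrogate's
ion–oxygen RDF first-peak position to within 0.1 Å (validated across six
independent seeds during development).

## Free-energy machinery

Umbrella windows are independent restrained NVT runs; the equilibration
portion is discarded and neighbouring-histogram overlap is reported.  WHAM
iterates the window free-energy constants to a residual below 1e-7 and
returns the profile gauge-fixed to min A = 0; non-overlapping adjacent
windows are an error naming the gap.  For a single unbiased window WHAM
reduces exactly to Boltzmann inversion.  Distance-coordinate profiles can be
corrected by the radial configuration-volume (Jacobian/entropy) term
2 k_B T ln(r/r_ref), with r_ref at the reactant minimum; barriers are
A(TS) − A(reactant minimum) with the TS at the profile maximum beyond the
minimum (distance CV) or at a supplied CV value (coordination CV), and the
uncertainty is the standard deviation across repeats at the TS point.

The coordination-number CV uses the rational switch
s(r) = (1 − (r/r₀)^p)/(1 − (r/r₀)^q) with p = 6, q = 12 and a series branch
through the removable singularity at r = r₀ (s → p/q), so the analytic
gradient is continuous everywhere and passes finite-difference checks at
r = r₀ itself.

Desk-scale umbrella presets use 12 windows of 20 ps; the production-scale
protocol (48 windows over 1.5–6.0 Å, 500/250 kcal/mol/Å² force constants,
2400 kcal/mol per CV-unit² for the coordination CV) goes through the same
API.  Note the window count and range are primary; the spacing is
derived from them.

## Structural analysis

RDFs histogram minimum-image centre–partner distances normalized by
ideal-gas shell counts at the partner density (bin width 0.05 Å); the running
coordination number is the cumulative mean partner count, so N(r_max) equals
the directly counted average.  First-shell detection smooths g with a 5-point
moving average (edge-replicated padding) for peak/minimum location but
integrates N on the raw histogram; a g that has decayed to numerical zero
after an isolated peak counts as having its minimum there (gas-phase
clusters have no second shell).  Cluster extraction keeps molecules whole by
their anchor atom (O for water-like, N for nitrile-like), unwraps them across
the periodic boundary and re-centres on the centre atom.  The axial
classifier fits the equatorial plane through the 4 bound anchors by SVD and
counts solvent anchors within 2.4–3.6 Å of the metal and a 35° cone about
the plane normal (0/1/2 → square-planar/square-pyramidal/octahedral).

## Synthetic systems

Solvent boxes are packed on a jittered cubic lattice at the target density
(box edge from L = (n·M/(ρ·N_A))^{1/3}; 112 water-like molecules at
0.997 g/cm³ give L = 14.98 Å) with random molecular orientations and a
2.2 Å intermolecular heavy-atom contact rule; the jitter amplitude shrinks
automatically at tight packings so the contact margin survives.  A packed
lattice retains local order: cluster counts and liquid structure are only
meaningful after ~20 ps of thermostatted MD, which is what the equilibration
steps in the tests and the reproduction script use.  Complex builders place
template ligands on ideal octahedral / square-planar / square-pyramidal /
trigonal-bipyramidal anchors (with separately settable equatorial/axial bond
lengths for transition-state-like templates), and a damped steepest-descent
minimizer relaxes packed fixtures before dynamics.  All generators are
deterministic per seed.

## What the synthetic conditions do and do not show

Everything here runs against the classical surrogate, whose energy surface
is far smoother than an electronic-structure reference: there is no charge
transfer, no proton transfer, and the solvent is rigid in composition.
Passing tests therefore demonstrate that the *workflow* is correct — the
selector admits exactly the structures it should, the fitted potential's
forces are exact gradients, the thermostat samples the canonical ensemble,
WHAM inverts known biased distributions, the AL loop converges and its
product reproduces the reference solvation structure — but not that a
potential trained this way reaches any particular accuracy against a quantum
reference.  Quantities tied to the reference surface (dissociation barriers,
MAD magnitudes, axial-occupancy ratios) are surrogate properties.

## Known limitations

* Orthorhombic cells only; no Ewald/PME (DSF throughout), no barostat, no
  rigid-body constraints.
* The linear model's transferability across compositions is limited; the
  core-repulsion guard and block regularization manage, but do not remove,
  extrapolation risk far from the training manifold.
* SOAP descriptor gradients are not implemented (selection needs values
  only).
* The classical surrogate's square-planar palladium-like system is used for
  geometry fixtures and the classifier; an isotropic point-charge model does
  not itself enforce square-planar coordination in free dynamics.
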