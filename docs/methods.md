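# Methods

## The model

`deltagap` implements delta-learning interatomic potentials for molecular
crystals containing several distinct neutral components (co-crystals).  A
cheap, long-ranged physical *baseline* calculator is corrected by
short-ranged machine-learned terms, split by interaction type:

    E(crystal) = E_baseline(crystal)
               + sum over component types t,
                 sum over molecules i of type t:  dE_intra^t(monomer_i)
               + dE_inter(crystal)

One intramolecular correction is fitted per component type; a single
intermolecular correction covers all component combinations.  The split is
motivated by the different length scales of the two interaction classes and
by the fact that intramolecular training data comes from cheap gas-phase
single points (possibly even at a different level of theory per component —
supported here through independent per-component label generation).
Corrections apply to energies, forces and virials, so the composite model
drives variable-cell relaxation and constant-pressure dynamics.

Intra corrections are evaluated on unwrapped in-crystal monomer geometries;
their forces map back onto the parent atoms and their virial contribution is
assembled from the monomer's internal displacement vectors.  Because intra
forces sum to zero over each molecule, this is gauge-consistent: the result
does not depend on which periodic image of the molecule the cell stores.

The *inter* training label is deliberately defined as the residual

    y_inter = [E_target - E_baseline] - sum_i dE_intra(monomer_i at the
              in-crystal geometry, as predicted by the fitted intra models]

rather than as a difference of raw monomer reference energies.  This choice
makes the energy expression exact by construction on the training data:
whatever the intra models failed to capture is absorbed into the inter
label, and the decomposition audit (baseline + intra + inter == total,
within 1e-10 eV) holds identically for any structure.

## Descriptors

Atomic environments are encoded by the SOAP power spectrum.  Each neighbor
within the cutoff is smeared by a Gaussian (width `sigma_atom`) multiplied
by a C2 polynomial switching function over the outer `smooth_width` of the
cutoff; the density is expanded in `n_max` Gaussian radial functions times
spherical harmonics up to `l_max`, and contracted to the rotation-invariant
power spectrum over species pairs.  The contraction is computed through the
spherical-harmonic addition theorem, i.e. as a double sum over neighbor
pairs weighted by Legendre polynomials of the enclosed angle.  This form is
algebraically identical to the usual sum over m of c_nlm c*_n'lm and gives
compact analytic gradients with respect to every neighbor displacement
vector, from which forces and virials follow exactly.

The radial integrals (neighbor Gaussian against each radial basis function,
including the modified spherical Bessel factor) are tabulated once per
hyperparameter set by 220-point Gauss-Legendre quadrature on a 500-point
grid of neighbor distances and represented as cubic splines.  The spline
*is* the definition of the radial channel: its analytic derivative is the
exact gradient of what the forward pass computes, so force consistency does
not depend on quadrature accuracy.  Descriptors are L2-normalized, the
normalization included in the chain rule.

Environment similarity is the dot-product kernel k = (d . d')^zeta with
integer zeta (even powers keep Gram matrices positive semidefinite by the
Schur product theorem).  The kernel between environments of different
center species is defined as zero.  Structure dissimilarity is the
symmetric Hausdorff value of the kernel-induced metric d = sqrt(2 - 2k)
over the two environment sets — symmetric and zero for identical sets,
which a raw cross-maximum of environment distances would not be.

Two descriptor configurations are used by role: intra models see a short
cutoff (3.0 A), the inter model one reaching just past the intermolecular
interaction range (3.2 A in the toy pipeline; the generic default is
5.0 A).  Keeping the inter cutoff tight matters beyond cost: environments
that stop at the physics' own range transfer far better between unrelated
random packings than ones that fold two further neighbor shells into the
descriptor.  The toy pipeline also uses a smoother kernel (zeta 2) and a
sharper smearing (sigma_atom 0.4 A) for the inter model — the correction
is a smooth pairwise function and a high kernel exponent memorizes
structures instead of generalizing it — while intra models keep zeta 4.
Conventional GAP-style defaults are n_max 8, l_max 4, sigma_atom 0.5 A,
zeta 4; the toy pipeline uses n_max 4 and l_max 3, which fully resolves
its two- and three-atom molecules at a fraction of the cost.

## Regression

The total energy is a sum of per-atom local energies, each a kernel
expansion over m representative ("sparse") environments chosen by farthest
point sampling in descriptor space, plus a constant per-species offset.
Weights solve one regularized least-squares system whose rows are energy
sums, force components (chain rule through the descriptor gradients) and,
when labeled, virial components; each row is scaled by its noise level
(defaults: 1 meV/atom for energies, 50 meV/A for forces, 50 meV for
virials; the toy pipeline tightens these to 0.5 meV/atom and 10-20 meV/A
because its labels are analytic and noise-free).  A `weight_class` tag per
observation selects alternative noise levels, so strongly perturbed
structures can carry looser weights.  The sparse-point Gram matrix (plus
1e-8 jitter) enters through its Cholesky factor as a Tikhonov prior — the
standard projected-process objective — and the stacked system is solved by
orthogonal factorization (LAPACK gelsd).  A tiny ridge (1e-8) on the offset
columns removes the exact collinearity that arises when all observations
share one stoichiometry.

## The toy universe

The bundled fixture universe stands in for the production setting in which
the baseline is a tight-binding method and the target a hybrid-functional
composite: both are replaced by analytic calculators whose difference is a
smooth, short-ranged, learnable function of local geometry.  Components are
one "active" bent triatomic (water-like geometry: O-H 0.97 A, 104.5
degrees) and four co-formers (two diatomics, N2 and O2; a heteronuclear
diatomic, NO; and a linear triatomic, N2O), giving element-labeled graphs
that are mutually non-isomorphic using only H, N and O.  Both calculators
sum (a) harmonic terms on all intramolecular atom pairs — stiff for bonded
pairs, softer for 1-3 pairs, equilibria taken from the component reference
geometry — and (b) smoothly truncated intermolecular Lennard-Jones terms
under strict minimum image.  Bonding topology is perceived once per
species sequence and then held fixed (the way a force field fixes
connectivity), so a thermally stretched bond cannot transiently
re-partition the system mid-trajectory; the toy stack uses a bond
tolerance of 1.1 x the covalent-radius sum, slightly tighter than the
generic 1.2 default, so compressed intermolecular contacts are never read
as bonds.

The baseline over-binds through its attraction, not its wall: the r^-6
term is 30% too strong while the r^-12 repulsion is shared with the
target, and the target alone carries a weak extra attractive tail.  Two
considerations fix this design.  First, it matches the physics being
emulated — semi-empirical baselines contract molecular crystals because
the repulsion/attraction balance at contact distances is off, not because
their hard walls differ.  Second, it keeps the learning problem honest: the
target-minus-baseline pair difference is then a smooth bounded function
(proportional to the attraction), so a short-ranged kernel correction can
represent it everywhere a relaxation or barostat will go; had the walls
differed, the correction would have had to extrapolate a steeply rising
repulsion difference exactly where kernel models extrapolate worst.  Well
depths (eps 0.014-0.032 eV per species) are set so lattice energies come
out at tens to a few hundred meV per molecule — the realistic scale for
organic crystals — because a much softer landscape makes packing densities
ill-conditioned against model errors of any origin.  Bonds are ~30%
stiffer under the baseline with equilibria contracted by 3%, which
dominates the baseline's force-component errors just as intramolecular
errors do in the production setting.

The toy interaction cutoff is 3.0 A rather than the SOAP 5 A because the
calculator insists on strict minimum image and raises when the cutoff
exceeds half the smallest cell height.  The Lennard-Jones radii (sigma
1.70-1.85 A per species) put that cutoff at about 1.7 sigma, so the
attractive well and the nearest part of the second neighbor shell sit
inside the interaction range and the potential has a proper density
minimum (a shorter relative cutoff would reward unbounded
coordination-maximizing collapse).  Study cells hold twelve molecules and
generation enforces a minimum cell height of 7.0 A, so relaxation paths
stay inside the validity domain; generation also rejects intermolecular
contacts below 2.0 A, safely above every bond-perception cutoff, so
perturbation and thermal motion cannot silently merge molecules.  One
consequence of the small radii is that fully equilibrated packings are
dense in g/cm^3 terms (2.5-4.5); this is internally consistent and only
the finite-temperature fixture works in that regime.

What the toy universe does *not* emulate: electrostatics and polarization,
many-body dispersion, conformational flexibility beyond harmonic
distortions, space-group symmetry, and fully compact packing (random
packings relax to partly porous structures of 0.3-0.8 g/cm3).  Passing the
miniature study therefore demonstrates that the machinery — splitting,
labeling, selection, regression, bookkeeping, relaxation and dynamics —
recovers a learnable baseline/target gap; it does not certify accuracy for
any real chemistry.

## The miniature study

The bundled protocol mirrors a screening study at desk scale: for each of
the four active/co-former pairs, 600 random trial crystals of twelve
molecules spanning five stoichiometries (including both single-component
crystals) are generated at 40-110 A^3 per molecule, locally relaxed at the
baseline level (a capped, loose variable-cell relaxation — trial
candidates in a screening workflow are always baseline-relaxed before
anything else sees them) and randomly perturbed (positions 0.02-0.12 A,
cell strain 0.5-3%), so the pool covers packed, near-minimum and distorted
geometries.  150 training structures per pair are selected by farthest
point sampling seeded at the lowest-baseline-energy structure; 100 test
structures per pair are then selected by FPS *including the training set*,
making the test set maximally dissimilar from the training data.  Intra
models train on up to 250 in-crystal monomer geometries per component
(labeled with the looser "crystal" noise class, since they can be strongly
strained) plus 40 perturbed gas-phase configurations at tight noise, which
anchors the fit in the gas-phase region the lattice-energy references
probe; 60 sparse points each.  The inter model trains on all 600 training
crystals' residual energy/force labels, plus rigid-molecule compressed
copies (scales 0.95/0.90/0.85 of every third training crystal, "compressed"
noise class — relaxations and barostats probe the compressed side of the
pool distribution, and a kernel model must see that region in training or
its extrapolation there is uncontrolled), plus the gas-phase monomers,
which anchor the no-neighbor limit where the correction must vanish; 600
sparse points.  Virial labels are supported but not used by the default
pipeline.  Held-out lattice energies use per-method gas references from
trust-region monomer relaxations (the delta model's own gas minimum for
the delta column, etc.).  Per-pair FPS quotas are run independently, one
pool per pair.

## Relaxation and dynamics

Variable-cell relaxation minimizes over atomic positions plus six symmetric
strain components (scaled by the cell length scale so both blocks carry
eV/A gradients) with L-BFGS-B; the strain gradient is the negative virial.
Strains are bounded (|eps| <= 0.3) so a bad line-search step cannot collapse
the cell, and calculator failures inside a line search return a large
energy sloping back toward the last accepted point, which makes the
optimizer backtrack rather than stall.  Convergence requires every force
component below `fmax` and, with cell relaxation, max |virial| / L below
`smax` (default `fmax/4`: soft molecular cells need a residual-stress
criterion tighter than the force one, or the converged density is sloppy).
An optional `max_displacement` box bounds each coordinate near its start —
used for gas-reference refinement, where a sparse-GP model far outside its
training data is meaningless.

Density comparisons between methods use `relax_volume`: a rigid-molecule
isotropic volume relaxation (scalar bounded minimization of the energy
over a cell scale factor, molecular centers of mass riding along) around a
reference produced by a positions-only relaxation under the target.  Two
deliberate restrictions make this the right probe.  Desk-scale random
packings are partly porous, and their pore-collapse modes carry forces
below any trained model's residual error, so a full 3N+6 relaxation hops
between packing basins and measures that noise instead of the density
response; and letting the cell shear during reference preparation drives
the smallest cell height onto the minimum-image validity wall, which pins
every method's volume optimum.  Fixing the (near-cubic) generated cell
shape and comparing scalar volume optima probes exactly the volumetric
energetics — which is what a density deviation is — deterministically and
cheaply, with the target's own optimum as the zero point.

The finite-temperature fixture (`npt_expansion_check`) anneals a dense
36-molecule trial crystal to its equilibrium packing with a hot,
pressurized NPT run, relaxes the final frame (full relaxation alternating
with the exact scalar volume relaxation, so the ultra-soft volume mode is
truly converged), and runs production NPT at 100 K / 1 bar from that
minimum; the large cell keeps the equilibrium packing's heights clear of
the minimum-image wall so the barostat samples freely.  Against that
reference, thermal expansion is a clean 2-3% signal.

NPT sampling couples a BAOAB Langevin integrator (default friction
0.02/fs, timestep 1 fs) to an isotropic Monte-Carlo barostat (log-volume
moves every 25 steps, molecular centers of mass rescaled with rigid
internal geometry, acceptance by the standard NPT criterion with the
molecular Jacobian).  Instantaneous temperature uses 3N kinetic degrees of
freedom; pressure is (2K + tr W)/3V.  Densities are reported as
block-averaged means (default: drop the first 20%, five contiguous blocks,
standard error from the scatter of block means).  Trajectories are
reproducible for a fixed seed on one platform; across platforms only
statistical equality is promised.

## Validation metrics

Lattice energy per molecule subtracts per-method optimized gas-phase
component energies and divides by the molecule count (single-component
crystals are the one-component special case).  Density deviations are
percentages relative to the reference density.  RMSD15 cuts a cluster of a
central molecule plus its 14 nearest neighbors (center-of-mass distance,
periodic images allowed) from both structures, seeds the correspondence by
superimposing the central molecules (all atoms, since small molecules may
have too few heavy atoms to fix a rotation), greedily matches molecules of
equal component type by center-of-mass distance, refines the assignment to
a fixed point, and reports the heavy-atom RMSD under the optimal *proper*
rotation (no inversion), minimized over candidate central molecules of the
reference.  The comparison requires both structures to decompose into the
same atom-index molecules, which is the relaxed-versus-reference use case.
MAE/STD statistics use the population divisor n, and force statistics are
computed on Cartesian components (zero-by-symmetry components retained).

## Numerical choices and limitations

- Bond perception: 1.2 x the sum of tabulated single-bond covalent radii,
  minimum image; an atom bonding to its own periodic image, or one pair
  bonding through two distinct images, raises rather than mis-partitioning.
- Component typing is element-labeled graph isomorphism without bond
  orders; isomers that differ only in bond order would collide.
- FPS ties break toward the lowest pool index; selection is fully
  deterministic given pool, seed and preselected set.
- k-point grids use the smallest n with n·a >= x per direction (default
  x = 30 A).
- Problem sizes of the bundled study (600/150/100 per pair, 6-molecule
  cells, 60/400 sparse points) were chosen as the smallest conditions under
  which the held-out improvement factors are stable run-to-run; the same
  pipeline accepts larger settings through `StudyConfig`.
- Known limitations: no uncertainty estimates, no marginal-likelihood
  hyperparameter optimization, no long-range ML terms (by design — the
  baseline owns long range), isotropic barostat only, and the toy universe
  caveats above.
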