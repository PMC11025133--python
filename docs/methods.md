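# Methods

`cgtribo` is a desk-scale toolkit for the coarse-grained modelling of
cationic-polysaccharide / anionic-surfactant boundary lubrication on
grafted biomimetic surfaces.  It covers four stages of that workflow:
bottom-up parametrization of harmonic bonded terms from (pseudo-)
atomistic trajectories, construction of molecules and confined systems,
a small molecular-dynamics engine able to squeeze and slide a confined
film, and the measurement layer (through-film profiles, film thickness,
hydration, coverages, friction-law fits, chain-size scaling).  This note
records the model, its assumptions, the tunable parameters, and the
numerical choices, in the order a user meets them.

## Units and functional forms

Internal units are GROMACS-style: nm, ps, amu, kJ/mol, elementary
charge, K.  The LAMMPS data-file writer converts to *real* units
(angstrom, fs, kcal/mol) on export.

Nonbonded interactions are 12-6 Lennard-Jones with polynomial
force-switching between `r_on = 0.9 nm` and `r_cut = 1.2 nm`: the pair
force on each `r^-p` term is ramped by a cubic/quartic polynomial chosen
so that force and its derivative vanish at the cutoff, and the energy is
the integral of that force (zero at and beyond the cutoff).  This is the
standard smooth-cutoff scheme of coarse-grained bead force fields; the
coefficients are derived from the two boundary conditions
`F(r_cut) = F'(r_cut) = 0` per power term.

Bonds and angles are harmonic.  Force constants are stored
*half-included*: `E = K (r - r0)^2` and `E = K_theta (theta - theta0)^2`
(the LAMMPS `harmonic` convention, with the textbook 1/2 folded into K).
The explicit-1/2 dialect is supported through a convention flag on the
parameter table; conversion is an exact factor of two.  The three-site
polarizable water uses two rigid 0.14-nm constraint bonds and a harmonic
satellite angle with `theta0 = 0 deg`, `K_theta = 2.1 kJ/mol/rad^2`
(half-included); satellites carry +-0.46 e.

Electrostatics are damped force-shifted Coulomb with a finite cutoff
(the Fennell-Gezelter construction; `alpha = 0` reduces to plain
shifted-force).  A uniform relative dielectric is configurable
(2.5 is the conventional value for the polarizable-water medium).
**This is the single largest fidelity compromise of the engine**: mesh
(Ewald/PPPM) summation is out of scope at desk scale.  Ion pairing and
counterion condensation — the qualitative electrostatic drivers of
polyelectrolyte-surfactant complexation — survive the approximation;
long-wavelength dielectric response does not.

## Boltzmann inversion

Mapped bead positions are mass-weighted centers of their member atoms,
computed with minimum-image unwrapping relative to the bead's first
member atom.  Bond/angle samples are pooled per type over frames and
instances, and harmonic parameters are obtained by Gaussian moment
matching of the Boltzmann distribution:

    r0 = <r>,    K = k_B T / (2 Var(r))        (half-included)

For angles the 3D equilibrium distribution carries a sin(theta)
geometric factor; samples are reweighted by 1/sin(theta) before moment
matching (`jacobian=True`, the default), so that the fitted potential is
the one whose Boltzmann factor generates the observed distribution.  No
equivalent deconvolution is applied to bonds (the r^2 volume factor
shifts the fitted r0 by `2 sigma^2 / r0`, about 0.2% at the default
stiffness — far below the 5% recovery tolerance; applying it would also
break the simple moment-matching contract).  Moment matching rather than
a least-squares fit of `-k_B T ln P` is used because it is noise-robust
and estimator-exact for the harmonic form; a histogram-potential view is
available for reporting.

Inversion temperature defaults to 300 K.  Histograms for reporting use
Freedman-Diaconis binning; fitting always uses the raw samples.

## Synthetic data

The fixtures module generates statistically controlled stand-ins for
cluster-scale inputs; all generators are deterministic in (spec, seed)
with per-item `SeedSequence` substreams, so adding one species or frame
type does not perturb the others.

* `gen_boltzmann_samples` draws from the plain Gaussian implied by the
  half-included harmonic Boltzmann factor.
* `gen_pseudo_atomistic_traj` grows a linear bead skeleton per frame in
  internal coordinates, with bond lengths drawn including the `r^2`
  volume factor and bending angles including `sin(theta)` (rejection
  against the Gaussian envelope), because these factors are present in
  real mapped atomistic statistics.  Member atoms are placed rigidly
  around each bead center with weighted-mean-zero offsets, so mapping
  recovers the skeleton to machine precision.  What the generator does
  *not* emulate: nonbonded correlations between beads, solvent drag, or
  any coupling between bonded degrees of freedom — a recovery test on
  this data validates the estimator chain, not atomistic force fields.
* `gen_confined_film_traj` produces layered films (uniform slabs or
  Gaussian layers) with linear-in-z Couette velocity plus Gaussian
  noise.
* `gen_friction_dataset` composes the two friction laws as
  `tau = (mu sigma + tau0) (v/v_ref)^alpha` with multiplicative
  lognormal noise, so that at `v = v_ref` the extended Amontons law
  holds exactly and at fixed sigma the log-log velocity slope is alpha.

## Builders

The cationic-guar chain defaults to 9 backbone beads per repeat unit
(three 3-bead sugar units); each functionalized repeat adds a P1
hydroxypropyl bead and a Q0 trimethylammonium bead (+1e) as a two-bead
side chain.  A degree of substitution DS in [0, 1] functionalizes
`round(DS * n_repeat)` monomers, by default uniformly at random without
replacement (regular spacing optional).  The backbone is laid down by a
self-avoiding random walk (default step 0.36 nm, minimum non-bonded
distance 0.30 nm, resampled steps with a retry cap); self-avoidance is
asserted post-build.  SDS is the standard four-bead model (three apolar
C1 tail beads, one Qa head, net -1e) with a hydrated Qd sodium
counterion; hydrated counterions are single Qd/Qa beads of 72 amu.

The grafted surface is a deliberately simplified stand-in for validated
biomimetic hair-surface models: a rigid square-lattice anchor sheet with
linear grafted chains at a prescribed density, an anionic fraction of
graft heads (0 = intact fatty-acid monolayer, > 0 = oxidized/bleached),
and +1e counterions restoring neutrality.  Graft base beads are tagged
for axis-restricted thermostatting during sliding.

Bulk assembly inserts molecules with uniform random rotations and
positions, rejecting placements within 0.3 nm (about the smallest bead
sigma) of existing beads; neutralization adds hydrated counterions so
the net charge is exactly zero in integer arithmetic.  Confined contacts
mirror a surface through the mid-plane; the mirrored anchor tag becomes
`upper_anchor`.

## Engine

Velocity-Verlet integration, default `dt = 5 fs`.  Thermostats:

* **Langevin** — an exact Ornstein-Uhlenbeck velocity update after the
  second half-kick (`v <- c1 v + c2 xi`, `c1 = exp(-dt/damping)`),
  which is unbiased in the kinetic temperature for any `dt` and reduces
  to pure exponential friction at `T = 0`.  Friction and noise can be
  restricted to a subset of axes and to a named bead group, as used in
  sliding runs (y-only, graft-base beads).
* **Nose-Hoover** — single-thermostat formulation with a 1-ps default
  damping constant, for equilibrium runs.

SHAKE iterates mass-weighted corrections along the pre-step constraint
directions until every constrained distance is within `1e-8 nm`
(configurable) of its target; RATTLE projects constraint-direction
components out of the velocities.  Both conserve linear momentum
exactly.

Nonbonded interactions use a Verlet pair list (skin 0.3 nm, rebuilt when
any bead has moved more than half the skin), with first bonded
neighbours, constraint partners and satellite pairs of the same rigid
molecule excluded.  Pair forces are accumulated with `bincount`
scatters; energies and forces of the switched LJ terms are evaluated
from fused per-pair coefficients `4 eps sigma^12`, `4 eps sigma^6`.

Confined runs freeze the lower anchor and drive the upper anchor as a
rigid body: constant sliding velocity along x, y fixed, and a single z
degree of freedom integrating the interaction force plus the applied
load `sigma * A` (equal per-bead distribution over the rigid sheet).  A
viscous term `-M v_z / damping` (default 5 ps) damps piston ringing; it
vanishes at steady state and therefore does not bias the transmitted
load, which is verified against `sigma * A` in the tests.  The log
records the anchor-sheet gap and the normal/lateral anchor forces.

A damped steepest-descent minimizer (displacement-capped, backtracking
step) relaxes hard-core overlaps left by random insertion before any
dynamics; this mirrors the conjugate-gradient pre-relaxation step of
production workflows.

Degenerate inputs: angle forces guard `sin(theta) >= 1e-8` (the
`theta0 = 0` water angle is regular because the torque prefactor
`delta_theta / sin(theta)` stays finite); zero pair separations raise an
integration error naming the pair; non-finite forces abort with the bead
index.

## Measurement layer

Profiles are time-averaged binned quantities along the surface normal,
default bin width 0.1 nm (fine enough to resolve bead-scale layering);
velocity bins never visited are NaN, not zero, and velocity profiles are
computed over mobile beads only.  Film thickness is the distance between
the 1% and 99% quantiles of the cumulative mass distribution (the extent
containing 98% of the species' mass), linearly interpolated inside bins.
Hydration is the water mass fraction inside that extent.  Coverages
count coarse-grained water *beads* and surfactant/polymer *molecules*
per unit lateral area (the bead convention for water matches how
hydration inventories are tabulated); charge ratios divide summed
anionic charges (surfactant, or surface grafts) by summed polymer
cationic charges, the surface ratio reported as a magnitude.

Shear stress is the time-averaged lateral reaction force on the driven
anchor divided by the lateral area, with a block-averaged standard error
(5 equal blocks).  The friction laws are fitted by ordinary least
squares: `tau = mu sigma + tau0` (extended Amontons; tau0, the Derjaguin
offset, unconstrained in sign) and a line in `(ln v_s, ln tau)` for the
velocity power law, over points with `v_s >= v_min`.  Rg-Mw scaling fits
`ln <Rg>` against `ln M_w` after averaging duplicate molecular weights.
The interdigitation overlap of two opposing density profiles is
`integral min(rho_lower, rho_upper) dz` on a common grid.

## Validation experiments and problem sizes

The composed experiments in `cgtribo.protocols` define the package's
validation conditions; sizes are chosen so each experiment runs in
minutes on one core while leaving the statistical tolerance it is tested
against attainable.

* **Closed-loop inversion** — 20,000 pseudo-atomistic frames of a
  6-residue chain are mapped and inverted; 8 non-interacting replica
  chains are then simulated bonded-only for 150,000 steps and their
  bond/angle distributions compared to the generating ones.  The overlap
  coefficient (integral of the minimum of the normalized histograms)
  exceeds 0.95 per type; residual mismatch is dominated by the
  `r^2`-factor bond-mean shift discussed above (~0.07 sigma) plus
  histogram sampling noise.
* **Couette shear** — a dense LJ fluid film (210 beads, 2.5 x 2.5 nm
  lateral, 5 nm gap) between rough single-layer walls (quenched
  positional jitter 0.1 nm, wall-fluid epsilon 8 vs fluid-fluid 4, so
  the boundary is no-slip), thermostatted in y only, driven at 100 m/s
  under 10 MPa for 150,000 steps.  The first fluid layer at each wall
  moves with its wall and carries the boundary velocities; the linear
  fit is taken over the sheared interior (one bead layer, 0.9 nm,
  excluded at each wall), as is conventional for extracting NEMD
  velocity profiles.
* **Ideal-chain statistics** — freely jointed chains (stiff harmonic
  bonds, b = 0.47 nm, no nonbonded terms), 64 replicas per length at
  N = 8-24, weak Langevin coupling (damping 10 ps) to keep conformation
  decorrelation fast, step counts growing with N^2.  `<Rg^2>` is
  compared to `b^2 (N^2 - 1)/(6 N)` pooled over lengths (single-length
  estimates carry ~1-2% standard error) and the scaling exponent to 1/2.
* **Excluded-volume chains** — the same chains with a repulsive-core
  pair interaction (epsilon 3.5, sigma 0.47, switch window 0.45-0.53 nm
  ending just past the LJ minimum, i.e. a good-solvent WCA-like core) at
  N = 8-32.  This is the desk-scale analogue of the full-model Rg-Mw
  scaling measurement; short chains measure an effective exponent
  between the Flory value 0.588 and the swollen short-chain regime
  around 0.6-0.65, to be compared with the reference 0.62 only at the
  scaled-down tolerance.
* **Confined-film protocol** — the full sequential workflow (grafted
  surfaces, adsorbed polyelectrolyte/surfactant/water film, squeeze at
  constant load, slide at constant velocity) at a few hundred beads.
  It exercises every code path of a production run; its outputs are
  checked for physical sanity (gap decreases under load, neutral
  charge, finite shear stress), not for production values, which are
  cluster-scale.

What passing these tests shows — and does not.  The synthetic fixtures
guarantee distributions, not physics: recovery and closed-loop checks
validate the estimator and integrator chain.  The toy films validate
momentum transport, load balance and the measurement layer.  None of
this reproduces production adsorption structures, squeeze-out
compositions or friction curves, which require orders of magnitude more
beads and time than a desk run.

## Known limitations

* Cutoff electrostatics (no mesh summation); uniform dielectric.
* No barostat: bulk boxes are fixed at builder-chosen sizes.
* Dihedrals are not implemented (the parent coarse-grained model omits
  them for stability).
* The grafted surface is a minimal stand-in; it reproduces anchoring,
  charge and graft-density effects, not the chemistry of validated
  hair-surface models.
* The repulsive top boundary for open adsorption runs is a one-sided
  harmonic wall of configurable stiffness.
* Single-core, NumPy-vectorized: practical up to a few thousand beads
  and ~10^6 steps; production scales need a parallel MD code.
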