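# Methods

`silkfric` rebuilds, at desk scale, the chain of analyses that turns
force-probe pulling data on a silk-like protein composite into an
interfacial coefficient of viscosity, and then uses that coefficient in a
small explicit-dynamics slider. This note records the models, their
assumptions, the tunable parameters, and the numerical and design choices,
in the package's own words.

## The composite structure

Dragline silk is a semicrystalline composite: stacked antiparallel
beta-sheet crystals of polyalanine (AAAAAAAA) embedded in a disordered
glycine-rich matrix (here the 24-residue repeat GPGGYGPGSQGPSGPGGYGPGGPG).
The builder produces the idealized geometry directly: two crystal units of
5 sheets x 5 strands (rise 0.35 nm/residue, strand spacing 0.48 nm, sheet
spacing 0.53 nm - standard beta-geometry constants, configurable), 3 nm
apart, with seven bundles of eight fully extended amorphous chains placed
symmetrically between and around them - 50 crystalline and 56 amorphous
peptides. Atoms are a coarse heavy-atom set (N, CA, C, O, + CB except
glycine) with Bondi radii; this is sufficient for the two geometric
consumers (surface areas and contact counts) and avoids a rotamer builder.
No energetics, hydrogens, or equilibration dynamics are modeled; the
entangled equilibrium state is emulated statistically downstream. Bundle
placement puts each bundle a configurable standoff (0.30 nm) from a crystal
face; an inter-body clash check (minimum atom distance 0.2 nm) guards the
placement. The builder is fully deterministic.

PDB I/O is a minimal fixed-width reader/writer: the composite has 106
chains (more than the PDB one-character chain column can name), so the
chain label lives in the segid field (columns 73-76) and the phase tag is
its first character (C = crystalline, A = amorphous). Coordinates are nm
internally and Angstrom on disk.

## Contact area and contacting residues

The solvent-accessible surface area is computed with the Shrake-Rupley
rolling-probe construction (probe 0.14 nm, the standard water radius) on a
deterministic golden-spiral point set - no RNG anywhere, so SASA values are
bit-reproducible for a fixed point count (default 960; total area at 960
points agrees with 4000 points to ~0.1% on the composite). A sample point
must lie strictly outside every neighbouring expanded sphere, so exactly
coincident atoms occlude each other; a body overlaid on itself is then
completely buried, which keeps the inclusion-exclusion identity exact.

The interface ("resistance") area is
`A = (SASA_amorphous + SASA_crystalline - SASA_combined) / 2`,
and a residue counts as contacting (`N`) when it buries more than
0.01 nm^2 (configurable) of its isolated SASA in the complex; residues of
both bodies are counted, which keeps `contact_area(X, Y)` exactly
symmetric. For the default composite this gives A ~ 6.3 nm^2 and N = 232.
A list of frames can be supplied, returning mean +- SD; the default is the
single built frame.

## The washboard bond-friction model

A residue sliding over the crystal surface sees a periodic corrugation of
lattice constant `a` whose wells are adhesive bonds of strength `U_bond`
(in kT); `m` bonds rupture cooperatively. The collective coordinate is an
overdamped particle in a tilted cosine washboard of period `a`,
peak-to-trough depth `m U_bond kT`, and bare friction `m xi0` (xi0 is the
background per-residue friction, default 1e-12 Ns/m, the bulk-water
per-residue scale). The steady-state Fokker-Planck (Stratonovich) solution
gives the mean drift velocity at a given force; `force_velocity` inverts it
to the mean friction force per residue at prescribed sliding speed.

Observables depend on the parameters only through the products `m a`
(tilt) and `m U_bond` (depth), so fits report the product `ma`, mirroring
the two published fit families: hold `U_bond = 8.4` and fit `ma`, or hold
`ma = 1.32 nm` and fit `U_bond`.

Two independent evaluation routes guard against algebra errors:

* the production closed form: the Stratonovich double integral reduced
  analytically to the Bessel series
  `S(f, z) = sum_n eps_n (-1)^n I_n(z)^2 f/(f^2+n^2)` with
  `f = beta F a/(2 pi)`, `z = m U_bond/2`, and `v = (2 pi D/a)/S`;
  inversion by vectorized geometric bisection between the exact
  free-draining (`xi0 V`) and viscous (`xi0 I0(z)^2 V`) brackets;
* an oracle evaluating the same double integral by direct 2D quadrature
  (spectral trapezoid in the periodic variable, composite Gauss-Legendre
  with an exponential-scaled variable in the other) and bracketed root
  finding, converged to ~1e-6 and cross-checked at two resolutions.

The two routes agree to ~1e-11 relative over U_bond in [0, 12], ma in
[0.5, 2] nm and five decades of velocity; a third, stochastic route
(overdamped Brownian dynamics at fixed force) is checked in the tests at 3
SEM. Known limits hold exactly: zero corrugation gives `F = xi0 V`; the
low-velocity limit is the Zwanzig amplification `xi_visc = xi0 I0(m
U_bond/2)^2` (used in closed form by `viscous_limit`, never by naive
division); the force is odd and strictly increasing in V. The series
suffers catastrophic cancellation only for depths beyond ~30 kT, far
outside the regime used here.

Viscosities follow Newton's law of shear viscosity: with the shear gap
`d_shear` (default: the lattice constant `a`; the convention is ours and
configurable) the viscous-limit interface coefficient is
`eta = xi_visc N d_shear / A`.

Parameter presets `interface` and `amorphous` anchor the two published
viscous-limit viscosities (2e2 and 1e4 Ns/m^2, a ~50x ratio): with
`U_bond` and `ma` fixed at their reference values, the cooperativity `m` is
solved so that the model's viscous limit, combined with the builder
composite's own contact geometry (N/A = 36.9 residues/nm^2), reproduces
those numbers. This is a consistency anchor for the synthetic truth, not a
recomputation of any atomistic result.

## Synthetic pulling traces

The generator replaces force-probe MD with an overdamped Langevin model of
one effective bundle coordinate (the pulled center of mass; internal chain
elasticity is not modeled because only peak forces are consumed
downstream). A harmonic spring (830 pN/nm per bundle, 7 bundles, i.e.
5.81 N/m total) moves at constant velocity V in 0.02-20 m/s; the bundle
feels water drag `N_total xi_w u` on all pulled residues, the washboard
bond force on the `N` contacting residues (tabulated once per truth on a
700-point log grid, solved per step by safeguarded Newton), and thermal
noise at 300 K.

Noise model: thermal fluctuations are linear response about the
deterministic pull trajectory, with the local differential friction
`xi_d = dPhi/du` setting both the relaxation and the noise amplitude
(fluctuation-dissipation; for water-only pulls the spring-extension
variance is exactly kT/k). The deliberate refinement over feeding the
noisy instantaneous velocity through the full nonlinear friction law is
documented here because it matters: the instantaneous-speed variant
rectifies the concave force law by ~0.5% at the lowest velocities (where
velocity fluctuations reach ~30% of V), which is an emulator artifact
rather than washboard physics and visibly biases parameter recovery.

Contact history: contact stays at full `N` while the bundles cover the
crystal, then decays linearly to zero over `detach_length` (2.8 nm, the
8-residue crystal length along the pull), after which the trace ends - a
pull "stopped after detachment". The constant-contact plateau is held for
400 force-autocorrelation times (`xi_d/k`) before the detachment window so
the recorded plateau supports an unbiased steady-force estimate; the
equilibration ramp up to 99.5% of the drive velocity is integrated but not
recorded, as in routine trace post-processing. Replicas differ through
thermal noise and the stochastic detachment onset only.

Time step: the only stiff explicit term is the spring, stable for
`dt < 2 xi/k`; accuracy requires resolving the force-noise correlation
time `xi_d/k` (~30 steps) and the washboard period at the drift speed.
`dt = min(0.03 xi_d/k, 0.05 a/V, 0.3 xi_min/k)`; halving dt moves the
plateau estimate by less than a replica SEM. Traces are recorded at
<= ~4000 samples; a full campaign (7 velocities x 4 replicas x 2 kinds)
takes ~1 s.

## Extraction and fitting

The peak force of a trace is the maximum of the running-mean-smoothed
force. The default window is plateau-scaled: water-only traces (no
detachment transient) use the full record - a single selection-free window
whose maximum is the plateau mean; traces with detachment use a window
reaching to the detachment drop, located by a coarse running mean, so any
window shifted into the decay is deterministically penalized and the
maximum stays pinned to the plateau. A short extreme-value window (the
obvious alternative) carries a positive bias comparable to its own
replica scatter at every window length, which would defeat 2-SE coverage
of the recovered parameters; explicit time windows remain available.

Per velocity: replica mean and SEM for total and water-only peaks,
`F_ac = F_total - F_water` with SEMs combined in quadrature (the paper's
error propagation is not stated; quadrature is the standard choice),
`f_res = F_ac/N` (the friction force is taken as equally shared by the
contacting residues), `tau = F_ac/A` (pN/nm^2 = MPa), and the apparent
per-residue viscosity `eta_res(V) = (f_res/V) d_shear/A_res`.

The water law `F_w = N_total xi_w V` is fitted by zero-intercept weighted
least squares (no drag at V = 0). Bond-model fits minimize the SEM-weighted
chi^2 of `force_velocity` against `f_res(V)`; parameter errors are
Delta-chi^2 = 1 profile half-widths (the model is strongly nonlinear in
U_bond), inflated by the standard scale factor sqrt(chi2/dof) when the fit
scatters more than the stated uncertainties. Because four-replica SEMs
have only 3 degrees of freedom, weights use SEM shrinkage: each SEM is
floored at 1.2x the cross-velocity median relative SEM (a freak agreement
of four replicas must not dominate the fit). Calibration by simulation:
over 100 synthetic campaigns at the default truth, the +-2 SE intervals
cover the true `ma`, `U_bond`, and `xi_w` in >= 90% of runs (typically
92-100%). Noiseless (zero-temperature) campaigns recover all generator
parameters to three significant figures.

## The slider

A 2D plane-strain reduction (bilinear quads, 2x2 Gauss, lumped mass,
central difference): an elastoplastic crystal block (J2 radial return,
bilinear mixed isotropic/kinematic hardening) slides over a viscoelastic
amorphous plate (elastic bulk response; deviatoric relaxation
`G(t) = Ginf + (G0-Ginf) e^{-beta t}` by recursive exponential
integration). Material cards are presets in the range of prior silk-phase
models (crystal E = 25 GPa, sigma_y = 2 GPa, E_t = 2.5 GPa; amorphous
K = 4 GPa, G0 = 1.5 GPa, Ginf = 0.15 GPa, beta = 1e9/s; density 1300
kg/m^3) - the classes of behaviour matter here, not the exact numbers, and
all are overridable.

The bodies never share nodes. The film transmits a Newtonian tangential
traction `tau = eta dv/h` between facing surfaces plus a normal penalty
(stiffness ~0.3 (K+E)/h_elem, with a penetration deadband of 1% film
thickness so picometre elastic bulges at the traction edges are not
amplified). Because the film's damping rate c/m is ~1e18/s, the tangential
coupling is integrated implicitly: each contact pair's relative velocity
follows an exact exponential (OU) update with the explicit forces as a
constant source, relaxing in the stiff limit to the force-balance sliding
speed - this reproduces the rigid-limit Couette traction `eta V/h` (to 1%
with a kinematically driven block), which a plain implicit decay would
not. With the default cards the film is effectively "stick": the interface
transmits whatever stress the materials can sustain, so reported stresses
grow with velocity through the materials' rate dependence, mirroring the
qualitative published structure (negligible stresses below ~1 m/s for
horizontal pulling; substantial stresses at low velocity once the pull is
inclined 10 degrees into the plate).

Boundary conditions: the block's top face (or, for verification runs, the
whole block) is driven at the prescribed velocity, tilted into the plate
by `load_angle`; the plate base is fully fixed by default. A base that is
tangentially free (one literal reading of the original restraint
description) cannot sustain steady sliding at the nanometre scale - the
plate co-moves within femtoseconds - so that reading is kept only as the
`plate_base="normal_only"` option. Optional mass-proportional damping
quiets elastic ringing in quasi-static verification runs.

Energy bookkeeping pairs every impulse with the same midpoint velocity
that carries it into the kinetic energy, so
`external work = kinetic + material work + film dissipation + penalty +
damping` closes to machine precision by construction; the film dissipation
term is non-negative at every step. Constrained dofs never integrate
momentum. Known limitation: at artificially extreme (x1e6) moduli the
foot-node interpolation drifts bias the film traction over multi-ps
horizons; rigid-limit verification uses the ~1 ps window accepted by the
steady-state detector. Physical-card runs are unaffected.

## What the synthetic data does and does not show

The generator emulates the statistical structure the extraction assumes:
peak forces that estimate steady friction at each velocity, replica
scatter from thermal noise and detachment timing, a linear water
background, and a bond-friction contribution that follows the washboard
model exactly. Passing recovery tests therefore demonstrates that the
extraction-and-fitting chain is unbiased and correctly calibrated for data
of this structure - not that real pulling data obey the washboard model,
and not the published absolute force values, which derive from undeposited
atomistic trajectories. The interface/amorphous preset viscosities (2e2
and 1e4 Ns/m^2) are calibration anchors, so pipeline outputs reproducing
them are consistency checks, not independent measurements.

## Reduced problem sizes

Defaults are chosen so the full chain runs on a laptop: SASA at 960 sphere
points, pulling plateaus of 400 correlation times (~1 s per campaign),
slider meshes of ~100 elements at 0.2-2 ns duration. The analysis scripts
state the sizes they use; all are configurable upward.
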