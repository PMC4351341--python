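# Methods

## The method in brief

`adbfsim` implements adaptive buffered force mixing for two-resolution
molecular dynamics.  Two force models describe the same system: an
"accurate" model A (the stand-in for a QM engine) and a cheap model B
(the stand-in for an MM force field).  At every step the system is
partitioned into four nested regions — core ⊆ dynamical QM ⊆ (dynamical
QM ∪ buffer), remainder MM — and two composite evaluations are run: an
*extended* one whose A-region is the dynamical QM region plus the buffer,
and a *reduced* one whose A-region is just the core (possibly empty, in
which case it is a plain model-B call).  The dynamical forces are then
selected abruptly per atom,

    F_i = F_i^extended   if i ∈ dynamical QM (incl. core)
    F_i = F_i^reduced    otherwise,

with no interpolation region.  The buffer exists only to push the
A/B interface error away from the atoms whose extended forces are
actually used; its own forces are discarded.  Setting the radii
appropriately recovers the other adaptive variants: a single evaluation
with core = dynamical QM and no buffer is adaptive conventional coupling
(AdConv), force mixing with an empty buffer is the unbuffered variant
(AdUF), and all radii zero is conventional fixed-region coupling (Conv).

Because the mixed force field is not the gradient of any total energy,
two consequences follow and are handled explicitly:

* the net force does not vanish; a momentum correction subtracts it each
  step (mass-weighted over all atoms by default; uniform weighting and
  region-restricted variants are config options);
* energy is not conserved, so the dynamics must be thermostatted by a
  thermostat that can absorb a steady, spatially localized heat flux.

## Regions and hysteresis

Each region is a fixed user list plus atoms selected by distance from a
reference set (fixed core for the core, current core for the dynamical QM
region, current dynamical QM region for the buffer).  All cutoffs are
hysteretic: an atom enters a region when it comes within `r_in` and
leaves only beyond `r_out >= r_in`, which suppresses membership flicker
for atoms hovering near a boundary.  For water-like systems the
selection is applied to heavy-atom (O–O) distances only, and whole
molecules are promoted to the innermost label any of their atoms
reached, after all three selections — selection never cuts a molecule.

Two details the construction leaves open were fixed as follows and are
relied on by the tests: the "previously a member" test of the hysteresis
uses the previous step's *post-promotion* labels, and previous
membership in any inner region counts as previous membership in an outer
one (an atom that was core last step is inside the dynamical QM region's
memory too).  Distances are always measured against the current step's
reference sets, matching the sequential construction order.

## Toy force models and the mismatch dial

A water-like molecule is 1 heavy + 2 light atoms with harmonic bonds
(k_b = 450 kcal/mol/Å², b₀ = 1.0 Å) and a harmonic angle (k_θ = 55
kcal/mol/rad², θ₀ = 104.52°).  Molecules interact through a
shifted-force 12-6 Lennard-Jones term between heavy atoms (ε = 0.20
kcal/mol, r_min = 2.95 Å, r_cut = 6.5 Å) and a shifted-force Gaussian
attraction between heavy and light atoms of different molecules
(ε = 0.75 kcal/mol at 1.9 Å, width 0.28 Å), which plays the role of
hydrogen bonding and gives the liquid a structured first neighbour shell
(g(r) peak ≈ 3 at ≈ 2.7 Å at 300 K and 0.0334 molecules/Å³).  No
fidelity to real water thermodynamics is intended — the liquid only
needs a discernible first shell for the structural analyses to probe.

Model A is derived from model B by scaling every *intermolecular* well
depth and length parameter by (1 + δ).  δ = 0 makes the two models
bitwise identical; δ > 0 gives model A a deeper, longer-ranged, larger-
molecule liquid, i.e. a controlled chemical-potential mismatch across
the A/B boundary.  In a composite evaluation a pair interaction uses A's
parameters iff both atoms are in the QM set; intramolecular terms use A
iff the whole molecule is.  This "both-in ⇒ A, else B" rule concentrates
the error exactly at the boundary, which is the error structure buffered
force mixing is designed to bury.

Because pure-model and composite evaluations run through the same
kernel (with per-pair parameter selection), a δ = 0 composite is bitwise
identical to a single-model call; the variant-identity test exploits
this to demand *exactly* coinciding trajectories, not approximately.

## Adaptive thermostats

The adaptive Langevin thermostat couples, per Cartesian degree of
freedom ("massive" coupling),

    dq = (p/m) dt
    dp = F dt − (χ + γ) p dt + √(2 γ m k_B T) dW
    dχ = (p²/m − n k_B T)/Q dt,    Q = n k_B T τ_NH²,  n = 1,

i.e. a Langevin thermostat (friction γ = 1/τ_L, guaranteeing ergodicity)
in parallel with a Nosé–Hoover control variable χ that drifts until the
effective friction χ + γ dissipates exactly the nonconservative heat.
The chain variant replaces the direct Langevin coupling on p by a
Nosé–Hoover chain ξ₁…ξ_r whose last element is optionally
Langevin-thermalized (r = 1: adaptive NH–Langevin; γ_l = 0, r > 1:
adaptive NH chain).  The equations of motion are implemented from this
structural description; the normative contracts are the limits (γ = 0 ⇒
deterministic NH dynamics; χ frozen ⇒ plain Langevin) and the stationary
statistics, which the tests check: canonical ⟨q²⟩, ⟨p²⟩ on harmonic
oscillators to <2%, and under a constant injected heating rate a
steady ⟨χ⟩ > 0 with the kinetic temperature held at T while a frozen-χ
control run overheats by the full injected fraction.

Discretization is a symmetric BAOAB-style splitting: half kick, half
drift, thermostat part, half drift, half kick, with the
Ornstein–Uhlenbeck step integrated exactly at the instantaneous friction
(fluctuation–dissipation applied to the γ part only) and the χ coupling
as symmetric half-updates around it.  The exact OU step avoids a
dt-dependent temperature bias; the per-DOF state arrays make the
coupling massive by construction.  Default time constants ship as two
presets, τ_L = τ_NH = 200 fs and τ_L = 300 fs / τ_NH = 74 fs, matching
the two coupling regimes used in the validation scenarios.  Units
throughout: Å, fs, amu, kcal/mol, k_B = 1.9872×10⁻³ kcal/mol/K; the
single conversion constant is 1 (kcal/mol/Å)/amu = 4.184×10⁻⁴ Å/fs².

## Simulation loop

Per step: partition (every step by default; a cadence option exists),
extended + (if the variant requires) reduced evaluation, abrupt mixing,
restraint/bias forces, momentum correction, thermostatted integration.
Restraints and bias are added *before* the momentum correction — the
bias is part of the dynamical force field and the correction must see
the total.  The default time step is 0.5 fs.  Runs are bit-reproducible
for a fixed seed; all random streams derive from `numpy` generators
seeded from the config.

## Collective variables and umbrella integration

Two reaction coordinates are provided with analytic gradients: the
difference of rational coordination numbers (DRCN) of an acceptor and a
donor oxygen over a set of transferable hydrogens, with switching
function n(r) = (1−(r/r₀)^α)/(1−(r/r₀)^β), α = 6, β = 18, r₀ = 1.6 Å
(the removable point r = r₀ is evaluated by series expansion within
|r/r₀ − 1| < 10⁻⁴, giving the limit α/β), and the distance difference
DD = d(O_leaving, P) − d(O_attacking, P).  The hydrogens entering the
DRCN sums are an explicit list (by default the reactant hydrogens),
configurable because the physically relevant set is the transferable
protons.

Free-energy profiles use umbrella integration: each window holds the
coordinate with a harmonic bias (k/2)(x − x₀)², the mean bias gradient
gives the local PMF slope dF/dx|_{x̄} = −k(x̄ − x₀), and the per-window
slopes are integrated along the coordinate, anchored at F(anchor) = 0.
The default quadrature integrates a cubic-spline interpolant of the
window slopes.  A plain trapezoid rule is available but deliberately not
the default: at a typical window spacing of 0.25 in the coordinate, the
gradient of a barrier profile is strongly curved between windows and the
trapezoid rule carries a systematic barrier bias of order 0.3 kcal/mol
on the analytic double-well benchmark, an order of magnitude above the
spline's, at identical statistical cost.  A second-order
Gaussian-variance (Kästner–Thiel) gradient correction is available
behind a flag but is not default.  Window-mean uncertainties come from
block averaging; profile confidence bands from propagation or from a
block bootstrap (default for the CI helper, labelled in its output).
Steered schedules move the restraint centre linearly between windows and
hold for the sampling period, with per-window equilibration dropped
(≈ 18% of the window by default in the benchmark studies).

## Synthetic systems

All inputs are generated: molecules are placed on a jittered cubic
lattice at the target density (default 0.0334 molecules/Å³) with random
orientations, relaxed by a short displacement-capped descent under model
B, and given Maxwell–Boltzmann velocities.  Solute embedding removes
overlapping solvent molecules whole and tags the solute as the default
fixed core.  What the generator deliberately does *not* emulate:
electrostatics, polarization, realistic hydrogen-bond networks, NpT
density relaxation.  Passing tests therefore demonstrate the adaptive
*machinery* — region algebra, force mixing, momentum bookkeeping,
thermostat response, estimator correctness — on a liquid with realistic
geometry and diffusion, not the chemistry of any real QM/MM pairing.

## Validation studies and problem sizes

The `studies` module fixes the scenario battery run by
`scripts/acceptance.py` and the heavier tests; sizes were chosen so the
whole battery completes on one CPU in well under half an hour:

* **Variant identity** (δ = 0): 24 molecules, 1000 steps, all four
  variants against single-model MD; identical trajectories expected to
  the bit, asserted at 10⁻⁸ Å.
* **Momentum conservation**: AdBF, δ = 0.3, 40 molecules, 1000 steps;
  |ΣF| ≤ 10⁻¹⁰ kcal/mol/Å after mass-weighted correction on every step.
* **Hysteresis**: 50-molecule rigid-molecule random walk, 10⁴ steps,
  relabelled with (4.0, 4.5) vs. (4.25, 4.25) Å O–O radii; switch events
  ≈ 150 vs. ≈ 2000.
* **Thermostat sampling**: 384 independent harmonic DOFs × 2×10⁴ steps
  (≈ 2×10⁶ samples, τ_L = τ_NH = 20 fs, dt = 0.05/ω); heating test with
  an injected kick worth 25% of the thermal Langevin variance.
* **Umbrella integration**: one particle in U = a(x² − 1)², a = 5
  kcal/mol, steered through 13 windows x₀ ∈ [−1.5, 1.5], k = 400
  kcal/mol, 3.6×10⁴ hold steps per window; barrier F(0) − F(−1) within
  0.25 kcal/mol of the exact profile.
* **Boundary instability**: δ = 0.5, 150 molecules, r_qm = 3.0–3.5 Å;
  the buffer radii (4.0–4.5 Å) are chosen by the method's own protocol —
  the smallest radii at which the pre-production force-convergence scan
  puts the mean force error on dynamical-QM atoms below 2 kcal/mol/Å.
  8000-step runs; cumulative neighbour counts at 3.5 Å around the
  central molecule, referenced to a fully-model-A run of the same box.
  The undersized 3.0–3.5 Å buffer (mean force error ≈ 5 kcal/mol/Å)
  leaves visible residual depletion in the AdBF arm, which is precisely
  the behaviour the convergence-test protocol exists to prevent.
* **Buffer scan**: 6 equilibrated 150-molecule configurations, δ = 0.2,
  non-hysteretic buffers 1–6 Å against a 7.5 Å reference; the δ = 0 and
  self-reference error identities hold exactly.

## Numerical choices and degenerate inputs

* Shifted-force potentials: energy and force both go continuously to
  zero at the cutoffs, so region changes never create discontinuities
  beyond the intended mixing ones.
* Minimum-image distances assume orthorhombic cells and no interaction
  range beyond half the smallest periodic edge; the RDF enforces
  r_max ≤ L/2 explicitly.  Selection distances use direct O(N²)
  evaluation — adequate at the ≤10³-atom scale this package targets; the
  distance API is isolated so a neighbour-list backend could be swapped
  in.
* An empty core is allowed; the reduced evaluation is then a pure
  model-B call.  An empty selection reference simply yields an empty
  adaptive selection.
* The angle gradient guards sin θ ≥ 10⁻⁸; coincident atoms in distance
  CVs raise rather than return garbage.
* Blow-ups (non-finite positions or forces) abort with the step index.

## Known limitations

* No electrostatics, Ewald summation, electrostatic embedding, or
  bond-cutting across region boundaries; molecules are the indivisible
  selection unit.
* The mixed-force energy is undefined; only PMF-type free-energy methods
  apply (by design of force mixing).
* The NHC-Langevin integrator is validated at the level of stationary
  statistics, not per-step agreement with any particular reference
  integrator's trajectory.
* At 150 molecules the extended region with the convergence-chosen
  buffer approaches half the box edge, so the MM far field is thin;
  conclusions about the *magnitude* of residual AdBF structural error at
  strong mismatch are box-size limited (the AdUF/AdBF contrast is not).
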