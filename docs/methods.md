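# Methods

`pnnbrush` simulates a single tracer particle diffusing through a planar
brush of charged, semi-flexible bead-spring polymers tethered to a
repulsive wall — a minimal model of the perineuronal net (PNN), the
glycosaminoglycan-rich extracellular matrix that wraps certain neurons —
and analyzes the resulting trajectories for anisotropic diffusion
constants, brush structure, tortuosity-model fits and electrical
transport. This note records the model, the estimators, the numerical
choices, and what the desk-scale defaults do and do not demonstrate.

## Model

One coarse-grained bead represents one disaccharide unit of hyaluronan or
unsulfated chondroitin: length σ = 1 nm, charge −e, unit mass. Chains of
N = 101 beads are tethered to a neutral substrate through two immobile
beads (at z = σ and 2σ) on an n×n square grid of spacing d (default 3×3).
The substrate is a dense lattice of immobile neutral beads at z = 0 with
~1σ spacing, dense enough that its excluded volume blocks passage; the box
is periodic in x and y with L = n·d, and open above. A single unbonded
tracer of radius a (default 0.5σ, charge q ∈ {0, ±e, …}) is inserted near
the wall, uniform in (x, y) with z ∈ [2σ, 5σ], overlap-rejected.

Interactions (reduced units, energies in ε_E):

- **Excluded volume** — 12-6 Lennard-Jones, ε_LJ = 0.73 (from the 0.15
  kJ/mol carbon–carbon parameter of GAG coarse-graining), truncated at its
  minimum r_min = 2^(1/6) σ_pair and energy-shifted to zero there (WCA
  form, athermal/good solvent). The shift changes only the energy
  bookkeeping, never the forces. Pair diameters mix arithmetically, so a
  tracer of radius a sees a cutoff 2^(1/6)·(σ + 2a)/2.
- **Stretching** — harmonic, u = K_bond (r − r₀)², K_bond = 140.2,
  r₀ = 1σ.
- **Bending** — harmonic in the bead angle, u = K_bend (θ − π)²,
  K_bend = 14.02, giving a persistence length of 10 nm (below).
- **Screened electrostatics** — Debye–Hückel, u = A q_i q_j e^(−κr)/r,
  with screening length 1/κ = 1 nm (brain interstitial fluid) and cutoff
  3σ. The prefactor A is the physical Coulomb energy of two unit charges
  at 1 nm in water (ε_r ≈ 80), expressed in the model's energy unit:
  A ≈ 8.45 ε_E·σ, independent of the reduced temperature. (A
  Bjerrum-length parameterization A = kT·l_B is available but, at the
  calibrated kT, gives a contact coupling of only ~0.26 kT — too weak to
  produce any of the charge-dependent transport this model exists to
  study.) At kT = 2.804 ε_E the default coupling is ~1.1 kT at contact.
- Nonbonded terms are excluded between beads up to three bonds apart on
  the same chain (1-2, 1-3, 1-4), the convention of bead-spring MD codes;
  connectivity is carried entirely by the bond and angle terms.

Solvent is implicit: mobile beads follow the Langevin equation
m dv/dt = F − γv + B(t) with per-bead friction γ (default 1 m/τ for chain
beads). The tracer's friction scales with its radius (Stokes, γ ∝ a) and
its mass with volume, relative to the 0.5σ chain bead, which preserves
the D = kT/γ ∝ 1/a bulk law across tracer sizes.

Four system types: **dynamic** (chains and tracer integrated), **static**
(chains equilibrated, then frozen for the production), **straight**
(perfectly vertical frozen chains) and **no-stiffness** (dynamic with the
bending term removed).

## Reduced units and temperature

σ, the bead mass, and ε_E define the unit system; τ = σ√(m/ε_E). The
reduced temperature is kT = 2.804 ε_E, chosen so that the discrete
worm-like-chain relation l_p ≈ 2 K_bend r₀ / kT reproduces the calibrated
l_p = 10 nm exactly. (Mapping kT through the physical value of ε_E would
instead give kT ≈ 12.5 ε_E and l_p ≈ 2.2 nm; the stiffness calibration is
taken as authoritative.) For statements in physical time we assign
m = 400 g/mol per disaccharide and ε_E = 0.15/0.73 kJ/mol, giving
τ ≈ 44 ps; with γ = 1 m/τ this maps the bulk tracer diffusivity to
~6×10⁻⁸ m²/s, an order of magnitude above physiological ionic
diffusivities. This is a known consequence of using a computationally
feasible friction rather than the physical Stokes drag (γ_phys ≈ 560 m/τ,
which would make tracer displacements unmeasurably slow at desk scale);
quantities proportional to absolute D (conductivity, resistance,
traversal times) therefore carry this scale factor and are interpreted at
order-of-magnitude level only.

## Integration

BAOAB splitting of the Langevin equation: half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity update (c₁ = e^(−γΔt/m), noise variance
kT(1−c₁²)/m — discrete fluctuation–dissipation holds exactly), half-drift,
force evaluation, half-kick. At γ = 0 the scheme reduces to velocity
Verlet and conserves the shadow energy (drift < 10⁻⁴ over 10⁴ steps in
the test suite). Δt = 0.005τ, ≥ 75 steps per bond vibration period
(ω = √(2K_bond/m) ≈ 16.7/τ). Equilibrations open with 500 steps at Δt/5
so residual close contacts in the initial configuration relax gently.

Forces use a Verlet pair list built brute-force over (mobile, any) pairs
within max-cutoff + skin (0.5σ; 1σ when fewer than ten beads are mobile),
refreshed when any mobile bead has moved half a skin; the jitted kernels
are verified pairwise-exactly against a plain-NumPy O(N²) reference.
Immobile beads (wall, tethers, frozen chains) exert forces but are never
integrated. Positions are kept unwrapped; the minimum image in x, y is
applied inside every distance evaluation.

Randomness: a `numpy` PCG64 generator per realization, seeded through
`SeedSequence([base_seed, index])`; trajectories are bit-reproducible for
a given seed.

## Initial configurations

Chains start either near-vertical with a small seeded jitter (the default
contract) or, optionally, as equilibrium discrete worm-like-chain samples
("wlc" mode, used by the sweeps): bead angles drawn from the Boltzmann
density ∝ e^(−βK(θ−π)²) sin θ, uniform azimuths. WLC candidates are
rejected if they approach the wall, self-overlap, or come within 0.9σ of
already-placed chains; if any chain cannot be placed (dense brushes), the
whole system falls back to the near-vertical start, which is closest to
the dense-brush equilibrium anyway. This equilibrium initialization is
what makes short equilibrations sufficient in the mushroom regime, where
relaxing a vertical rod to a coil would otherwise take Rouse-scale times
(~10² τ).

## Estimators

**Dual MSD.** Two ensemble curves from the production origin: over all
realizations, and over realizations whose tracer has remained inside the
brush — defined as tracer z not exceeding the instantaneous maximum
chain-bead z of its own realization — up to that time (exit is absorbing
for the bookkeeping). D_∥ and D_⊥ come from straight-line fits
⟨Δx²+Δy²⟩ = 4D_∥t and ⟨Δz²⟩ = 2D_⊥t.

**Fit window.** The earliest decade-wide interval, starting after frame
20, on which (i) the local log-log slopes of the all-realizations and
in-brush curves agree within 10%, (ii) each slope lies in [0.7, 1.3]
(diffusive — this excludes the ballistic/inertial transient), and
(iii) the in-brush ensemble is not depleted. Local slopes are windowed
regressions over ±0.5 in ln t, which stay usable on small-ensemble
curves; a window is accepted when its ends are valid and ≥80% of its
interior is. If no decade qualifies, the longest valid stretch (≥5
frames) is used; if none exists the fit fails explicitly.

**Errors.** The ensemble is split into ten equal groups (mirroring the
groups-of-100 procedure at full scale); mean ± std over the ten group
fits.

**Structure.** R_g per chain about its center of mass, averaged over
chains and realizations at the final frame; brush height L_z as the mean
maximal chain-bead z; correlation length ξ as the mean distance from a
chain bead to the nearest bead of another chain (KD-tree over periodic
images; exact against the O(N²) reference). The brush/mushroom boundary
is d = 2⟨R_g⟩.

**Persistence length.** ⟨cos θ(s)⟩ between bond vectors s bonds apart,
fitted as log ⟨cos θ(s)⟩ vs s over s ∈ [1, 3·l_p⁰] (l_p⁰ from s = 1).
Points are weighted by the inverse scatter of C(s) across independent
chains when block structure is available, otherwise by the nominal
counting precision; the large-s tail is noisy (slow conformational
decorrelation) and is correspondingly down-weighted. The calibration runs
a *phantom* chain (stretching + bending only): this is the ensemble the
discrete-WLC relation describes, and the independent quadrature oracle
(⟨cos θ⟩ under the Boltzmann bend density) confirms l_p = 10.2σ at
βK_bend = 5. With the WCA repulsion switched on, self-avoidance flattens
C(s) at large s and the apparent l_p rises to ~13σ; the `excluded_volume`
switch exposes this.

**Energy statistics.** Per production frame: the tracer's nonbonded
interaction energy, the fraction of frames with any interaction (a pair
within cutoff), the mean energy conditioned on interacting — the
unconditional mean equals their product by construction — and the chain
beads' half-share nonbonded energy. Because the LJ term is WCA-shifted,
absolute contact energies sit +ε_LJ above the unshifted convention.

## Transport models

Porosity treats beads as spheres of radius a_f:
φ = 1 − (4/3)π a_f³ N_bead/(d² L_z), with L_z the *simulated* height at
each d. Tortuosity families map φ to D_eff/D_bulk = 1/τ²: hyperbola of
revolution (τ² = 2−φ), ordered packings ((3−φ)/2), heterogeneous catalyst
(φ/[1−(1−φ)^⅓]), cation-exchange resin (τ = (2−φ)/φ), and the
generalized lattice-walk model τ = 1 + p_first/(1−p_next) with
p_first = 1−φ and p_next = k + (k−1)(1−φ); at p_next = (2−φ)/2 the
generalized model reduces identically to the cation-exchange-resin form.
A d power law D/D_bulk = 1 − d^(−n)/c is provided as a heuristic
alternative (the typeset source form is ambiguous between this and
1 − c·d^(−n); the latter is available behind `alt_power_law`).

Fitting: tortuosity families leave a_f free (Levenberg–Marquardt) — since
none of them was derived for a brush, a_f acts as an effective obstacle
size, and good fits push the formal φ below zero; the fitting path
evaluates the porosity formula raw, while the public `porosity()`
enforces φ ∈ (0, 1]. The generalized model fixes a_f = 0.5σ (the physical
bead radius; the convention is not otherwise determined) and fits k alone
within (0, 1) by bounded trust region. The anisotropy ratio is fitted as
D_⊥/D_∥ = A d^(−l) + 1, and the brush height as L_z = A d^(−2/3).

The electrical endpoint uses the Nernst–Einstein conductivity
σ_e = F²/(RT) Σ_x D_x z_x² [x] with a documented CSF-like composition
pooled by valency (Na⁺+K⁺ 148 mM, Cl⁻+HCO₃⁻ 145 mM, Ca²⁺+Mg²⁺ 2.2 mM —
external physiological reference values), D per valency taken from
charged-tracer simulations at matching charge (divalent species fall back
to the monovalent D of the same sign unless simulated). The PNN is
treated as a spherical shell of thickness h = 500 nm around a neuron of
radius r: R = ρ_e h/(4π r(r+h)), the exact integral of ρ/(4πr'²). The
slab traversal time is t = h²/(2D_⊥).

## Desk-scale study conditions

Full scale (1,000 realizations per cell over ~15 spacings and four system
types) is hours of CPU. The shipped defaults are chosen once for a
single-CPU desk run and recorded here:

- Bulk reference: 500 free-particle realizations × 10⁵ steps for radii
  {0.125, 0.25, 0.5, 1}σ.
- Persistence calibration: 30 independent phantom chains × 20
  configurations sampled every 2τ after a 5τ burn-in (600 configurations).
- Brush sweep: d ∈ {2, 3, 4, 5, 7, 10}σ, static mode with 3 independently
  equilibrated brushes per d (near-vertical init for d < 5, relaxed-WLC +
  push-off for d ≥ 5; 20,000 equilibration steps) shared by the tracer
  productions: 192 neutral, 120 at q = −e and 48 at q = +e per d, each
  8,000 steps (40τ) sampled every 40 steps — many short productions
  rather than few long ones, since single-origin-MSD precision scales
  with the realization count and short runs lose fewer tracers over the
  brush top. Sharing a frozen brush across tracers rests on the
  static-mode finding that geometry, not chain dynamics, governs
  diffusion.
- Brush/mushroom crossover: d ∈ {15, 20, 25, 30, 40}σ on a 2×2 grid,
  four brushes per d (equilibrium-coil start, 6,000 relaxation steps).

What these sizes show: the qualitative structure of the full study —
anisotropy, charge dependence, crossover, model-fit parameters in the
right range — with group-std error bars an order of magnitude wider than
the published full-scale ones. What they do not show: convergence of the
long-time (hopping) diffusion regime, position-resolved transport, or
absolute transport coefficients beyond the γ-mapping caveat above.

## Initial-overlap relaxation

Relaxed-WLC placement accepts interchain overlaps (coils cannot be
packed with hard clearance at moderate densities); they are removed by a
capped push-off: pair forces clamped at 50 ε_E/σ, timestep reduced 5×,
velocities zeroed at entry and clamped near the thermal scale every 100
steps, for 3,000 steps. The harmonic-angle force floors sin θ at 10⁻³
(the convention of production MD codes): near θ = π the force vanishes
anyway, while near θ = 0 — transiently reachable in pushed-off tangles —
the naive 1/sin θ geometric factor would blow up through floating-point
cancellation.

## Known limitations

- The synthetic fixtures emulate linear MSD growth, a ballistic
  crossover, and ideal WLC statistics; they do not emulate
  charged-tracer trapping, so estimator behavior under strong
  subdiffusion is only exercised by the (slow, qualitative) brush cells.
- Static-mode sweeps reuse equilibrated brushes across tracer
  realizations; residual correlation between tracers in the same brush
  is mitigated by averaging over independent brushes but not eliminated.
- Brush equilibration (6,000 steps from WLC initialization) relaxes local
  structure well but global chain conformations only partially at
  intermediate d; L_z and R_g at d ≈ 10–25σ carry a corresponding bias
  toward the initialization ensemble.
- Electrostatics is pairwise screened Debye–Hückel with a fixed
  prefactor; no explicit ions, no charge regulation, no long-range
  (Ewald) correction.
- The reduced temperature cannot simultaneously satisfy the
  persistence-length calibration (kT = 2.804 ε_E) and the physical
  energy-unit mapping (kT ≈ 12 ε_E); with the calibrated kT the
  electrostatic contact coupling is ~1.1 kT, which slows a q = −e tracer
  by ~20–30% rather than the ~2× seen in strongly coupled regimes. A
  charge-transport study that needs stronger coupling should raise
  `coulomb_const` or lower `kT` explicitly and re-derive l_p.
- Desk-scale diffusion constants are short-time in-brush values (fit
  windows within ~8–40τ); longer productions probe slower transport, so
  the D(d)/D_bulk curve here sits above full-scale references and the
  fitted obstruction parameters (effective bead size a_f, walk
  continuation k) are correspondingly smaller.
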