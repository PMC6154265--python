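# Methods

This note documents the model as implemented, its numerical choices, the
default parameter set and its provenance, what the synthetic data emulate,
and known limitations.

## Model summary and assumptions

The airway wall is an axisymmetric two-layer thick-walled cylinder of fixed
length in plane strain (zero axial displacement, λ_z = 1), with no torsion
and no shear. Growth and elastic deformation are separated by timescale:
growth is slow (days), elasticity is instantaneous, so the elastic problem
is quasi-static and re-solved after every growth step. The grown
configuration is stress-free — growth itself imparts no residual stress —
and the total deformation is the multiplicative composition of a radial
growth map and an incompressible elastic map.

The tissue is a constrained mixture: contractile ASM, proliferative ASM and
ECM share one elastic deformation, plus an inert fluid phase at constant
hydration Φ_w = 0.70 (uniform in space and time). All solid phases have
equal true density (ρ_T = 1 by unit convention; it enters only through
products with the apoptosis and ECM rates). The inner layer (SBM) is pure
ECM; the outer layer carries all three solid phases.

Strain energies: the proliferative phase is neo-Hookean,
W_p = (c_neo/2)(I₁ − 3). The contractile and ECM phases are a neo-Hookean
ground matrix plus two symmetric helical fibre families with exponential
fibre energy, W_fib = (k₁/2k₂)[exp(k₂ x²) − 1], where x = I₄ − 1 for muscle
and x = I₄ − λ_u² for collagen (active only above the recruitment stretch;
both fibre terms are tension-only). These specific forms follow the standard
fibre-reinforced family the verbal model description points to; if a
different supplementary parameterization is preferred, the coefficients are
all exposed.

Two conventions deserve note:

* **Stress-free reference normalisation.** The extra stress
  2F(∂Ψ/∂C)Fᵀ carries an isotropic offset 2(∂Ψ/∂I₁)·1 at the identity;
  we subtract it so the unstrained state reports exactly zero stress. The
  offset is isotropic at each material point and is absorbed by the Lagrange
  multiplier; stress *differences*, which alone enter equilibrium and the
  pressure–radius relation, are unaffected.
* **Fibre-stress projection.** τ = T_θθ cos²α + T_zz sin²α uses the
  reference helical angle as projection weights. Projecting instead onto the
  deformed unit fibre directions would weight by the stretched components;
  at the default α = 5° the difference is below 1% and vanishes at α = 0.

The active stress Φ_c A_c(k) is split half-and-half over the two fibre
families, so the θ–z shear cancels and the total force density along fibres
is Φ_c A_c; in the α = 0 limit τ reduces to the full active tone.

## Stimuli

Challenges are Gaussian pulses of width σ = 0.5 day (shape constant d = 1,
kept distinct from σ only for fidelity to the customary printed form; each
pulse then integrates to one). Periodic protocols place events at
t_i = t₁ + (i−1)/ω with t₁ = 1 day, confined to a 50-day challenge window
inside a 1000-day horizon (the long tail exposes post-challenge resolution
and persistence). Inflammation μ is global; agonist k is a material field
riding the Lagrangian grid (no diffusion or transport law — the model's
k(ξ, t) distributions arise purely from local release and decay). The
Heaviside gates use the strict convention H(0) = 0 everywhere (stress
release, tier thresholds, stress-modulated rates).

Both stimulus ODEs are linear in their own variable and are advanced by an
exact exponential integrator with the source frozen at mid-step: decay is
exact to machine precision (important when resolution times hinge on decay
through six orders of magnitude), and non-negativity is automatic for
non-negative sources.

## Growth and its discretisation

The volume-fraction balances are solved in Lagrangian form: on material
points, dΦ_a/dt = S_a − Φ_a q and dξ/dt = v, which eliminates the advective
term exactly, satisfies the zero-flux interface conditions identically, and
makes solid-fraction conservation an algebraic identity (the forward-Euler
update preserves ΣΦ = 1 − Φ_w exactly, verified to ~1e-15 in runs). The
growth velocity integrates (1/ξ)∂(ξv)/∂ξ = q from the pinned outer wall
(v(ξ₂) = 0, all growth inward) by cumulative trapezoid — exact for the
per-layer-constant dilatations that dominate in practice. Default step
dt = 0.05 day with 101 nodes per layer; halving dt and doubling nodes moves
the day-55 inner radius of the default challenged run by ~0.26%.

Operator splitting per step, in fixed order: challenge train and μ update →
elastic equilibrium on the current grown geometry → agonist update using the
fresh τ field → sources, dilatation, velocity, Lagrangian advance. The
ordering guarantees the mechanotransductive terms always see the currently
constricted state.

Closure: a run is flagged closed (and discarded from sweep surfaces) when
the loaded inner radius falls below 0.01 mm or when the next growth step
would carry the grown inner radius below it; near closure the inward
velocity diverges like 1/ξ₁, so the pre-step check is what terminates runs
cleanly.

## Elastic solve

Because the radial map is explicit under incompressibility, the shooting
problem collapses to a 1-D root find on r1: for each trial r1 the momentum
ODE is a known integrand integrated by cumulative Simpson per layer (radial
stress continuous at the interface; hoop stress jumps with the composition),
and brentq closes the outer pressure residual (xtol 1e-12, warm-started
from the previous growth step). An unloaded, agonist-free state returns the
exact identity map with exactly zero stress — this keeps the homeostatic
fixed point exact instead of accumulating quadrature noise through 20,000
steps. The solver is validated against an independent adaptive-quadrature
evaluation of the classical inflation identity P1 = P2 + ∫(T_θθ−T_rr)/r dr
(agreement ~1e-11 relative). A pure ground-matrix (neo-Hookean) wall has a
finite limit-point pressure (~0.58 kPa at default stiffness); the
exponential fibre terms remove it.

## Default parameters

No published parameter table accompanies the model description available to
us, so the defaults form a self-consistent set chosen once from the
constraints the model itself imposes, then frozen:

* **Geometry** (mm): R1 = 1.8, Rint = 1.9, R2 = 2.3 — a large (generation-4
  sized) airway with a thin collagenous SBM and ~0.5 mm wall.
* **Homeostatic partition.** The closed-form steady state must fill the
  solid fraction: Φ_c* = 0.20, Φ_p* = 0.02, Φ_e* = 0.08 (ASM predominantly
  contractile with a small proliferative pool). With c_pc = 1, c_p0 = 0.5,
  c_c0 = 0.05 /day this fixes c_a = 0.25; with c_de = 0.5, c_pe = 0.25 /day
  the config loader re-solves c_e0 (= 0.035) so the partition is exact.
* **Inflammation tiers.** c_c1 = 2×, c_c2 = 4× baseline switching. The tier
  rates bound the proliferative steady state reachable during sustained
  inflammation (solid mass ×~2 at the mild tier, ×~4 at severe); much larger
  multipliers drive even the moderate operating point into closure within
  days, destroying the regime structure (plateau → threshold → closure) the
  model is meant to exhibit. Thresholds μ₁ = 0.5, μ₂ = 1.5 with a_μ = 1 per
  challenge: the default protocol peaks μ just under 0.6, crossing the mild
  tier briefly per challenge, and reaches the severe tier only under slow
  clearance or higher amplitude.
* **Clearance.** c_dμ = 0.7 /day places the default run in the moderate-
  remodelling regime, with the insensitive plateau above ~1 /day and closure
  below ~0.35 /day; c_dk = 1 /day gives a baseline agonist resolution time
  of order 10 days. a_kμ = a_c = 0.02 keep inflammation-induced and
  stress-induced agonist release weak by default (so inflammation-only runs
  constrict little), while a_c ≈ 0.1 with T_c ≈ 60 kPa establishes the
  self-perpetuating feedback loop.
* **Material.** c_ground = c_neo = 8, k1_c = 4, k1_e = 25 kPa, k2_c = 1.5,
  k2_e = 2, λ_u = 1.2, α = 5°; T_c = 20 kPa, K_d = 0.5, n = 2. These give a
  compliant low-pressure limb, collagen engagement from ~0.5 kPa, and ~45%
  hoop stretch at 3 kPa, with half-maximal tone at k ≈ 0.7.
* **Stress modulation.** c_cp_f = 0.05 /(day·kPa) (tension mode),
  c_p_f = 0 (proliferation unmodulated) by default. The compression modes
  use the stress magnitude, c_f·(−τ)·H(−τ), so the added rate is always
  non-negative — taking the signed product would *reduce* switching under
  compression, the opposite of the intended mechanism.
* **SBM-thickening mode.** Inner-layer ECM turnover re-uses the outer
  layer's tier increments on a baseline re-balanced against degradation of
  the resting SBM (c_e0_inner = c_de·0.3), so the unchallenged SBM is
  stationary and only inflammation thickens it. Taking the outer-layer
  baseline literally would shrink the SBM at ~0.4/day even at rest.
* **Steady-state closed form.** Consistency of the printed proliferative
  fraction with the mass balances requires reading the bare proliferation
  symbol as its baseline value c_p0; the implementation uses the re-derived
  form (verified against an independent nonlinear root find).

## Passive-parameter fitting and synthetic data

`generate_synthetic_pr` emulates a quasi-static inflation experiment on the
passive, ungrown airway at homeostatic composition: the forward
pressure–radius curve (20 points, 0.05–3 kPa) plus homoscedastic Gaussian
radius noise — instrument error of a displacement gauge, fixed at 1% of the
reference radius (0.018 mm) rather than proportional to signal. It does
not emulate hysteresis, adaptation, actively toned states, or inter-subject
geometric variability; recovery results say nothing about those.

Identifiability on a single inflation curve is limited: c_neo multiplies
2% of the same invariant as c_ground's 28%, and each exponential fibre
amplitude trades off against its exponent. The default fit therefore frees
two well-conditioned quantities — the pre-recruitment stiffness scale
(c_ground, with c_neo and k1_c tied at their prior ratios) and the collagen
amplitude k1_e — holding exponents, λ_u and α fixed. The active parameter
T_c is never fitted (it is not observable in passive inflation). Zero-noise
recovery is exact to machine precision; at the default noise, single-fit
scatter is ~4–7% per coefficient, so recovery accuracy is assessed as
Monte-Carlo bias over 50 seeded replicates (~0.4–1%), with mean R² ≈ 0.994.
Fits use trust-region-reflective least squares with bounds at 1e±3 of the
guess and tolerances 1e-10.

## Numerical edge cases

* Equilibrium failure (no sign change of the pressure residual over the r1
  bracket, e.g. beyond a limit-point pressure) raises an error carrying both
  bracket residuals; pressure–radius tables record such points as missing
  rather than failing the whole curve.
* Grid tangling (non-monotone ξ after a growth step) aborts the run with
  partial output; in practice it is pre-empted by the closure check.
* The agonist exponential integrator cannot undershoot zero for
  non-negative sources; a clip-with-warning guards the general case.
* Tier thresholds compare strictly (H(0) = 0), so a trajectory sitting
  exactly on μ₁ stays in the lower tier.

## Limitations

Axisymmetry excludes SBM buckling and non-axisymmetric collapse; growth is
radial only (no circumferential/axial growth, hence no residual stress
development); constituents share a single reference configuration; agonist
and cytokine transport is purely local (no diffusion); the epithelium is
not an explicit phase (compression-driven epithelial signalling is folded
into the compression-mode rate options); and there is no viscoelasticity or
tidal-breathing oscillation — loading is quasi-static throughout. The
default parameter set is self-consistent rather than fitted to a specific
animal dataset; quantitative outputs (e.g. the exact threshold clearance
rates) should be read as regime markers, not physiological predictions.
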