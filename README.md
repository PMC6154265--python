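# airwaymorph

A morphoelastic simulator of asthmatic airway remodelling: a two-layer
airway wall — a stiff collagenous subepithelial basement membrane (SBM)
inside a smooth-muscle layer — whose tissue composition evolves under
repeated inflammatory or contractile-agonist challenges, with quasi-static
nonlinear elastic equilibrium re-solved at every growth step and
mechanotransductive feedback from the tissue stress.

It is written for researchers in tissue biomechanics and mechanobiology who
want to explore how inflammation dynamics, airway smooth muscle (ASM)
phenotype plasticity, hyper-responsiveness and stress-mediated cytokine
release interact to produce long-term airway narrowing, persistent
contractile tone, and the regime thresholds ("switch" effects) between mild
and severe remodelling.

## The model

**Kinematics.** The airway is an axisymmetric, incompressible, plane-strain
thick-walled cylinder. Total deformation decomposes multiplicatively,
**H** = **F G**: a growth map **G** takes the reference configuration
(radii `R1 < Rint < R2`) to a grown, stress-free configuration with radii
`ξ(R, t)`, and an elastic map **F** = diag(∂r/∂ξ, r/ξ, 1) takes it to the
loaded, stressed configuration `r(ξ)`. Incompressibility of **F** gives
`r² = r1² + ξ² − ξ1²`, so equilibrium reduces to one unknown, the deformed
inner radius `r1`, found by shooting on the radial momentum balance
`∂T_rr/∂r + (T_rr − T_θθ)/r = 0` with pressure boundary conditions
`T_rr(r1) = −P1`, `T_rr(r2) = −P2`.

**Constitutive law.** The wall is a constrained mixture of contractile ASM
(Φ_c), proliferative ASM (Φ_p), collagen-dominated ECM (Φ_e) and fluid
(Φ_w = 0.70), all solid phases sharing **F**. The Cauchy stress is
`T = −p 1 + 2 F (∂Ψ/∂C) Fᵀ + T_active` with mixture energy
`Ψ = Σ_a Φ_a W_a`: a neo-Hookean proliferative phase, and fibre-reinforced
contractile/ECM phases (two symmetric helical families at angle α, with an
exponential fibre response; ECM collagen is crimped and bears load only
above the recruitment stretch λ_u). Active tone is a Hill-saturating force
density along the fibres, `A_c(k) = T_c kⁿ/(K_d + kⁿ)`, where `k` is agonist
concentration and `T_c` parameterizes hyper-responsiveness. The
mechanotransduction signal is the fibre stress
`τ = T_θθ cos²α + T_zz sin²α`.

**Stimuli.** Challenges are a train of Gaussian pulses `f(t)`. Global
inflammation obeys `dμ/dt = a_μ f − c_dμ μ`; the local agonist field obeys
`dk/dt = a_k f − c_dk k + a_kμ μ + a_c τ H(τ)` — the last term is
stress-mediated agonist release (only tensile τ releases).

**Growth.** Each volume fraction obeys an advection–reaction balance whose
sources encode phenotype switching (`c_cp(μ, τ)`, tiered in inflammation by
thresholds μ₁ < μ₂ and stress-modulated), switch-back (`c_pc`), logistic
apoptosis (`c_a`), proliferation (`c_p(τ)`), and ECM deposition/degradation
(`c_be(μ)`, `c_de`, `c_pe`). Constant hydration closes the system: the
mixture dilatation `q = ΣS_a / (1 − Φ_w)` drives a radial growth velocity
integrated inward from the pinned outer wall, so all growth is inward. The
homeostatic composition is a closed-form stable fixed point and the initial
condition.

## Worked example

`python examples/03_clearance_sweep.py` sweeps the inflammation clearance
rate `c_dμ` under ten periodic inflammatory challenges (days 1–46) and
reports the grown inner radius 5 days after the final challenge plus the
agonist resolution time (days until the cross-sectional agonist total drops
below 1e-6):

```
c_dmu (1/day)   remodelled r1 (mm)   resolution (days)   closed
         1.50                1.800                12.5   False
         1.00                1.800                14.5   False
         0.70                1.475                19.2   False
         0.50                0.899                26.6   False
         0.35          (discarded)                       True

Slower clearance (smaller c_dmu) monotonically increases remodelling
and agonist retention, with a sharp threshold before closure.
```

Read: at fast clearance the response sits on an insensitive plateau (no
remodelling from 1.8 mm); below a threshold clearance rate remodelling
increases sharply; at the slowest rate the airway grows completely into the
lumen and the run is discarded by the closure rule. Other examples show
pressure–radius curves with and without tone, a single challenged run,
passive-parameter fitting from synthetic inflation data, and the
hyper-responsiveness feedback loop with censored agonist resolution.

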