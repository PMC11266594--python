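# Methods

## The physical model

A biofilter bed removes two volatile organic compounds — methanol
(hydrophilic) and α-pinene (hydrophobic) — from a contaminated air
stream.  The packing is coated by a thin microbial biofilm of thickness
δ; air moves through the bed in plug flow.  At every height the
pollutants partition from the gas into the film (interface concentration
`S_i = C_gas / m` with partition coefficient `m`), diffuse into the film
and are degraded by Michaelis–Menten kinetics.  Methanol suppresses
pinene degradation through the inhibition factor

    α(C_m) = 1 / (1 + (C_m / K_i)²) ∈ (0, 1],

which multiplies the pinene reaction term.  Steady state is assumed
(constant film density, no transients), radial gradients and pore-phase
reaction are neglected, and the two compounds are degraded by distinct
microbial populations, so the only cross-coupling is α.

### Biofilm phase

In dimensionless form (depth `X* ∈ [0,1]`, saturation `S* = S/S_i`):

    S_m*'' = φ  S_m*/(1 + β  S_m*),      S_m*(0) = 1,  S_m*'(1) = 0,
    S_p*'' = αφ₁ S_p*/(1 + β₁ S_p*),     S_p*(0) = 1,  S_p*'(1) = 0,

with the Thiele-type modulus `φ = (X μ_max/Y) δ²/(D_e K)` (reaction
capacity over diffusion) and the saturation parameter `β = S_i/K`
(interface concentration over half-saturation).  Two limits close the
model analytically:

- unsaturated (first-order, β·S ≪ 1): `S* = cosh(√φ(1−x))/cosh(√φ)`,
  interface flux `S*'(0) = −√φ·tanh(√φ)`;
- saturated (zero-order, β·S ≫ 1): constant demand φ/β gives the
  parabola `S* = 1 + (φ/β)(x²/2 − x)` while φ ≤ 2β; for φ > 2β the
  substrate is exhausted at the penetration depth `x_p = √(2β/φ)` and
  the profile is the free-boundary parabola `(φ/2β)(x_p − x)²` for
  x ≤ x_p, zero beyond, C¹-continuous at the front.

### Gas phase

Plug flow depletes the gas linearly in the interface flux:

    dC_m*/dh* = A  · S_m*'(0),      dC_p*/dh* = α A₁ · S_p*'(0),

with `A = H A_s D_em S_im / (U_g δ C_mi)` and C*(0) = 1.  (The
dimensional balance fixes this sign: the flux is negative, so the
concentration declines; removal efficiency is `1 − C*(1)`.)  Two
couplings are implemented:

- `as_printed`: the flux is evaluated once at inlet conditions and held
  fixed — a literal linear decline, clamped at zero (clamps are logged);
- `local` (default): at each height the biofilm problem is re-solved for
  the local gas concentration.  This uses an exact rescaling: if
  S(0) = C then S = C·u where u solves the unit-boundary problem with
  saturation parameter β·C, so the physical flux is C·u'(0).  When the
  inlet-to-inhibition ratio `gamma = C_mi/K_i` is positive, α is
  recomputed at every height as `1/(1+(γ C_m*)²)`; otherwise the
  constant α of the parameter set is used.  For first-order kinetics the
  local flux is linear in C and the column has the closed form
  `C* = exp(−A √φ tanh(√φ) h*)`, which the integrator reproduces to
  ~1e-11 and the tests check to 1e-8.

Note that a *constant* α supplied as a sweep parameter (e.g. α = 1.34)
is a free positive number and deliberately not restricted to the (0,1]
range of the inhibition law; the two entry points are kept separate.

## Numerics

Biofilm BVP: fourth-order compact (Numerov) finite differences on a
uniform closed grid of 1001 nodes, Neumann closure by a symmetric ghost
node at X* = 1 — exactly consistent because the autonomous ODE with zero
terminal slope is even about X* = 1.  The nonlinear system is solved by
Newton iteration with residual-halving damping, initial guess S* ≡ 1,
tolerance 1e-12 on the infinity norm of the integrated residual
(the h²-multiplied form; the raw residual would amplify float64
rounding by 1/h² ≈ 1e6 and bottom out near 1e-10).  The problem is
monotone and converges in ≤ 10 iterations for all tabulated parameter
ranges.  Doubling the grid changes S*(1) by ~1e-12.  The interface flux
is a five-point one-sided difference (O(h⁴)); by integrating the ODE it
must equal the reaction consumed over the film, which the tests verify
to 1e-6 by independent Simpson quadrature.  The zero-order regime is
evaluated from its exact free-boundary parabola rather than by
iteration: the closed form already satisfies the discrete equations to
round-off and preserves the exact front position and flux.

An independent single-shooting solver (fixed-step classical RK4, step
1e-3, secant iteration on the unknown initial slope bracketed in
[−φ_eff, 0]) cross-checks the Numerov path to ~3e-12; during trial
integrations the reaction rate is clamped at S ≤ 0 so overshooting
slopes cannot cross the Michaelis–Menten pole at S = −1/β.  A further
independent oracle (scipy's collocation BVP solver) is used in tests
only.  The frozen 6-decimal reference profile values shipped in the
fixture registry agree with all three to ≤ 5e-7.

Column: classical fixed-step RK4 on 101 heights, with a step-halving
check (re-integration at doubled resolution) that warns above 1e-8.
Inner biofilm solves for the local coupling use 401 nodes (truncation
~1e-11, well below the column tolerance).

## The Elman-network surrogate

Architecture: one hidden layer of N = 60 logistic units plus its context
copy, logistic scalar output, biases on hidden and output units (without
an output bias even a constant target is unlearnable).  For ascending
inputs x(1..T) with zero initial context:

    h(t) = σ(w_hi x(t) + w_hc c(t−1) + b_h),  c(t) = h(t),
    y(t) = σ(w_oh h(t) + b_o).

Dataset: 1001 uniform points on [0, 1] sampled from a reference profile,
divided 701/150/150 (train/validation/test) by a seeded permutation with
largest-remainder rounding.  The dataset is one ordered trajectory; the
division selects which outputs are *scored*, while every forward pass
runs the full sequence.  Scoring sub-splits as separately-run sequences
would make the network's output depend on the spacing between
consecutive points of each split and introduces an irreducible ~3e-3
cross-split error floor; full-sequence scoring (the behaviour of
standard sequence-division tooling) removes it.

Training: damped least-squares (Levenberg–Marquardt) on the train-split
MSE.  The Jacobian is teacher-forced — the context sequence is treated
as exogenous, frozen at the values realized in the forward pass (the
classical Elman truncation; no backpropagation through time).  The step
solves `(JᵀJ + μI)Δ = Jᵀe` through the dual identity
`Δ = Jᵀ(JJᵀ + μI)⁻¹e` (701×701 instead of 3781×3781), with JJᵀ
assembled from a Hadamard/Gram factorization of the Jacobian blocks —
the full J is never formed during training, but an explicit
`enn_jacobian` exists and the two are verified identical in tests.
Damping: μ₀ = 1e-3, ×10 on rejection, ×0.1 on acceptance, accepted steps
must strictly decrease the training MSE.  Stopping: 2000-iteration cap,
gradient infinity-norm < 1e-7 (of the MSE gradient), μ > 1e10, or 6
consecutive accepted steps without validation improvement.

Initialization matters more than any other trainer setting here:
small-uniform random weights leave batch LM in shallow local minima
(train MSE ~1e-5).  The default is therefore Nguyen–Widrow style —
hidden input weights of magnitude 0.7·N with random signs and biases
placing each sigmoid transition at a random center in [0, 1], small
(uniform/N) context weights so the net starts near-feedforward, uniform
[−0.5, 0.5] output layer.  With it, training on the φ = β = 10 profile
reaches held-out MAD between ~6e-6 and ~5e-5 across ten seeds (mean
~2e-5) in 10–230 LM iterations; plain uniform init is retained as
`init="uniform"` for comparison.  All randomness flows from a single
integer seed; runs are bit-reproducible.

## Evaluation statistics

Per prediction/reference pair: MSE; mean absolute deviation (MAD);
Theil's inequality coefficient (RMS error over the sum of the two RMS
norms — scale-invariant, 0 perfect, ≤ 1); Nash–Sutcliffe efficiency in
its classical form `1 − Σ(pred−truth)²/Σ(truth−mean(truth))²` and its
complement ENSE = 1 − NSE.  A variant NSE pairing seen in the
soft-computing literature (denominator from the prediction's deviation
about the reference mean, 1/n on the numerator only) is available as
`variant="as_printed"`; it is not the default because it is degenerate
for the mean predictor and breaks the NSE = 0 baseline identity.
Stochastic trainings are aggregated per metric as minimum / mean /
sample (ddof = 1) standard deviation; point count and run count are kept
as distinct fields.

## Problem sizes and reproducibility

Defaults everywhere are the tabulated study conditions: 1001-node
biofilm grids, 101-height columns, 1001-point datasets split
701/150/150, 60 hidden neurons, ≤ 2000 LM iterations.  The test suite
trains the full-size surrogate on ten seeds (about a minute in total);
the acceptance script (`python scripts/acceptance.py --seed <s> --out
<json>`) re-solves every tabulated scenario, checks flux conservation
and the closed-form column, and trains three full-size surrogates for
the multi-run aggregate.

## What the generator does and does not emulate

All training data are generated by the reference solvers — the surrogate
is a solver emulator, not a model of measured biofilter data.  Passing
tests therefore demonstrate that the network can reproduce smooth,
monotone reaction–diffusion profiles to ~1e-5, not that the model fits
any particular experimental column.  Known limitations: steady state
only (no start-up dynamics or biomass growth), no axial dispersion or
radial gradients, single inhibition coupling, and the teacher-forced
Jacobian is an approximation that can slow (not bias) LM convergence
when context weights become large.
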