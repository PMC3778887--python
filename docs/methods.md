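# Methods

## Generative model

**Neural dynamics.**  Hidden neuronal states `x ∈ R^n` (one scalar per
region, the amplitude of that region's dominant activity mode) evolve as

    dx/dt = A x + Σ_i u_i B^(i) x + C u + Σ_j x_j D^(j) x + ϖ(t)

— a second-order Taylor expansion of an unknown evolution function.  `A`
(1/s) holds fixed coupling rates, `B^(i)` the modulation of coupling by
input channel `i`, `C` driving-input gains and `D^(j)` state-dependent
gating (region `j`'s activity scales connections; the nonlinear term).
Every matrix carries a binary mask selecting *free* parameters; mask-0
entries are fixed constants (usually zero, i.e. the connection is absent —
model comparison then compares genuinely different dimensionalities).
State noise `ϖ` is white (Wiener/Markovian); generalized, temporally
smooth state noise is out of scope.

The analytic state Jacobian used throughout (stability analysis,
sensitivity propagation) is

    J = A + Σ_i u_i B^(i) + Σ_j x_j D^(j) + Σ_j (D^(j) x) e_jᵀ ,

i.e. the exact derivative of the gating term, which the test battery pins
against finite differences.

**Hemodynamics.**  Each region's activity drives a balloon/Windkessel
cascade with states (s, log f, log v, log q): vasodilatory signal, blood
inflow, venous volume and deoxyhemoglobin content, the last three
log-transformed so the physical quantities stay positive:

    ds/dt      = x − κ_s s − κ_f (f − 1)
    d log f/dt = s / f
    d log v/dt = (f − v^{1/α}) / (τ₀ v)
    d log q/dt = [ f E(f)/(E₀ q) − v^{1/α}/v ] / τ₀ ,   E(f) = 1 − (1−E₀)^{1/f}

observed through the three-compartment BOLD equation

    y = V₀ [ k₁(1−q) + k₂(1−q/v) + k₃(1−v) ],
    k₁ = 4.3 ν₀ E₀ TE,  k₂ = ε₀ r₀ E₀ TE,  k₃ = 1 − ε₀ .

Defaults: κ_s = 0.65 /s, κ_f = 0.41 /s, τ₀ = 2 s, α = 0.32, E₀ = 0.34,
V₀ = 4, ν₀ = 40.3 /s, TE = 0.04 s, r₀ = 25 /s, ε₀ = 1.  The origin is the
unique equilibrium of the cascade and is locally stable, which the
stability module verifies by multi-start root search.

A property of these equations that matters in practice: under *sustained*
deactivation stronger than κ_f the inflow equation loses its equilibrium
and log f diverges in finite time (flow would have to go negative).  The
model is only meaningful while sustained deactivations stay above roughly
−0.4; the simulator raises an explicit divergence error past that, and the
fixtures are designed to respect the limit (see below).

**Priors.**  Free evolution parameters share an i.i.d. zero-mean shrinkage
prior of variance 0.1.  Hemodynamic parameters are fixed at their defaults
by default; an "empirical" mode frees them as log-scaling factors with
prior variance 1e-2 (positivity by construction).  Measurement noise is
i.i.d. Gaussian with precision λ_ε under a Jeffreys hyperprior implemented
as the conjugate Gamma limit Ga(1e-8, 1e-8), which keeps updates proper.
Neural state-noise precision λ_ϖ carries Ga(1, 0.1) (shape–rate): this
puts P(λ_ϖ < 30) = 1 − e⁻³ ≈ 0.95, i.e. 95% prior mass on state-noise
variance above 1/30.  The hemodynamic state-noise variance is *tied* to
the neural one as Ψ_ϖ^(n) = 100 · Ψ_ϖ^(h) rather than estimated — a
deliberate constraint that makes "hemodynamic noise explains the BOLD
signal" a priori implausible relative to a neuronal explanation.

**Temporal basis sets.**  A deterministic DCM can emulate unknown neural
fluctuations by projecting them onto K known temporal basis functions per
region (added coefficients share the shrinkage prior).  Fourier sets are
sine/cosine pairs up to order K/2 on the session (orthogonal on the grid;
odd K is rounded down with a warning); RBF sets are K evenly spaced
Gaussian bumps with width equal to their spacing.  The conventional K is
32 per region (64 extra parameters for two regions).

## Simulation

Sessions integrate from rest (x = 0) with a micro-step dt = TR/16.  The
scheme is Euler–Maruyama with a Heun (second-order) drift step: additive
Gaussian increments of variance `σ² dt` on neural states and `σ²/100 dt`
on hemodynamic states, while the deterministic skeleton gains an order of
accuracy (measured 2.6e-4 max BOLD deviation from an adaptive reference
solver on the linear fixture, versus ~2e-2 for a first-order drift step).
BOLD is read out at every TR.  Realized noise draws are stored and can be
replayed bit-exactly.

Measurement noise is calibrated to a target SNR, `10 log₁₀(⟨g²⟩/⟨ε²⟩)`
pooled over regions and time, by scaling the realized draws to the exact
empirical power — the realized SNR equals the target by construction.
Input fluctuations Δu (per region, added directly to the neural flow) are
a random mixture of eight 0.01–0.1 Hz sinusoids and white noise with an
equal power split, rescaled to a state SNR of 10 dB relative to the
controlled input's power; constant input channels (baseline drives) do
not count towards that reference power.

## Fixture networks

Exact coupling strengths are package choices, made once under three
constraints: (i) stability / the intended dynamical regime, (ii) the
hemodynamic deactivation limit above under 10 dB fluctuations, and (iii)
coherence with the shrinkage prior — generating values are plausible draws
under N(0, 0.1), because recovery statements are meaningless when the
"truth" is a 3σ outlier under the very prior the inversion uses.

- `linear_2r`: mutually inhibitory pair, A = [[−0.55, −0.25], [−0.25,
  −0.55]], driven by one-minute boxcars (amplitude 0.2, input gain 0.6)
  into region 1.
- `lotka_volterra_2r` / `gating_2r_limit_cycle`: a two-region system with
  almost-full gating whose deterministic skeleton has a stable limit cycle
  with an unstable spiral inside and a saddle outside.  Because an
  origin-centred cycle of useful amplitude necessarily violates the
  deactivation limit, the searched system is *translated* into positive
  state territory by a constant baseline drive delivered through a tonic
  input channel — the translated quadratic system is again exactly of
  A/C/D form.  The competition variant adds an experimental boxcar; the
  tonic variant is driven by a unit constant input.
- `mediated_3r` / `direct_3r`: a reciprocal chain 1↔2↔3 (couplings 0.3,
  self −0.8) without/with weak direct 1↔3 links (0.15); both induce
  dependence between regions 1 and 3, and only model comparison can tell
  them apart.
- `epilepsy_3r`: a fully connected three-node network (thalamus + two
  cortical regions) with block inputs mimicking spike-and-wave episodes at
  TR = 3 s.

## Stability analysis

Equilibria come from a multi-start root search (default 200 starts, root
tolerance 1e-9, deduplication radius 1e-5 in state units, solver
exploration clamped to a margin around the search box), classified by the
eigenvalues of the analytic Jacobian (node/spiral/saddle, stable/unstable,
centre-like).  The moving-frame stability matrix is built constructively:
with the frame's first axis along the flow, J* = U J U⁻¹ + (dU/dt) U⁻¹,
where the frame rotation rate along a path is φ̇ = (f × ḟ)/|f|² with
ḟ = J f.  Structurally, the element coupling tangential perturbations
into transverse motion is exactly zero, and trace(J*) = trace(J) because
the rotation generator is antisymmetric; both are verified to machine
precision, and a dual-integration oracle (rotating the integrated
linearised perturbation versus integrating the moving-frame system
directly) agrees to 1e-3 relative over one period of the limit cycle.
On grids (no path) the rotation rate uses the local field's ḟ = J f,
recorded in the output metadata; near-zero-flow nodes are flagged and
skipped.  The frame decomposition is two-dimensional by construction;
higher dimensions retain only the structural zero.

## Inversion

Both DCM variants are inverted as Gaussian-prior nonlinear regression.
The deterministic forward map integrates the model (same Heun drift,
micro-step dt = TR/8 by default — its residual discretisation error is
far below the measurement-noise floor; TR/16 is used where the test
compares against the generator exactly) while propagating the sensitivity
matrix dz/dθ, compiled with numba.  The neural flow is linear in all
evolution parameters, which keeps the parameter part of the sensitivity
update sparse; free hemodynamic parameters use finite-difference columns.

**Stochastic DCM.**  The Wiener state noise accumulated over each TR is
lumped into one impulse per region and scan boundary ("innovation" w,
prior N(0, TR/λ_ϖ)).  The parameter vector becomes (θ, w) and state
estimation turns into batch Gaussian smoothing solved *jointly* with the
parameters; the posterior state trajectory at any time is conditioned on
the whole session.  This replaces a fixed-lag filter design: the original
motivation for a look-ahead lag (hemodynamics delay the impact of neural
events on the BOLD signal by ~5 s, so state estimates must see future
data) is satisfied a fortiori, and the `lag` setting survives as metadata.
Hemodynamic innovations are not separately estimated — the 100:1 variance
tie makes their prior contribution negligible — and λ_ϖ gets conjugate
Gamma updates from E[w²].  As the state-noise precision grows the
innovations shrink to zero and the scheme reduces *exactly* to the
deterministic inversion (verified at 2% tolerance; measured ≲0.1%).

**Optimisation.**  Levenberg-damped Gauss–Newton steps on the Gaussian
mean (steps accepted only if the penalised data fit improves), closed-form
covariance Σ = (E[λ_ε] GᵀG + P₀)⁻¹, conjugate Gamma updates for both
precisions, and the free energy

    F = E_q[ln p(y|θ, λ_ε)] + E_q[ln p(θ)] + ½ ln|Σ| + (n_θ/2) ln 2πe + (Gamma terms)

evaluated under the local quadratic expansion of the forward map — exact
for linear maps, which is why F reproduces the analytic log evidence on
conjugate linear-Gaussian problems to 1e-6.  Convergence: relative ΔF
below 1e-4 or 64 iterations; if an iteration *decreases* F the scheme has
reached the resolution of the quadratic expansion, reverts to the best
iterate and stops (the reported trace is therefore non-decreasing).  The
initial expansion point is the prior mean with free self-connections at
−0.5 /s; if the forward model diverges there (a fixed baseline drive
meeting weak initial coupling can push the hemodynamics past the
deactivation limit), progressively stronger self-inhibition is tried.

## Evaluation machinery

MSE and the mean confidence bias MCB = mean[(truth − μ)² − Σ_ii]
(positive = overconfident: the posterior variance *is* the expected
squared error of a well-specified posterior) are computed for three
variable groups: shared evolution parameters, neural states at scan times
(variances from the propagated sensitivities), and the per-region input
drive (known input + modelled fluctuations, a linear functional of the
posterior).  The accuracy design crosses SNR {1, 10 dB} × linearity
{linear, gated} × fluctuations {off, on} with 24 repetitions (192
sessions), each analysed under DCM type {stochastic, deterministic} ×
basis {none, Fourier, RBF}; the discrimination design crosses generating
network {mediated, direct} × fluctuations at 1 dB with 24 repetitions (96
sessions), each inverted under both network structures and both DCM
types.  Session seeds derive from the cell labels and repetition index
(CRC mixing with the base seed), so execution order cannot change any
record, and inversion failures are recorded per record rather than
raised.  Reduced presets ship for desk-scale runs; the shipped test
battery exercises the discrimination replication at 8 repetitions of
5-minute sessions and the recovery battery at 20 seeds of 10-minute
sessions — sizes chosen as the smallest at which the directional claims
are stable.  Factorial summaries fit response = cell + repetition
(sum-to-zero blocking) by ordinary least squares and report adjusted cell
means and main effects with standard errors.

The epilepsy-style model space is the full factorial of 9 spike-and-wave
effects (4 driving-input placements: thalamus / either cortex / all;
4 modulatory connection sets: thalamo-cortical, cortico-thalamic,
intrathalamic, all; 1 null) × thalamic gating {on, off} × DCM type
{stochastic, deterministic} = 36 models, all with full reciprocal
endogenous connectivity and the relaxed (1e-2) hemodynamic prior.  Under
a deterministic model a purely modulatory effect cannot elicit any
activity from rest, so the deterministic modulatory family is effectively
null — verified by simulation.

## What the synthetic data do and do not emulate

The generator produces block-design sessions with calibrated measurement
noise, optional structured input fluctuations and genuine Wiener state
noise through the full nonlinear observation cascade — the features the
estimation theory actually engages.  It does not emulate scanner drift,
motion or physiological artifacts, spatial/regional averaging, slice
timing, non-Gaussian or temporally correlated noise, or hemodynamic
variability across regions (one parameter set per session).  Passing
tests therefore demonstrate internal consistency of estimator and
generator under the stated model class, not robustness to the
misspecifications real fMRI adds.

## Known limitations

- The balloon model's sustained-deactivation singularity bounds the
  usable dynamic range; strongly inhibitory regimes need rescaled inputs.
- Quadratic gating systems have finite basins; sessions that escape
  (possible under heavy fluctuations) terminate with a divergence error
  and are recorded as failed cells in the studies.
- In the exactly noiseless limit the Jeffreys measurement-noise prior
  drives the estimated precision to numerical infinity and model
  comparison degenerates; comparisons are meaningful at finite SNR.
- The joint Gaussian over (θ, w) costs O((p + nT)³) per covariance
  update; sessions beyond a few regions × ~1000 scans call for sparser
  smoothers.
- Recovery/calibration statements are counted per parameter-replicate
  pair, and hold for generating values that are plausible under the
  shrinkage prior (coverage against prior-outlier truths is not claimed —
  nor achievable for a correctly computed Bayesian posterior).
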