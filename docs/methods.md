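# Methods

## Model and assumptions

The package implements a differential-susceptibility epidemic model with
one infective class and an optional AIDS compartment, under two layers of
environmental noise. Susceptibles are split into n groups by inherent
susceptibility α_k; each group is recruited at rate μS_k⁰, dies naturally at
rate μ, and is infected through standard incidence βα_k S_k I / N with
N = Σ_k S_k + I the sexually interacting population. Infectives leave the
class at rate μ + γ (death plus progression); progression feeds A, which is
removed at rate δ and never feeds back, so A is an output channel only.

White noise enters through the effective contact rates: βα_k dt is replaced
by βα_k dt + σ_k dB_k, which puts the diffusion term ±σ_k (S_k I/N) dB_k
into the S_k and I equations with the *same* Brownian motion and opposite
signs. Two consequences shape the implementation: (i) noise moves mass
between compartments but injects none into the total, so N obeys the
deterministic recursion dN = [μ ΣS⁰ − μN − γI] dt along every sample path;
(ii) every noise term carries a factor I, so the disease-free face I = 0 is
invariant.

Telegraph noise enters by letting every parameter depend on a
continuous-time Markov chain ξ(t) on {1, …, L} with generator Γ = (γ_ij),
γ_ij > 0 for i ≠ j, irreducible with stationary law π (πΓ = 0, Σπ = 1,
π > 0). Long-run statements average regime quantities under π.

## Closed-form indices

* Per-regime deterministic reproduction number:
  R₀ = β Σ_k α_k S_k⁰ / ((μ+γ) Σ_k S_k⁰) — the S⁰-weighted mean effective
  contact rate times the mean infectious period.
* Strong-noise extinction index:
  R̄₀\* = [Σ_k Σ_l π_l β²(l)α_k²(l)/(2σ_k²(l))] / [Σ_l π_l(μ(l)+γ(l))].
  It arises from maximizing f(z) = βα_k z − (σ_k²/2) z² over the feasible
  incidence fraction z = S_k/N ∈ (0, 1]; the maximizer is interior when
  noise is strong, giving the β²α²/(2σ²) cap. Undefined when some
  σ_k(l) = 0 (we flag rather than substitute a limit).
* Weak-noise extinction index:
  R̄₀\* = [Σ_k Σ_l π_l β(l)α_k(l)] / [Σ_l π_l(μ(l)+γ(l)+Σ_k σ_k²(l)/2)],
  applicable when σ_k²(l) < β(l)α_k(l) for all k, l (then f is maximized at
  z = 1). Both indices share one symbol in the underlying theory; the
  package names them separately and reports applicability flags instead of
  auto-selecting.
* Exponent bounds: lim sup ln I(t)/t ≤ (π-averaged removal rate) × (index − 1),
  with the removal rate matching the index's denominator. Negative exactly
  when the index is below 1.
* Persistence index:
  R₀ˢ = Σ_k num_k³ / (d1_k · d2 · d3), where
  num_k = Σ_l π_l (μ²βα_k S_k⁰)^{1/3}, d1_k = Σ_l π_l (μ + σ_k²/2),
  d2 = Σ_l π_l (μ + γ + Σ_j σ_j²/2), d3 = Σ_l π_l (μ Σ_j S_j⁰). The
  cube-root structure comes from an AM–GM step in the Lyapunov argument;
  for L = 1 and σ ≡ 0 the expression reduces algebraically to R₀ (tested to
  1e−12 over randomized parameter sets). The Lyapunov weights are
  c_k = num_k³/(d1_k² d3) and a_k = num_k³/(d1_k d3²).
* Persistence lower bound:
  lim inf (1/t)∫ I/N ≥ d2 (R₀ˢ − 1) / (β̌ Σ_k c_k α̌_k), with β̌, α̌_k maxima
  over regimes. We implement the summed-denominator form (the final
  inequality of the underlying proof); the per-k display sometimes quoted
  for this bound carries a dangling group index and is not internally
  consistent.
* Drift bound: M = μ̌ Σ_k Š_k⁰ + (n+1)μ̌ + γ̌ + β̌ Σ_k α̌_k + Σ_k σ̌_k²
  dominates 𝓛V for V = Σ_k (S_k − 1 − ln S_k) + (I − 1 − ln I) at every
  strictly positive state (V is regime-independent, so the switching part
  of the generator vanishes). At the disease-free point (S = S⁰, I → 0⁺,
  σ = 0) the exact drift tends to (μ+γ)(1 − R₀), a value used as a
  hand-checked oracle in the tests.

## Recurrence domain

For R₀ˢ > 1 the process is positive recurrent with respect to the box-like
domain D cut out of the invariant region by three margins ε₁ (per-group
susceptible floor), ε₂ = (nε₁)² (infective floor) and ε₃ = ε₂² (ceiling
margin below the envelope upper = Σ_k Š_k⁰). The construction solves
−Mλ + Σσ̌_k²/2 + (n+1)μ̌ = −2 for the Lyapunov weight M, with
λ = d2 (R₀ˢ − 1), sets K̂ = β̌(M Σ c_k α̌_k + Σ α̌_k) − 2, and chooses the
largest ε₁ compatible with the three smallness conditions
ε₁ ≤ μ̂Ŝ_k⁰/(K̂+1), β̌(M Σ c_k α̌_k + Σ α̌_k) n ε₁ ≤ 1 and
(nε₁)² ≤ γ̂/(K̂+1) (conditions involving K̂+1 drop out when K̂ ≤ −1), then
halves it once as a safety factor so that D stays comfortably interior
despite discretization noise, halving further if needed for nonemptiness.
Boundary states count as outside D.

## Simulation

Jump times of the regime chain are drawn exactly from the CTMC (holding
times exponential with rate −γ_ll, next state ∝ γ_lj), which removes the
O(dt) bias of per-step Bernoulli switching. Between jumps the SDE is
integrated by Euler–Maruyama with coefficients evaluated at the
nonnegatively clamped incoming state and outgoing components clamped at
zero ("full truncation"): the exact solution is strictly positive, so any
positivity violation is a discretization artifact to be suppressed, not
modeled. The step straddling a jump is split so coefficients switch exactly
at the jump time. The chain and Brownian streams are spawned independently
from the master seed, so regime paths are reproducible independently of the
SDE resolution; ensemble replicates derive their seeds deterministically
from the master seed.

Defaults: dt = 0.01 time units, one recorded point per 10 steps (plus every
jump time), positivity floor 1e−8 × N(0) below which I is absorbed at 0.
Absorption stabilizes ln I diagnostics in extinction studies; persistence
and recurrence diagnostics instead run with the floor set to 0, because
under regime switching a supercritical model can spend long stretches in an
individually subcritical regime and dip transiently to very small I before
recovering — absorbing those dips would turn a recurrence property into a
spurious extinction. The inner fixed-regime loop is JIT-compiled with numba
when available; a pure-NumPy twin with identical semantics (verified against
the single-step reference in the tests) is used otherwise.

The deterministic subsystem is integrated with an adaptive stiff-capable
solver (LSODA, rtol 1e−10) and serves as the σ → 0, L = 1 oracle for the
stochastic integrator: the sup-norm gap between the two shrinks
proportionally as dt is halved, consistent with first-order weak error.

## Scenario generation

The built-in generator rejection-samples models from documented ranges —
rates μ, γ, β and switching rates in [0.05, 1], inflow targets S⁰ in
[10, 200], susceptibilities α in [0.5, 3] — and steers only the noise
intensities toward the requested verdict: σ_k a multiple 1.5–3 of βα_k for
strong-noise extinction, a fraction 0.3–0.7 of √(βα_k) for weak-noise
extinction (so σ² < βα holds automatically), 0.05–0.2 of √(βα_k) for
persistence. Accepted extinct scenarios must have their index at most 0.7
and persistent ones R₀ˢ at least 1.3: the theorems are asymptotic and
almost-sure, so a finite-horizon, finite-ensemble demonstration needs the
relevant exponent or bound comfortably away from criticality; scenarios
with indices near 1 are valid models but would need far longer horizons to
exhibit their verdict. These margins are part of the scenario definition,
not tuning knobs.

For positive-recurrence experiments the initial state is placed just inside
the invariant region but outside D — total population at upper − ε₃/2,
infectives at upper/4 — rather than below the infective floor ε₂, because
ε₂ is within an order of magnitude of the extinction-absorption floor and a
start there would conflate hitting-time measurement with numerically
spurious absorption.

## Estimating asymptotic statements

lim sup ln I(t)/t is estimated by the least-squares slope of ln I over a
window truncated at extinction (the full horizon in ensemble summaries,
since extinction typically precedes the half-way mark); lim inf (1/t)∫ I/N
by the trapezoidal time average over the second half of the horizon.
Theorem inequalities are asserted at two Monte-Carlo standard errors
(slopes) or as a ≥ 90% replicate-pass rate (persistence bound), because the
statements are almost-sure and asymptotic while simulations are finite.
Invariant-region compliance is checked against the envelope
max(Σ_k Š_k⁰, initial total) with tolerance 10 · dt · μ̌ · Σ Š⁰ for one-step
overshoot.

## Problem sizes

The verification suite uses 50 random generators (L ≤ 5) at chain horizon
1e4 for the stationary law; 100 noise-free parameter sets for the index
reduction; 10 models × 1e4 random states for the drift bound; 200
replicates at T = 200 for each extinction case; 100 replicates at T = 500
for persistence and at T = 1000 for recurrence, all at dt = 0.01. These
sizes make every Monte-Carlo margin wide (observed pass rates are 100%
against required 90–95%) while keeping the full run in tens of seconds.

## What the synthetic scenarios do and do not show

Generated scenarios exercise the model across its qualitative phases
(strong-noise extinction, weak-noise extinction, persistence) with
parameters in plausible per-unit-time ranges, but they are not calibrated
to any real HIV data: no age/behavior structure, no treatment dynamics, no
reporting noise, and group counts are small (n ≤ 4 in tests). Passing tests
therefore certify the mathematics and the implementation — indices computed
correctly, simulator consistent with theory — not epidemiological realism
of any particular parameterization.

## Known limitations

* Euler–Maruyama is first order; no Milstein or exact sampling.
* Strong-noise index is reported as undefined when any σ_k(l) = 0 rather
  than taking a limit.
* Reducible generators are accepted for path simulation but refused for any
  π-based index (the error names the unreachable regimes).
* Hitting times and occupation fractions are measured on the recorded grid,
  so they carry O(dt · record_every) resolution.
* The persistence lower bound is loose in practice (observed time averages
  exceed it by an order of magnitude); it is used as a one-sided check only.
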