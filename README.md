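# dsia — hybrid-switching differential-susceptibility epidemic model

`dsia` implements a stochastic DS-I-A (differential susceptibility /
infective / AIDS) epidemic model in which n susceptible groups with distinct
susceptibilities α_k feed one infective class, the effective contact rates
βα_k carry white noise of intensity σ_k, and *every* parameter switches
among L environmental regimes driven by a continuous-time Markov chain ξ(t)
(telegraph noise).  It is aimed at mathematical epidemiologists who want to
compute the closed-form extinction / persistence / positive-recurrence
indices of such hybrid models and check them against simulation.

## Model

Between regime switches the dynamics follow the Itô SDE (regime l fixed):

    dS_k = [ μ(l)(S_k⁰(l) − S_k) − β(l)α_k(l) S_k I / N ] dt − σ_k(l) (S_k I / N) dB_k
    dI   = [ Σ_k β(l)α_k(l) S_k I / N − (μ(l)+γ(l)) I ] dt + Σ_k σ_k(l) (S_k I / N) dB_k

with N = Σ_k S_k + I, standard incidence, and one Brownian motion B_k per
group shared (with opposite signs) between the S_k and I equations.  An
optional AIDS compartment dA = γI − δA is fed by I but never feeds back.
The regime process ξ(t) is a CTMC with generator Γ and stationary
distribution π.

The package computes, for any such model:

* the per-regime deterministic reproduction number
  R₀ = β Σ_k α_k S_k⁰ / ((μ+γ) Σ_k S_k⁰),
* two stochastic extinction indices R̄₀\* — a strong-noise form built from
  π-averages of β²α_k²/(2σ_k²), and a weak-noise form valid when
  σ_k² < βα_k — either one below 1 implies I(t) → 0 exponentially a.s.,
  with an explicit bound on lim sup ln I(t)/t,
* the stochastic persistence index R₀ˢ (a cube-root π-average construction)
  whose value above 1 implies persistence in the mean, with an explicit
  lower bound on the time-averaged infected fraction,
* the bounded domain D in which the process is positive recurrent when
  R₀ˢ > 1, and the drift bound M certifying global positive solutions.

The simulator samples regime paths exactly (exponential holding times),
integrates with Euler–Maruyama between jumps (splitting steps at each jump),
and runs seeded Monte-Carlo ensembles whose diagnostics — ln I decay slopes,
time-averaged I/N, invariant-region compliance, hitting times of D —
confront the theory.

## Worked example

Generate a persistent two-group, two-regime scenario, inspect its indices,
and verify persistence in the mean by simulation:

```python
import dsia

res = dsia.generate_scenario(n=2, L=2, target="persistent", seed=1)
model, rep = res.model, res.report
print("pi =", model.pi.round(4))
print("R0 per regime =", rep.r0_per_regime.round(3))
print("R0^s =", round(rep.persistence_index, 3),
      "| persistence bound =", round(rep.persistence_bound, 4))

init = dsia.EpidemicState(S=model.params(1).S0, I=5.0, regime=1)
settings = dsia.SimulationSettings(dt=0.01, horizon=500.0, seed=1,
                                   positivity_floor=0.0)
summ = dsia.run_ensemble(model, init, settings, 20)
mif = summ.mean_infected_fractions
print("mean infected fraction over [250, 500]:", round(mif.mean(), 3))
print("replicates above the bound:", int((mif >= rep.persistence_bound).sum()), "/ 20")
```

prints

```
pi = [0.5746 0.4254]
R0 per regime = [1.798 1.585]
R0^s = 1.347 | persistence bound = 0.0311
mean infected fraction over [250, 500]: 0.392
replicates above the bound: 20 / 20
```

The chain spends 57% / 43% of its time in the two regimes; both regimes are
individually supercritical and the π-averaged persistence index R₀ˢ = 1.35
predicts endemicity.  The simulated time-averaged infected fraction (0.39)
sits far above the guaranteed lower bound (0.031) in every replicate — the
bound is one-sided and conservative by construction.

The same workflow is available from a shell:

```
dsia scenario --target persistent --seed 1 --out model.json
dsia thresholds model.json
dsia simulate model.json --horizon 200 --out traj.csv
dsia diagnose model.json --replicates 50 --horizon 200
```

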