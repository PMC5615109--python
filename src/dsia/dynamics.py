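"""Trajectory integration for the switching DS-I-A model.

Between regime jumps the model is a fixed-coefficient SDE

    dS_k = [mu (S_k^0 - S_k) - beta alpha_k S_k I / N] dt
           - sigma_k (S_k I / N) dB_k,
    dI   = [sum_k beta alpha_k S_k I / N - (mu + gamma) I] dt
           + sum_k sigma_k (S_k I / N) dB_k,

with one Brownian motion per susceptibility group shared (opposite signs)
between the S_k and I equations, so white noise moves mass between
compartments but injects none into the total N.  Jump times of the
environmental chain are drawn exactly (exponential holding times, not
per-step Bernoulli approximations) and each Euler-Maruyama step straddling
a jump is split so coefficients switch exactly at the jump.

Discretization is Euler-Maruyama in "full truncation" style: coefficients
are evaluated at the nonnegatively clamped incoming state and outgoing
components are clamped at zero.  The exact solution is strictly positive,
so positivity violations are discretization artifacts to be suppressed.
Once I falls below a small positivity floor it is absorbed at zero (the
I = 0 face is invariant for the exact dynamics, and absorption stabilizes
ln I diagnostics).

The optional AIDS compartment dA = gamma I - delta A is fed by I but never
feeds back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .regimes import MarkovGenerator, sample_regime_path
from .thresholds import RegimeParameters, SwitchingModel

__all__ = [
    "EpidemicState",
    "SimulationSettings",
    "Trajectory",
    "EnsembleSummary",
    "step_em",
    "simulate_hybrid",
    "simulate_deterministic",
    "run_ensemble",
]


@dataclass(frozen=True)
class EpidemicState:
    """Population state: susceptibles by group, infectives, optional AIDS."""

    S: np.ndarray
    I: float
    regime: int = 1
    t: float = 0.0
    A: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", np.atleast_1d(np.asarray(self.S, dtype=float)))
        if np.any(self.S < 0) or self.I < 0 or (self.A is not None and self.A < 0):
            raise ValueError("populations must be nonnegative")

    @property
    def N(self) -> float:
        return float(self.S.sum() + self.I)


@dataclass(frozen=True)
class SimulationSettings:
    """Step size, horizon, seeding and output thinning.

    ``positivity_floor=None`` resolves to 1e-8 times the initial total
    population at simulation start.
    """

    dt: float = 0.01
    horizon: float = 100.0
    seed: int = 0
    positivity_floor: float | None = None
    record_every: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.horizon < self.dt or self.record_every < 1:
            raise ValueError("require dt > 0, horizon >= dt, record_every >= 1")
        if self.positivity_floor is not None and self.positivity_floor < 0:
            raise ValueError("positivity_floor must be nonnegative")


@dataclass(frozen=True)
class Trajectory:
    """Recorded sample path of one simulation run.

    ``S`` has shape (T, n); ``regimes`` holds the 1-based active regime at
    each recorded time; ``extinct_at`` is the first time I hit the
    positivity floor, or None.
    """

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    regimes: np.ndarray
    settings: SimulationSettings
    A: np.ndarray | None = None
    extinct_at: float | None = None

    @property
    def N(self) -> np.ndarray:
        return self.S.sum(axis=1) + self.I

    @property
    def n(self) -> int:
        return self.S.shape[1]

    def final_state(self) -> EpidemicState:
        return EpidemicState(
            S=self.S[-1],
            I=float(self.I[-1]),
            regime=int(self.regimes[-1]),
            t=float(self.times[-1]),
            A=None if self.A is None else float(self.A[-1]),
        )

    def to_dataframe(self):
        import pandas as pd

        data = {"time": self.times, "regime": self.regimes}
        for k in range(self.n):
            data[f"S_{k + 1}"] = self.S[:, k]
        data["I"] = self.I
        if self.A is not None:
            data["A"] = self.A
        data["N"] = self.N
        return pd.DataFrame(data)


def _em_interval_py(S, I, A, track_a, mu, gamma, beta, delta, S0, alpha, sigma,
                    h, dW, floor, extinct):
    """Integrate one fixed-regime stretch; returns per-substep states.

    Reference NumPy implementation; a numba-compiled twin is used when
    available.  Semantics must match :func:`step_em` exactly.
    """
    m, n = dW.shape
    S_out = np.empty((m, n))
    I_out = np.empty(m)
    A_out = np.empty(m)
    extinct_idx = -1
    for i in range(m):
        Sc = np.maximum(S, 0.0)
        Ic = max(I, 0.0)
        N = Sc.sum() + Ic
        if N > 0.0:
            frac = Sc * (Ic / N)
        elif Ic == 0.0:
            frac = np.zeros(n)
        else:
            raise ZeroDivisionError("total population reached zero with I > 0")
        inc = beta * alpha * frac
        noise = sigma * frac * dW[i]
        S = Sc + (mu * (S0 - Sc) - inc) * h[i] - noise
        I = Ic + (inc.sum() - (mu + gamma) * Ic) * h[i] + noise.sum()
        np.maximum(S, 0.0, out=S)
        I = max(I, 0.0)
        if track_a:
            A = max(A + (gamma * Ic - delta * A) * h[i], 0.0)
        if not extinct and I < floor:
            I = 0.0
            extinct = True
            extinct_idx = i
        S_out[i] = S
        I_out[i] = I
        A_out[i] = A
    return S_out, I_out, A_out, extinct_idx


try:  # optional JIT acceleration of the inner loop
    from numba import njit

    @njit(cache=True)
    def _em_interval_nb(S, I, A, track_a, mu, gamma, beta, delta, S0, alpha, sigma,
                        h, dW, floor, extinct):
        m, n = dW.shape
        S = S.copy()
        S_out = np.empty((m, n))
        I_out = np.empty(m)
        A_out = np.empty(m)
        extinct_idx = -1
        for i in range(m):
            Ic = max(I, 0.0)
            N = Ic
            for k in range(n):
                if S[k] < 0.0:
                    S[k] = 0.0
                N += S[k]
            inc_sum = 0.0
            noise_sum = 0.0
            Snew = np.empty(n)
            for k in range(n):
                frac = S[k] * Ic / N if N > 0.0 else 0.0
                inc = beta * alpha[k] * frac
                noise = sigma[k] * frac * dW[i, k]
                inc_sum += inc
                noise_sum += noise
                Snew[k] = S[k] + (mu * (S0[k] - S[k]) - inc) * h[i] - noise
                if Snew[k] < 0.0:
                    Snew[k] = 0.0
            Inew = Ic + (inc_sum - (mu + gamma) * Ic) * h[i] + noise_sum
            if Inew < 0.0:
                Inew = 0.0
            if track_a:
                A = A + (gamma * Ic - delta * A) * h[i]
                if A < 0.0:
                    A = 0.0
            if not extinct and Inew < floor:
                Inew = 0.0
                extinct = True
                extinct_idx = i
            S = Snew
            I = Inew
            for k in range(n):
                S_out[i, k] = S[k]
            I_out[i] = I
            A_out[i] = A
        return S_out, I_out, A_out, extinct_idx

    def _em_interval(S, I, A, track_a, p: RegimeParameters, h, dW, floor, extinct):
        if I > 0.0 and max(np.maximum(S, 0.0).sum() + max(I, 0.0), 0.0) <= 0.0:
            raise ZeroDivisionError("total population reached zero with I > 0")
        delta = p.delta if p.delta is not None else 0.0
        return _em_interval_nb(
            np.asarray(S, float), float(I), float(A or 0.0), bool(track_a),
            p.mu, p.gamma, p.beta, delta, p.S0, p.alpha, p.sigma,
            np.asarray(h, float), np.asarray(dW, float), float(floor), bool(extinct),
        )

except ImportError:  # pragma: no cover - exercised only without numba

    def _em_interval(S, I, A, track_a, p: RegimeParameters, h, dW, floor, extinct):
        delta = p.delta if p.delta is not None else 0.0
        return _em_interval_py(
            np.asarray(S, float), float(I), float(A or 0.0), bool(track_a),
            p.mu, p.gamma, p.beta, delta, p.S0, p.alpha, p.sigma,
            np.asarray(h, float), np.asarray(dW, float), float(floor), bool(extinct),
        )


def step_em(state: EpidemicState, p: RegimeParameters, dt: float, dW) -> EpidemicState:
    """One Euler-Maruyama step with caller-supplied Gaussian increments.

    ``dW`` must be a length-n vector of Normal(0, dt) draws.  Coefficients
    are evaluated at the nonnegatively clamped incoming state; outgoing
    components are clamped at zero.  Raises if N <= 0 with I > 0 (incidence
    terms undefined).
    """
    dW = np.atleast_1d(np.asarray(dW, dtype=float))
    Sc = np.maximum(state.S, 0.0)
    Ic = max(state.I, 0.0)
    N = Sc.sum() + Ic
    if N <= 0.0:
        raise ValueError("cannot form incidence: total population N <= 0 on entry")
    frac = Sc * (Ic / N)
    inc = p.beta * p.alpha * frac
    noise = p.sigma * frac * dW
    S_new = np.maximum(Sc + (p.mu * (p.S0 - Sc) - inc) * dt - noise, 0.0)
    I_new = max(Ic + (inc.sum() - (p.mu + p.gamma) * Ic) * dt + noise.sum(), 0.0)
    A_new = state.A
    if state.A is not None:
        delta = p.delta if p.delta is not None else 0.0
        A_new = max(state.A + (p.gamma * Ic - delta * state.A) * dt, 0.0)
    return EpidemicState(S=S_new, I=I_new, regime=state.regime, t=state.t + dt, A=A_new)


def _substeps(a: float, b: float, dt: float) -> np.ndarray:
    """Step sizes covering [a, b]: full dt steps plus a final partial one."""
    span = b - a
    m = int(span / dt)
    rem = span - m * dt
    if rem > 1e-12 * max(1.0, dt):
        return np.concatenate([np.full(m, dt), [rem]])
    if m == 0:
        return np.array([span])
    return np.full(m, dt)


def simulate_hybrid(
    model: SwitchingModel, init: EpidemicState, settings: SimulationSettings
) -> Trajectory:
    """Simulate the regime-switching SDE on [0, horizon].

    The regime path is sampled first from its own random stream, then the
    SDE is integrated with :func:`step_em` semantics between jumps, splitting
    the step that straddles each jump so coefficients switch exactly at the
    jump time.  The chain and Brownian streams are spawned independently
    from the master seed, so the regime path is reproducible regardless of
    dt.  States are recorded every ``record_every`` steps and at every jump.
    """
    chain_ss, brown_ss = np.random.SeedSequence(settings.seed).spawn(2)
    path = sample_regime_path(model.generator, init.regime, settings.horizon, chain_ss)
    rng = np.random.default_rng(brown_ss)
    n = model.n
    track_a = init.A is not None
    floor = settings.positivity_floor
    if floor is None:
        floor = 1e-8 * init.N

    times = [0.0]
    S_rec = [np.asarray(init.S, float)]
    I_rec = [float(init.I)]
    A_rec = [float(init.A)] if track_a else None
    reg_rec = [int(init.regime)]

    S, I = np.asarray(init.S, float), float(init.I)
    A = float(init.A) if track_a else 0.0
    extinct = I <= floor
    extinct_at = 0.0 if extinct else None
    if extinct:
        I = 0.0
    t = 0.0
    step_count = 0
    for a, b, regime in path.intervals():
        if b <= a:
            continue
        p = model.params(regime)
        h = _substeps(a, b, settings.dt)
        dW = rng.standard_normal((len(h), n)) * np.sqrt(h)[:, None]
        S_out, I_out, A_out, ext_idx = _em_interval(
            S, I, A, track_a, p, h, dW, floor, extinct
        )
        if ext_idx >= 0:
            extinct = True
            extinct_at = a + float(h[: ext_idx + 1].sum())
        t_sub = a + np.cumsum(h)
        for i in range(len(h)):
            step_count += 1
            if step_count % settings.record_every == 0 or i == len(h) - 1:
                times.append(t_sub[i])
                S_rec.append(S_out[i])
                I_rec.append(I_out[i])
                reg_rec.append(regime)
                if track_a:
                    A_rec.append(A_out[i])
        S, I = S_out[-1], I_out[-1]
        if track_a:
            A = A_out[-1]
        t = b
    return Trajectory(
        times=np.array(times),
        S=np.vstack(S_rec),
        I=np.array(I_rec),
        regimes=np.array(reg_rec, dtype=int),
        settings=settings,
        A=None if A_rec is None else np.array(A_rec),
        extinct_at=extinct_at,
    )


def _ode_rhs(t, y, p: RegimeParameters, track_a: bool):
    n = p.n
    S, I = y[:n], y[n]
    N = S.sum() + I
    inc = p.beta * p.alpha * S * I / N if N > 0 else np.zeros(n)
    dS = p.mu * (p.S0 - S) - inc
    dI = inc.sum() - (p.mu + p.gamma) * I
    if track_a:
        delta = p.delta if p.delta is not None else 0.0
        return np.concatenate([dS, [dI, p.gamma * I - delta * y[n + 1]]])
    return np.concatenate([dS, [dI]])


def simulate_deterministic(
    p: RegimeParameters, init: EpidemicState, settings: SimulationSettings
) -> Trajectory:
    """Integrate the noise-free single-regime system on the recording grid.

    Uses an adaptive Runge-Kutta scheme at tight tolerance; the optional
    AIDS compartment is appended when the initial state tracks it.
    """
    track_a = init.A is not None
    y0 = np.concatenate([init.S, [init.I, init.A] if track_a else [init.I]])
    t_eval = np.arange(0.0, settings.horizon + 1e-12, settings.dt * settings.record_every)
    if t_eval[-1] < settings.horizon:
        t_eval = np.append(t_eval, settings.horizon)
    sol = solve_ivp(
        _ode_rhs,
        (0.0, settings.horizon),
        y0,
        t_eval=t_eval,
        args=(p, track_a),
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    n = p.n
    return Trajectory(
        times=sol.t,
        S=sol.y[:n].T,
        I=sol.y[n],
        regimes=np.full(len(sol.t), init.regime, dtype=int),
        settings=settings,
        A=sol.y[n + 1] if track_a else None,
        extinct_at=None,
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-replicate outcomes and pooled summaries of a hybrid ensemble.

    Diagnostic windows default to the second half of the horizon (the
    usable finite-horizon proxy for the asymptotic statements).
    ``hit_times`` is filled only when a recurrence domain was supplied.
    """

    replicates: int
    seeds: np.ndarray
    terminal_I: np.ndarray
    terminal_S: np.ndarray
    extinction_times: np.ndarray  # NaN where the replicate never went extinct
    extinct_fraction: float
    slopes: np.ndarray  # ln I decay rates, NaN where not estimable
    mean_infected_fractions: np.ndarray
    envelope_violations: np.ndarray
    occupation: np.ndarray  # pooled regime occupation fractions
    hit_times: np.ndarray | None = None

    def summary(self) -> dict:
        def _stats(x):
            x = x[np.isfinite(x)]
            if len(x) == 0:
                return {"mean": None, "q25": None, "median": None, "q75": None}
            return {
                "mean": float(np.mean(x)),
                "q25": float(np.quantile(x, 0.25)),
                "median": float(np.median(x)),
                "q75": float(np.quantile(x, 0.75)),
            }

        return {
            "replicates": self.replicates,
            "extinct_fraction": self.extinct_fraction,
            "terminal_I": _stats(self.terminal_I),
            "extinction_time": _stats(self.extinction_times),
            "ln_I_slope": _stats(self.slopes),
            "mean_infected_fraction": _stats(self.mean_infected_fractions),
            "envelope_violations_total": int(self.envelope_violations.sum()),
            "occupation": self.occupation.tolist(),
        }


def run_ensemble(
    model: SwitchingModel,
    init: EpidemicState,
    settings: SimulationSettings,
    replicates: int,
    domain=None,
    keep_trajectories: bool = False,
):
    """Run ``replicates`` independent hybrid simulations and pool diagnostics.

    Replicate seeds are derived deterministically from the master seed, so
    the same master seed reproduces the whole ensemble.  When ``domain`` (a
    :class:`~dsia.diagnostics.RecurrenceDomain`) is given, first hitting
    times of the domain are recorded (NaN if never hit).  Returns the
    summary, or ``(summary, trajectories)`` with ``keep_trajectories``.
    """
    from . import diagnostics  # deferred: diagnostics consumes Trajectory

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(settings.seed).spawn(replicates)
    seeds = np.array([int(c.generate_state(1)[0] % 2**31) for c in children])
    # time averages over the settled second half; ln I slopes over the whole
    # run (they are truncated at extinction, which can precede the half-way
    # mark under a fast extinction scenario)
    window = (settings.horizon / 2.0, settings.horizon)
    slope_window = (0.0, settings.horizon)

    terminal_I = np.empty(replicates)
    terminal_S = np.empty((replicates, model.n))
    ext_times = np.full(replicates, np.nan)
    slopes = np.full(replicates, np.nan)
    mif = np.empty(replicates)
    violations = np.empty(replicates, dtype=int)
    occ_sum = np.zeros(model.L)
    hit_times = np.full(replicates, np.nan) if domain is not None else None
    trajectories = []

    for r in range(replicates):
        traj = simulate_hybrid(model, init, replace(settings, seed=int(seeds[r])))
        terminal_I[r] = traj.I[-1]
        terminal_S[r] = traj.S[-1]
        if traj.extinct_at is not None:
            ext_times[r] = traj.extinct_at
        try:
            slopes[r] = diagnostics.extinction_slope(traj, slope_window)
        except ValueError:
            pass
        mif[r] = diagnostics.mean_infected_fraction(traj, window)
        violations[r] = diagnostics.check_envelope(traj, model)
        occ_sum += np.bincount(traj.regimes - 1, minlength=model.L)
        if domain is not None:
            hit = diagnostics.hitting_time(traj, domain)
            if hit is not None:
                hit_times[r] = hit
        if keep_trajectories:
            trajectories.append(traj)

    summary = EnsembleSummary(
        replicates=replicates,
        seeds=seeds,
        terminal_I=terminal_I,
        terminal_S=terminal_S,
        extinction_times=ext_times,
        extinct_fraction=float(np.mean(~np.isnan(ext_times))),
        slopes=slopes,
        mean_infected_fractions=mif,
        envelope_violations=violations,
        occupation=occ_sum / occ_sum.sum(),
        hit_times=hit_times,
    )
    if keep_trajectories:
        return summary, trajectories
    return summary
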