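"""Empirical counterparts of the extinction / persistence / recurrence theory.

The closed-form results are almost-sure asymptotic statements; simulations
are finite.  This module estimates each limiting quantity by a
finite-window statistic:

* limsup ln I(t)/t  -> least-squares slope of ln I over a window,
* liminf (1/t) int I/N -> trapezoidal time average of I/N over a window,
* the invariant-region statement -> a violation counter against the
  envelope max(sum_k max_l S_k^0(l), initial total),
* positive recurrence -> first hitting time of the bounded domain D whose
  construction (epsilon constants, Lyapunov weight M, margin constant K̂)
  follows the recurrence proof,
* and the sufficient conditions themselves -> a categorical verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .thresholds import (
    SwitchingModel,
    ThresholdReport,
    _persistence_pieces,
    persistence_index,
)

__all__ = [
    "RecurrenceDomain",
    "DiagnosticReport",
    "extinction_slope",
    "mean_infected_fraction",
    "check_envelope",
    "recurrence_domain",
    "hitting_time",
    "classify_outcome",
]


@dataclass(frozen=True)
class RecurrenceDomain:
    """Bounded open domain D in which the process is positive recurrent.

    D = { n eps1 < sum S_k < upper - eps2 - eps3,
          eps2 < I < upper - n eps1 - eps3,
          n eps1 + eps2 < sum S_k + I < upper - eps3 },

    with upper = sum_k max_l S_k^0(l), eps2 = (n eps1)^2 and eps3 = eps2^2.
    """

    eps1: float
    eps2: float
    eps3: float
    n: int
    upper: float
    K_hat: float
    M_weight: float
    lambda_: float

    def __post_init__(self) -> None:
        if not math.isclose(self.eps2, (self.n * self.eps1) ** 2, rel_tol=1e-9):
            raise ValueError("eps2 must equal (n*eps1)^2")
        if not math.isclose(self.eps3, self.eps2**2, rel_tol=1e-9):
            raise ValueError("eps3 must equal eps2^2")
        if self.n * self.eps1 + self.eps2 >= self.upper - self.eps3:
            raise ValueError("domain is empty: n*eps1 + eps2 >= upper - eps3")

    def contains(self, S, I) -> bool:
        """Strict membership of a single state (boundary counts as outside)."""
        S_sum = float(np.sum(S))
        total = S_sum + I
        return (
            self.n * self.eps1 < S_sum < self.upper - self.eps2 - self.eps3
            and self.eps2 < I < self.upper - self.n * self.eps1 - self.eps3
            and self.n * self.eps1 + self.eps2 < total < self.upper - self.eps3
        )


@dataclass(frozen=True)
class DiagnosticReport:
    """Finite-horizon estimates of the quantities the theory bounds."""

    extinction_slope: float  # NaN when not estimable
    mean_infected_fraction: float
    envelope_violations: int
    occupation: np.ndarray
    hit_time_D: float | None = None


def extinction_slope(traj, window) -> float:
    """Least-squares slope of ln I(t) over a time window (per unit time).

    The window is truncated at the extinction time (ln 0 is unusable); a
    window left empty, or with fewer than two points, raises ValueError
    ("not estimable").
    """
    lo, hi = window
    if traj.extinct_at is not None:
        hi = min(hi, traj.extinct_at)
    mask = (traj.times >= lo) & (traj.times <= hi) & (traj.I > 0)
    if mask.sum() < 2:
        raise ValueError(f"slope not estimable: window [{lo}, {hi}] has {mask.sum()} usable points")
    slope, _ = np.polyfit(traj.times[mask], np.log(traj.I[mask]), 1)
    return float(slope)


def mean_infected_fraction(traj, window) -> float:
    """Trapezoidal time average of I(t)/N(t) over a window; lies in [0, 1]."""
    lo, hi = window
    mask = (traj.times >= lo) & (traj.times <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window [{lo}, {hi}] holds fewer than two recorded points")
    t = traj.times[mask]
    N = traj.N[mask]
    if np.any(N <= 0):
        raise ValueError("total population N reached zero inside the window")
    frac = traj.I[mask] / N
    return float(np.trapezoid(frac, t) / (t[-1] - t[0]))


def check_envelope(traj, model: SwitchingModel, tol: float | None = None) -> int:
    """Count recorded states breaching the invariant-region envelope.

    The exact dynamics never exceed max(sum_k max_l S_k^0(l), initial total)
    in total population, and never go negative.  The default tolerance
    10 * dt * (max recruitment rate) absorbs one-step discretization
    overshoot.
    """
    upper = float(model._S0.max(axis=0).sum())
    bound = max(upper, float(traj.S[0].sum() + traj.I[0]))
    if tol is None:
        tol = 10.0 * traj.settings.dt * float(model._mu.max()) * upper
    over = int(np.sum(traj.N > bound + tol))
    negative = int(np.sum(traj.S < 0)) + int(np.sum(traj.I < 0))
    if traj.A is not None:
        negative += int(np.sum(traj.A < 0))
    return over + negative


def recurrence_domain(model: SwitchingModel, safety: float = 0.5) -> RecurrenceDomain:
    """Construct the recurrence domain D for a persistent model (R0^s > 1).

    lambda = sum_l pi_l (mu + gamma + sum_k sigma_k^2/2) * (R0^s - 1) must be
    positive; the Lyapunov weight is M = (2 + (n+1) mu_max +
    sum_k sigma_k_max^2 / 2) / lambda and K̂ = beta_max (M sum_k c_k
    alpha_k_max + sum_k alpha_k_max) - 2.  eps1 is the largest value
    compatible with the three smallness conditions of the construction
    (each trivially satisfied when K̂ + 1 <= 0), shrunk by ``safety`` and
    further halved until the domain is nonempty; eps2 = (n eps1)^2,
    eps3 = eps2^2.
    """
    r0s, c, _ = persistence_index(model)
    if r0s <= 1.0:
        raise ValueError(f"recurrence domain undefined: R0^s = {r0s:.6g} <= 1")
    _, _, d2, _ = _persistence_pieces(model)
    lam = d2 * (r0s - 1.0)
    n = model.n
    mu_max = float(model._mu.max())
    mu_min = float(model._mu.min())
    gamma_min = float(model._gamma.min())
    beta_max = float(model._beta.max())
    alpha_max = model._alpha.max(axis=0)
    S0_min = model._S0.min(axis=0)
    upper = float(model._S0.max(axis=0).sum())
    sigma2_max_sum = float((model._sigma**2).max(axis=0).sum())

    M = (2.0 + (n + 1) * mu_max + 0.5 * sigma2_max_sum) / lam
    contact = beta_max * (M * float(c @ alpha_max) + float(alpha_max.sum()))
    K_hat = contact - 2.0

    bounds = [1.0 / (n * contact)]  # the incidence-smallness condition
    if K_hat + 1.0 > 0:
        bounds.append(mu_min * float(S0_min.min()) / (K_hat + 1.0))
        bounds.append(math.sqrt(gamma_min / (K_hat + 1.0)) / n)
    eps1 = safety * min(bounds)
    while n * eps1 + (n * eps1) ** 2 >= upper - (n * eps1) ** 4:
        eps1 *= 0.5
    eps2 = (n * eps1) ** 2
    return RecurrenceDomain(
        eps1=eps1, eps2=eps2, eps3=eps2**2, n=n, upper=upper,
        K_hat=K_hat, M_weight=M, lambda_=lam,
    )


def hitting_time(traj, D: RecurrenceDomain) -> float | None:
    """First recorded time at which the state lies strictly inside D.

    Returns 0.0 when the initial state is already inside, None when the
    trajectory never enters D within its horizon.  Boundary states count as
    outside (the recurrence statement concerns the open domain).
    """
    S_sum = traj.S.sum(axis=1)
    total = S_sum + traj.I
    inside = (
        (D.n * D.eps1 < S_sum)
        & (S_sum < D.upper - D.eps2 - D.eps3)
        & (D.eps2 < traj.I)
        & (traj.I < D.upper - D.n * D.eps1 - D.eps3)
        & (D.n * D.eps1 + D.eps2 < total)
        & (total < D.upper - D.eps3)
    )
    idx = np.flatnonzero(inside)
    if len(idx) == 0:
        return None
    return float(traj.times[idx[0]])


def classify_outcome(report: ThresholdReport) -> str:
    """Categorical verdict from the sufficient conditions.

    Checks, in order: strong-noise extinction (strong index < 1), weak-noise
    extinction (condition holds and weak index < 1), persistence
    (R0^s > 1).  The conditions are sufficient, not exhaustive, so
    "indeterminate" is a legitimate outcome.
    """
    if report.strong_defined and report.extinction_strong < 1.0:
        return "extinct_strong"
    if report.weak_condition_holds and report.extinction_weak < 1.0:
        return "extinct_weak"
    if report.persistence_index > 1.0:
        return "persistent"
    return "indeterminate"


def diagnose(traj, model: SwitchingModel, window=None, domain=None) -> DiagnosticReport:
    """Bundle the per-trajectory diagnostics into one report."""
    from .regimes import occupation_fractions  # cheap; avoids top-level cycle concerns

    if window is None:
        window = (traj.times[-1] / 2.0, traj.times[-1])
    try:
        slope = extinction_slope(traj, window)
    except ValueError:
        slope = math.nan
    occ = np.bincount(traj.regimes - 1, minlength=model.L).astype(float)
    return DiagnosticReport(
        extinction_slope=slope,
        mean_infected_fraction=mean_infected_fraction(traj, window),
        envelope_violations=check_envelope(traj, model),
        occupation=occ / occ.sum(),
        hit_time_D=None if domain is None else hitting_time(traj, domain),
    )
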