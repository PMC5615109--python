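"""Closed-form threshold indices for the switching DS-I-A model.

The model divides susceptibles into n groups with distinct susceptibilities
alpha_k feeding one infective class I through standard incidence
beta alpha_k S_k I / N, with recruitment mu S_k^0, natural death mu, and
progression gamma out of I.  Every rate may depend on the current
environmental regime l in {1, ..., L}, and each effective contact rate
beta alpha_k additionally carries a Brownian perturbation of intensity
sigma_k.  This module computes:

* the deterministic basic reproduction number R0 of one regime,
* the two stochastic extinction indices (strong- and weak-noise cases) whose
  value below 1 implies almost-sure exponential extinction of I, together
  with the corresponding upper bounds on limsup ln I(t)/t,
* the stochastic persistence index R0^s with its Lyapunov coefficients c_k,
  a_k, and the lower bound on the time-averaged infected fraction that holds
  when R0^s > 1,
* the drift bound M that dominates LV for the positivity Lyapunov function
  V = sum_k (S_k - 1 - ln S_k) + (I - 1 - ln I).

All regime averages are taken under the stationary distribution pi of the
regime chain; "check" envelopes (max over regimes) and "hat" envelopes (min
over regimes) are coordinate-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .regimes import MarkovGenerator, stationary_distribution, validate_generator

__all__ = [
    "RegimeParameters",
    "SwitchingModel",
    "ThresholdReport",
    "deterministic_r0",
    "extinction_index_strong",
    "extinction_index_weak",
    "extinction_exponent_bound",
    "persistence_index",
    "persistence_lower_bound",
    "drift_bound_M",
    "lyapunov_drift_V",
    "compute_thresholds",
]


@dataclass(frozen=True)
class RegimeParameters:
    """All rate constants of one environmental regime.

    Parameters
    ----------
    mu : recruitment/natural-death rate (per unit time).
    gamma : progression rate out of the infective class (per unit time).
    beta : infection probability per new partner (dimensionless).
    S0 : length-n inflow targets S_k^0 (individuals); group k is recruited
        at rate mu * S_k^0.
    alpha : length-n susceptibilities (dimensionless).
    sigma : length-n white-noise intensities on beta*alpha_k (per sqrt(time)).
    delta : removal rate of the optional AIDS compartment (per unit time).
    """

    mu: float
    gamma: float
    beta: float
    S0: np.ndarray
    alpha: np.ndarray
    sigma: np.ndarray
    delta: float | None = None

    def __post_init__(self) -> None:
        for name in ("S0", "alpha", "sigma"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if not (self.mu > 0 and self.gamma > 0 and self.beta >= 0):
            raise ValueError("mu, gamma must be positive and beta nonnegative")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive when given")
        n = len(self.S0)
        if len(self.alpha) != n or len(self.sigma) != n:
            raise ValueError("S0, alpha, sigma must share length n")
        if np.any(self.S0 <= 0) or np.any(self.alpha <= 0) or np.any(self.sigma < 0):
            raise ValueError("require S0 > 0, alpha > 0, sigma >= 0")

    @property
    def n(self) -> int:
        return len(self.S0)


@dataclass(frozen=True)
class SwitchingModel:
    """L parameter regimes coupled by a Markov generator."""

    generator: MarkovGenerator
    regimes: tuple[RegimeParameters, ...]

    def __post_init__(self) -> None:
        regimes = tuple(self.regimes)
        object.__setattr__(self, "regimes", regimes)
        if len(regimes) != self.generator.L:
            raise ValueError(
                f"{len(regimes)} parameter regimes for an L={self.generator.L} generator"
            )
        ns = {r.n for r in regimes}
        if len(ns) != 1:
            raise ValueError(f"all regimes must share the same group count n, got {sorted(ns)}")

    @property
    def L(self) -> int:
        return self.generator.L

    @property
    def n(self) -> int:
        return self.regimes[0].n

    @cached_property
    def pi(self) -> np.ndarray:
        """Stationary distribution of the regime chain (raises if reducible)."""
        return stationary_distribution(self.generator).pi

    def params(self, regime: int) -> RegimeParameters:
        """Parameters of a 1-based regime index."""
        return self.regimes[regime - 1]

    # stacked per-regime parameter arrays, shape (L,) or (L, n)
    @cached_property
    def _mu(self):
        return np.array([r.mu for r in self.regimes])

    @cached_property
    def _gamma(self):
        return np.array([r.gamma for r in self.regimes])

    @cached_property
    def _beta(self):
        return np.array([r.beta for r in self.regimes])

    @cached_property
    def _S0(self):
        return np.stack([r.S0 for r in self.regimes])

    @cached_property
    def _alpha(self):
        return np.stack([r.alpha for r in self.regimes])

    @cached_property
    def _sigma(self):
        return np.stack([r.sigma for r in self.regimes])


def switching_model(generator_rates, regimes) -> SwitchingModel:
    """Convenience constructor validating the generator matrix."""
    return SwitchingModel(generator=validate_generator(generator_rates), regimes=tuple(regimes))


@dataclass(frozen=True)
class ThresholdReport:
    """Every closed-form index and bound for one model.

    ``extinction_strong`` is NaN with ``strong_defined`` False when some
    sigma_k(l) = 0 (the strong-noise index divides by sigma_k^2);
    ``weak_condition_holds`` records whether sigma_k^2(l) < beta(l) alpha_k(l)
    for every k, l, which is the hypothesis under which the weak-noise index
    is conclusive.
    """

    r0_per_regime: np.ndarray
    extinction_strong: float
    strong_defined: bool
    extinction_weak: float
    weak_condition_holds: bool
    extinction_exponent_strong: float
    extinction_exponent_weak: float
    persistence_index: float
    c: np.ndarray
    a: np.ndarray
    persistence_bound: float
    lambda_: float
    drift_bound_M: float


def deterministic_r0(p: RegimeParameters) -> float:
    """Basic reproduction number of one regime without noise.

    R0 = beta * sum_k alpha_k S_k^0 / ((mu + gamma) * sum_k S_k^0): the
    S0-weighted mean effective contact rate times the mean infectious period.
    """
    return float(p.beta * (p.alpha @ p.S0) / ((p.mu + p.gamma) * p.S0.sum()))


def extinction_index_strong(model: SwitchingModel) -> tuple[float, bool]:
    """Strong-noise extinction index (case (i)).

    R = [sum_k sum_l pi_l beta^2(l) alpha_k^2(l) / (2 sigma_k^2(l))]
        / [sum_l pi_l (mu(l) + gamma(l))].

    Undefined (NaN, flag False) when any sigma_k(l) = 0.  A value below 1
    implies I(t) -> 0 exponentially fast with probability one, however large
    the deterministic R0: strong noise alone can suppress the epidemic.
    """
    pi = model.pi
    if np.any(model._sigma == 0):
        return math.nan, False
    num = float(np.sum(pi[:, None] * model._beta[:, None] ** 2 * model._alpha**2
                       / (2.0 * model._sigma**2)))
    den = float(pi @ (model._mu + model._gamma))
    return num / den, True


def extinction_index_weak(model: SwitchingModel) -> tuple[float, bool]:
    """Weak-noise extinction index (case (ii)) and its applicability flag.

    R = [sum_k sum_l pi_l beta(l) alpha_k(l)]
        / [sum_l pi_l (mu(l) + gamma(l) + sum_k sigma_k^2(l)/2)].

    The flag states whether sigma_k^2(l) < beta(l) alpha_k(l) holds for
    every k and l; the extinction conclusion requires both the flag and the
    index below 1.  The index itself is always computed.
    """
    pi = model.pi
    num = float(np.sum(pi[:, None] * model._beta[:, None] * model._alpha))
    den = float(pi @ (model._mu + model._gamma + 0.5 * (model._sigma**2).sum(axis=1)))
    holds = bool(np.all(model._sigma**2 < model._beta[:, None] * model._alpha))
    return num / den, holds


def extinction_exponent_bound(model: SwitchingModel, case: str) -> float:
    """Almost-sure upper bound on limsup ln I(t)/t for the given case.

    Strong case: sum_l pi_l (mu + gamma) * (index - 1);
    weak case:   sum_l pi_l (mu + gamma + sum_k sigma_k^2/2) * (index - 1).
    Negative exactly when the corresponding index is below 1.
    """
    pi = model.pi
    if case == "strong":
        index, defined = extinction_index_strong(model)
        if not defined:
            return math.nan
        rate = float(pi @ (model._mu + model._gamma))
    elif case == "weak":
        index, _ = extinction_index_weak(model)
        rate = float(pi @ (model._mu + model._gamma + 0.5 * (model._sigma**2).sum(axis=1)))
    else:
        raise ValueError(f"case must be 'strong' or 'weak', got {case!r}")
    return rate * (index - 1.0)


def _persistence_pieces(model: SwitchingModel):
    """Shared numerators/denominators of R0^s, c_k and a_k.

    num_k = sum_l pi_l (mu^2 beta alpha_k S_k^0)^(1/3)     (length n)
    d1_k  = sum_l pi_l (mu + sigma_k^2/2)                  (length n)
    d2    = sum_l pi_l (mu + gamma + sum_j sigma_j^2/2)
    d3    = sum_l pi_l (mu sum_j S_j^0)
    """
    pi = model.pi
    num = pi @ (model._mu[:, None] ** 2 * model._beta[:, None]
                * model._alpha * model._S0) ** (1.0 / 3.0)
    d1 = pi @ (model._mu[:, None] + 0.5 * model._sigma**2)
    d2 = float(pi @ (model._mu + model._gamma + 0.5 * (model._sigma**2).sum(axis=1)))
    d3 = float(pi @ (model._mu * model._S0.sum(axis=1)))
    return num, d1, d2, d3


def persistence_index(model: SwitchingModel) -> tuple[float, np.ndarray, np.ndarray]:
    """Stochastic persistence index R0^s and its coefficients c_k, a_k.

    R0^s = sum_k num_k^3 / (d1_k * d2 * d3) with the pieces of
    :func:`_persistence_pieces`; for L = 1 and sigma = 0 it reduces
    algebraically to the deterministic R0.  The Lyapunov weights are
    c_k = num_k^3 / (d1_k^2 d3) and a_k = num_k^3 / (d1_k d3^2); R0^s > 1
    implies persistence in the mean and positive recurrence.
    """
    num, d1, d2, d3 = _persistence_pieces(model)
    r0s = float(np.sum(num**3 / (d1 * d2 * d3)))
    c = num**3 / (d1**2 * d3)
    a = num**3 / (d1 * d3**2)
    return r0s, c, a


def persistence_lower_bound(model: SwitchingModel) -> float:
    """Lower bound on liminf (1/t) int_0^t I/N dr when R0^s > 1.

    bound = d2 * (R0^s - 1) / (beta_max * sum_k c_k alpha_k_max), with
    beta_max and alpha_k_max the coordinate-wise maxima over regimes.
    Positive exactly when R0^s > 1 (and then the time-averaged infected
    fraction stays above it almost surely in the limit).
    """
    r0s, c, _ = persistence_index(model)
    _, _, d2, _ = _persistence_pieces(model)
    beta_max = float(model._beta.max())
    alpha_max = model._alpha.max(axis=0)
    return d2 * (r0s - 1.0) / (beta_max * float(c @ alpha_max))


def drift_bound_M(model: SwitchingModel) -> float:
    """Constant M dominating LV over the whole open positive orthant.

    M = mu_max * sum_k S0_k_max + (n+1) mu_max + gamma_max
        + beta_max * sum_k alpha_k_max + sum_k sigma_k_max^2,
    all maxima coordinate-wise over regimes.  Together with
    :func:`lyapunov_drift_V` < M it yields the global existence and
    positivity of solutions.
    """
    mu_max = float(model._mu.max())
    return float(
        mu_max * model._S0.max(axis=0).sum()
        + (model.n + 1) * mu_max
        + model._gamma.max()
        + model._beta.max() * model._alpha.max(axis=0).sum()
        + (model._sigma**2).max(axis=0).sum()
    )


def lyapunov_drift_V(state, model: SwitchingModel) -> float:
    """Exact generator drift LV at a strictly positive state.

    V = sum_k (S_k - 1 - ln S_k) + (I - 1 - ln I) does not depend on the
    regime, so the switching part of the generator vanishes and

    LV = mu sum_k S_k^0 - mu (sum_k S_k + I) - gamma I
         - mu sum_k S_k^0 / S_k + (n+1) mu + gamma
         + (beta I / N) sum_k alpha_k - sum_k beta alpha_k S_k / N
         + sum_k (sigma_k^2 / 2)(I^2 + S_k^2) / N^2,

    with all rates evaluated in the state's current regime.  For every
    strictly positive state LV < :func:`drift_bound_M`.
    """
    S = np.atleast_1d(np.asarray(state.S, dtype=float))
    I = float(state.I)
    if np.any(S <= 0) or I <= 0:
        raise ValueError("LV is only defined at strictly positive states")
    p = model.params(state.regime)
    N = S.sum() + I
    return float(
        p.mu * p.S0.sum()
        - p.mu * N
        - p.gamma * I
        - p.mu * (p.S0 / S).sum()
        + (p.n + 1) * p.mu
        + p.gamma
        + p.beta * I / N * p.alpha.sum()
        - p.beta * (p.alpha * S).sum() / N
        + 0.5 * (p.sigma**2 * (I**2 + S**2)).sum() / N**2
    )


def compute_thresholds(model: SwitchingModel) -> ThresholdReport:
    """Assemble every index and bound into one report."""
    strong, strong_defined = extinction_index_strong(model)
    weak, weak_holds = extinction_index_weak(model)
    r0s, c, a = persistence_index(model)
    _, _, d2, _ = _persistence_pieces(model)
    return ThresholdReport(
        r0_per_regime=np.array([deterministic_r0(p) for p in model.regimes]),
        extinction_strong=strong,
        strong_defined=strong_defined,
        extinction_weak=weak,
        weak_condition_holds=weak_holds,
        extinction_exponent_strong=(
            extinction_exponent_bound(model, "strong") if strong_defined else math.nan
        ),
        extinction_exponent_weak=extinction_exponent_bound(model, "weak"),
        persistence_index=r0s,
        c=c,
        a=a,
        persistence_bound=persistence_lower_bound(model),
        lambda_=d2 * (r0s - 1.0),
        drift_bound_M=drift_bound_M(model),
    )
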