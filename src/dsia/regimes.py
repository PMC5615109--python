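"""Environmental regime (telegraph-noise) Markov chain.

The environment switches among L regimes according to a continuous-time
Markov chain xi(t) with generator Gamma = (gamma_ij): gamma_ij >= 0 for
i != j is the rate of jumping from regime i to regime j, and each row sums
to zero.  The chain is assumed irreducible, so it has a unique stationary
distribution pi solving pi @ Gamma = 0 with sum(pi) = 1 and pi > 0.  Holding
times are exponential with rate -gamma_ll, and the ergodic theorem makes the
long-run occupation fraction of each regime converge to pi.

Regime indices are 1-based in every user-facing structure (the regime state
space is {1, ..., L}); arrays are indexed internally from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MarkovGenerator",
    "StationaryDistribution",
    "RegimePath",
    "validate_generator",
    "stationary_distribution",
    "sample_regime_path",
    "occupation_fractions",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MarkovGenerator:
    """Validated L x L transition-rate matrix of the regime chain."""

    rates: np.ndarray
    fully_connected: bool = True

    @property
    def L(self) -> int:
        return self.rates.shape[0]

    @property
    def exit_rates(self) -> np.ndarray:
        """Rate of leaving each regime, -gamma_ll >= 0."""
        return -np.diag(self.rates)


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run occupation probabilities pi of the regime chain."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("stationary distribution must be positive and sum to 1")
        object.__setattr__(self, "pi", pi)


@dataclass(frozen=True)
class RegimePath:
    """One realization of the regime chain on [0, horizon].

    ``regimes`` holds one (1-based) regime index per inter-jump interval, so
    ``len(regimes) == len(jump_times) + 1``; the final interval
    [last jump, horizon] is always included.
    """

    jump_times: np.ndarray
    regimes: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        rg = np.asarray(self.regimes, dtype=int)
        if len(rg) != len(jt) + 1:
            raise ValueError("need one regime per inter-jump interval")
        if len(jt) and (np.any(np.diff(jt) <= 0) or jt[0] <= 0 or jt[-1] > self.horizon):
            raise ValueError("jump times must be strictly increasing in (0, horizon]")
        if np.any(rg[1:] == rg[:-1]):
            raise ValueError("consecutive regimes must differ (a jump changes state)")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "regimes", rg)

    @property
    def n_jumps(self) -> int:
        return len(self.jump_times)

    def intervals(self):
        """Yield (t_start, t_end, regime) triples covering [0, horizon]."""
        bounds = np.concatenate(([0.0], self.jump_times, [self.horizon]))
        for i, regime in enumerate(self.regimes):
            yield bounds[i], bounds[i + 1], int(regime)


def validate_generator(rates) -> MarkovGenerator:
    """Validate a transition-rate matrix and return a :class:`MarkovGenerator`.

    Off-diagonal entries must be nonnegative and each row must sum to zero
    (diagonal recomputed from the off-diagonals when consistent to within
    1e-12 of the matrix scale).  A zero off-diagonal rate with L >= 2
    violates the standing assumption gamma_ij > 0 under which the stationary
    distribution is guaranteed unique; it is flagged with a warning, not
    rejected, since sample paths remain well defined.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
        raise ValueError(f"generator must be square, got shape {rates.shape}")
    L = rates.shape[0]
    if L < 1:
        raise ValueError("generator needs at least one regime")
    off = rates.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        i, j = np.argwhere(off < 0)[0]
        raise ValueError(f"negative off-diagonal rate gamma[{i + 1},{j + 1}] = {off[i, j]}")
    scale = max(1.0, float(np.abs(rates).max()))
    diag = -off.sum(axis=1)
    bad = np.abs(np.diag(rates) - diag) > _ROW_SUM_TOL * scale
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"row {i + 1} sums to {rates[i].sum():g}, not 0: diagonal must equal "
            "minus the off-diagonal row sum"
        )
    clean = off
    np.fill_diagonal(clean, diag)
    fully_connected = L == 1 or bool(np.all(off[~np.eye(L, dtype=bool)] > 0))
    if not fully_connected:
        warnings.warn(
            "generator has zero off-diagonal rates; the standing assumption "
            "gamma_ij > 0 (irreducibility) may fail",
            UserWarning,
            stacklevel=2,
        )
    return MarkovGenerator(rates=clean, fully_connected=fully_connected)


def _unreachable_states(gen: MarkovGenerator) -> list[int]:
    adjacency = (gen.rates > 0).astype(int)
    n_comp, labels = connected_components(adjacency, directed=True, connection="strong")
    if n_comp == 1:
        return []
    # states outside the largest strongly connected component (1-based)
    counts = np.bincount(labels)
    keep = np.argmax(counts)
    return [int(i) + 1 for i in np.flatnonzero(labels != keep)]


def stationary_distribution(gen: MarkovGenerator) -> StationaryDistribution:
    """Solve pi @ Gamma = 0, sum(pi) = 1 for the unique stationary law.

    Solved through the augmented linear system (transpose of the generator
    with the normalization row appended) for exactness at small L.
    """
    L = gen.L
    if L == 1:
        return StationaryDistribution(pi=np.ones(1))
    bad = _unreachable_states(gen)
    if bad:
        raise ValueError(
            f"generator is reducible: regimes {bad} are not in the recurrent "
            "communicating class; no unique stationary distribution"
        )
    a = np.vstack([gen.rates.T, np.ones(L)])
    b = np.zeros(L + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    residual = np.abs(pi @ gen.rates).max()
    if residual > 1e-10 or np.any(pi <= 0):
        raise ValueError(f"stationary solve failed (residual {residual:g}, min pi {pi.min():g})")
    return StationaryDistribution(pi=pi / pi.sum())


def sample_regime_path(
    gen: MarkovGenerator,
    initial_regime: int,
    horizon: float,
    seed: int | np.random.Generator | np.random.SeedSequence,
) -> RegimePath:
    """Sample one chain trajectory on [0, horizon], reproducible from ``seed``.

    Holding time in regime l is exponential with rate -gamma_ll; the next
    regime j is drawn with probability gamma_lj / (-gamma_ll).  A jump
    landing exactly at the horizon is discarded.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if not 1 <= initial_regime <= gen.L:
        raise ValueError(f"initial regime {initial_regime} not in 1..{gen.L}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = initial_regime - 1
    t = 0.0
    jump_times: list[float] = []
    regimes = [initial_regime]
    while True:
        rate = -gen.rates[current, current]
        if rate <= 0.0:  # absorbing regime, no further switches
            break
        t += rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        probs = gen.rates[current].copy()
        probs[current] = 0.0
        probs /= rate
        current = int(rng.choice(gen.L, p=probs))
        jump_times.append(t)
        regimes.append(current + 1)
    return RegimePath(
        jump_times=np.array(jump_times), regimes=np.array(regimes, dtype=int), horizon=horizon
    )


def occupation_fractions(path: RegimePath) -> np.ndarray:
    """Fraction of [0, horizon] spent in each regime (sums to 1).

    The vector has one entry per regime index up to the largest visited.
    """
    L = int(path.regimes.max())
    frac = np.zeros(L)
    for a, b, regime in path.intervals():
        frac[regime - 1] += b - a
    return frac / path.horizon
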