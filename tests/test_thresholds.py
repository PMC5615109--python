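"""Closed-form indices: worked values, reductions, collapses, Lyapunov drift."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsia import (
    EpidemicState,
    RegimeParameters,
    SwitchingModel,
    compute_thresholds,
    deterministic_r0,
    drift_bound_M,
    extinction_exponent_bound,
    extinction_index_strong,
    extinction_index_weak,
    lyapunov_drift_V,
    persistence_index,
    persistence_lower_bound,
    switching_model,
    validate_generator,
)
from conftest import make_generator, make_model, make_params


def single(p):
    return switching_model([[0.0]], [p])


def duplicated(p, rates=((-1.0, 1.0), (2.0, -2.0))):
    return switching_model(rates, [p, p])


class TestDeterministicR0:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(mu=0.1, gamma=0.4, beta=0.5, S0=[100.0], alpha=[1.0], sigma=[0.0]), 1.0),
            (dict(mu=0.1, gamma=0.4, beta=0.0, S0=[100.0], alpha=[1.0], sigma=[0.0]), 0.0),
            (
                dict(mu=0.1, gamma=0.4, beta=0.5, S0=[100.0, 100.0], alpha=[1.0, 2.0],
                     sigma=[0.0, 0.0]),
                1.5,
            ),
        ],
    )
    def test_worked_examples(self, kwargs, expected):
        assert deterministic_r0(RegimeParameters(**kwargs)) == pytest.approx(expected, abs=1e-14)


class TestExtinctionIndices:
    def test_strong_worked_example(self):
        p = RegimeParameters(mu=0.1, gamma=0.3, beta=0.4, S0=[100.0], alpha=[1.0], sigma=[0.8])
        value, defined = extinction_index_strong(single(p))
        assert defined
        assert value == pytest.approx(0.3125, abs=1e-14)  # (0.16/1.28)/0.4

    def test_strong_vanishes_with_large_noise(self):
        p = RegimeParameters(mu=0.1, gamma=0.3, beta=0.4, S0=[100.0], alpha=[1.0], sigma=[50.0])
        value, _ = extinction_index_strong(single(p))
        assert value < 1e-4

    def test_strong_undefined_without_noise(self, single_regime_params):
        value, defined = extinction_index_strong(single(single_regime_params))
        assert not defined and math.isnan(value)

    def test_weak_worked_example(self):
        p = RegimeParameters(mu=0.1, gamma=0.3, beta=0.3, S0=[100.0], alpha=[1.0], sigma=[0.0])
        value, holds = extinction_index_weak(single(p))
        assert value == pytest.approx(0.75, abs=1e-14)
        assert holds

    def test_weak_condition_flag(self):
        # sigma^2 = 0.5 >= beta*alpha = 0.4 violates the weak-noise hypothesis
        p = RegimeParameters(
            mu=0.1, gamma=0.3, beta=0.4, S0=[100.0], alpha=[1.0], sigma=[math.sqrt(0.5)]
        )
        _, holds = extinction_index_weak(single(p))
        assert not holds

    def test_weak_dominates_r0_without_noise(self, rng):
        """For L=1, sigma=0: weak index >= R0 (sum alpha_k >= its S0-mean)."""
        for _ in range(20):
            p = make_params(rng, int(rng.integers(1, 4)), sigma_scale=0.0)
            value, _ = extinction_index_weak(single(p))
            assert value >= deterministic_r0(p) - 1e-12


class TestExponentBound:
    def test_strong_worked_example(self):
        p = RegimeParameters(mu=0.1, gamma=0.3, beta=0.4, S0=[100.0], alpha=[1.0], sigma=[0.8])
        assert extinction_exponent_bound(single(p), "strong") == pytest.approx(-0.275, abs=1e-14)

    def test_sign_matches_index(self, rng):
        for _ in range(20):
            m = make_model(rng, n=2, L=2, sigma_scale=rng.uniform(0.1, 2.0))
            strong, defined = extinction_index_strong(m)
            if defined:
                assert (extinction_exponent_bound(m, "strong") < 0) == (strong < 1)
            weak, _ = extinction_index_weak(m)
            assert (extinction_exponent_bound(m, "weak") < 0) == (weak < 1)

    def test_unknown_case_rejected(self, two_regime_model):
        with pytest.raises(ValueError, match="case"):
            extinction_exponent_bound(two_regime_model, "medium")


class TestPersistenceIndex:
    def test_reduces_to_r0_without_noise(self, rng):
        worst = 0.0
        for _ in range(100):
            p = make_params(rng, int(rng.integers(1, 5)), sigma_scale=0.0)
            r0s, c, a = persistence_index(single(p))
            worst = max(worst, abs(r0s - deterministic_r0(p)))
            assert np.all(c > 0) and np.all(a > 0)
        assert worst < 1e-12

    def test_noise_strictly_decreases_index(self, single_regime_params):
        p0 = single_regime_params
        noisy = RegimeParameters(
            mu=p0.mu, gamma=p0.gamma, beta=p0.beta, S0=p0.S0, alpha=p0.alpha, sigma=[0.2]
        )
        r_quiet, _, _ = persistence_index(single(p0))
        r_noisy, _, _ = persistence_index(single(noisy))
        assert r_noisy < r_quiet

    def test_identical_regimes_collapse_all_indices(self, rng):
        """Duplicating one regime over any generator leaves every index unchanged."""
        for _ in range(10):
            p = make_params(rng, 2, sigma_scale=0.4)
            base = compute_thresholds(single(p))
            L = int(rng.integers(2, 5))
            dup = SwitchingModel(
                generator=make_generator(rng, L), regimes=tuple([p] * L)
            )
            rep = compute_thresholds(dup)
            for attr in (
                "extinction_strong",
                "extinction_weak",
                "persistence_index",
                "persistence_bound",
                "drift_bound_M",
            ):
                assert getattr(rep, attr) == pytest.approx(getattr(base, attr), rel=1e-12)
            np.testing.assert_allclose(rep.c, base.c, rtol=1e-12)
            np.testing.assert_allclose(rep.a, base.a, rtol=1e-12)


class TestPersistenceLowerBound:
    def test_hand_evaluated_chain(self, single_regime_params):
        # mu=0.1, gamma=0.15, beta=0.5, alpha=1, S0=100, sigma=0:
        # R0^s = R0 = 2; c_1 = mu^2*beta*alpha*S0 / (mu^2 * mu*S0) = 5;
        # bound = (mu+gamma)(R0^s-1) / (beta*c_1*alpha) = 0.25/2.5 = 0.1
        m = single(single_regime_params)
        r0s, c, _ = persistence_index(m)
        assert r0s == pytest.approx(2.0, abs=1e-12)
        assert c[0] == pytest.approx(5.0, abs=1e-12)
        assert persistence_lower_bound(m) == pytest.approx(0.1, abs=1e-12)

    def test_sign_and_cap(self, rng):
        for _ in range(20):
            m = make_model(rng, n=2, L=2, sigma_scale=0.2)
            r0s, _, _ = persistence_index(m)
            bound = persistence_lower_bound(m)
            assert (bound > 0) == (r0s > 1)
            if r0s > 1:
                assert bound <= 1.0


class TestDriftBound:
    def test_worked_example(self):
        p = RegimeParameters(mu=0.1, gamma=0.2, beta=0.3, S0=[10.0], alpha=[1.0], sigma=[0.1])
        assert drift_bound_M(single(p)) == pytest.approx(1.71, abs=1e-14)

    def test_duplicate_regimes_leave_M_unchanged(self, single_regime_params):
        p = single_regime_params
        assert drift_bound_M(duplicated(p)) == pytest.approx(drift_bound_M(single(p)))

    def test_monotone_in_regime_maxima(self, single_regime_params):
        p = single_regime_params
        bigger = RegimeParameters(
            mu=p.mu, gamma=p.gamma + 0.1, beta=p.beta, S0=p.S0, alpha=p.alpha, sigma=p.sigma
        )
        assert drift_bound_M(single(bigger)) > drift_bound_M(single(p))


class TestLyapunovDrift:
    def test_below_M_at_random_states(self, rng):
        """LV < M over random strictly positive states and every regime."""
        for _ in range(5):
            m = make_model(rng, n=2, L=2, sigma_scale=rng.uniform(0.1, 1.0))
            M = drift_bound_M(m)
            for _ in range(400):
                state = EpidemicState(
                    S=rng.uniform(1e-3, 300.0, 2),
                    I=rng.uniform(1e-3, 300.0),
                    regime=int(rng.integers(1, 3)),
                )
                assert lyapunov_drift_V(state, m) < M

    def test_disease_free_limit(self, single_regime_params):
        """At (S = S^0, I -> 0+), sigma = 0: LV -> (mu+gamma)(1 - R0)."""
        p = single_regime_params
        m = single(p)
        limit = (p.mu + p.gamma) * (1.0 - deterministic_r0(p))
        drift = lyapunov_drift_V(EpidemicState(S=p.S0, I=1e-9, regime=1), m)
        assert drift == pytest.approx(limit, abs=1e-6)

    def test_rejects_nonpositive_state(self, single_regime_params):
        m = single(single_regime_params)
        with pytest.raises(ValueError, match="positive"):
            lyapunov_drift_V(EpidemicState(S=[0.0], I=1.0, regime=1), m)


rates = st.floats(0.05, 1.0, allow_nan=False)
vec = st.lists(st.floats(0.5, 3.0, allow_nan=False), min_size=1, max_size=4)


class TestAlgebraicProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(mu=rates, gamma=rates, beta=rates, alpha=vec, scale=st.floats(10.0, 200.0))
    def test_noise_free_single_regime_identities(self, mu, gamma, beta, alpha, scale):
        """Without noise or switching, R0^s collapses to R0 and the weak-noise
        index dominates R0 (sum of alphas beats their S0-weighted mean)."""
        n = len(alpha)
        p = RegimeParameters(
            mu=mu, gamma=gamma, beta=beta, S0=np.full(n, scale),
            alpha=np.array(alpha), sigma=np.zeros(n),
        )
        m = single(p)
        r0 = deterministic_r0(p)
        r0s, _, _ = persistence_index(m)
        assert r0s == pytest.approx(r0, abs=1e-12, rel=1e-12)
        weak, holds = extinction_index_weak(m)
        assert holds
        assert weak >= r0 - 1e-12

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(mu=rates, gamma=rates, beta=rates, alpha=vec, sigma_frac=st.floats(0.1, 0.9))
    def test_exponent_bound_sign_matches_index(self, mu, gamma, beta, alpha, sigma_frac):
        n = len(alpha)
        alpha = np.array(alpha)
        p = RegimeParameters(
            mu=mu, gamma=gamma, beta=beta, S0=np.full(n, 50.0),
            alpha=alpha, sigma=sigma_frac * np.sqrt(beta * alpha),
        )
        m = single(p)
        strong, defined = extinction_index_strong(m)
        assert defined
        assert (extinction_exponent_bound(m, "strong") < 0) == (strong < 1)


class TestReportAssembly:
    def test_report_is_coherent(self, two_regime_model):
        rep = compute_thresholds(two_regime_model)
        assert rep.r0_per_regime.shape == (2,)
        assert rep.drift_bound_M > 0
        assert len(rep.c) == len(rep.a) == two_regime_model.n
        # lambda = d2*(R0s-1) shares sign with R0s-1
        assert (rep.lambda_ > 0) == (rep.persistence_index > 1)
        assert (rep.persistence_bound > 0) == (rep.persistence_index > 1)
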