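import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navsig import (HHGatingScheme, LinearChainScheme, OccupancyState,
                    hh_gate_timecourse, mean_activation_latency,
                    open_probability, propagate_epoch, steady_state)
from navsig.rates import RateFunction

from conftest import random_chain


def const_chain(*pairs):
    fw = tuple(RateFunction("constant", a) for a, _ in pairs)
    bw = tuple(RateFunction("constant", b) for _, b in pairs)
    return LinearChainScheme(fw, bw)


class TestSteadyState:
    def test_symmetric_two_state(self):
        ss = steady_state(const_chain((1.0, 1.0)), 0.0)
        assert ss.probabilities == pytest.approx([0.5, 0.5])

    def test_hh_gate_equilibrium(self):
        scheme = HHGatingScheme(3, 0, RateFunction("constant", 2.0),
                                RateFunction("constant", 6.0))
        assert steady_state(scheme, 0.0).m == pytest.approx(0.25)

    def test_matches_nullspace_oracle_on_random_chain(self):
        rng = np.random.default_rng(7)
        scheme = random_chain(rng, 3)
        q = scheme.generator(-30.0)
        ss = steady_state(scheme, -30.0)
        # independent oracle: eigen-decomposition, eigenvector of eigenvalue 0
        w, vecs = np.linalg.eig(q)
        k = int(np.argmin(np.abs(w)))
        expect = np.real(vecs[:, k])
        expect = expect / expect.sum()
        assert ss.probabilities == pytest.approx(expect, abs=1e-10)
        # stationarity: zero time-derivative
        assert np.max(np.abs(q @ ss.probabilities)) < 1e-9

    def test_disconnected_scheme_rejected(self):
        scheme = const_chain((0.0, 0.0), (1.0, 1.0))
        with pytest.raises(ValueError, match="stationary"):
            steady_state(scheme, 0.0)


class TestPropagation:
    def test_two_state_closed_form(self, two_state_scheme):
        # p_O(t) = p_inf + (p_O(0) - p_inf) exp(-(a+b) t)
        p0 = OccupancyState([1.0, 0.0], two_state_scheme.labels)
        t, p = propagate_epoch(two_state_scheme, 0.0, p0, 5.0, 0.005)
        a, b = 2.0, 1.0
        p_inf = a / (a + b)
        expect = p_inf + (0.0 - p_inf) * np.exp(-(a + b) * t)
        assert p[:, 1] == pytest.approx(expect, abs=1e-6)

    def test_long_propagation_reaches_stationarity(self):
        rng = np.random.default_rng(3)
        scheme = random_chain(rng, 4)
        n = scheme.n_states
        p0 = OccupancyState(np.full(n, 1.0 / n), scheme.labels)
        _, p = propagate_epoch(scheme, 0.0, p0, 200.0, 0.05)
        ss = steady_state(scheme, 0.0)
        assert p[-1] == pytest.approx(ss.probabilities, abs=1e-6)

    def test_expm_and_fixed_step_agree(self):
        rng = np.random.default_rng(11)
        scheme = random_chain(rng, 4)  # 5 chain states
        p0 = steady_state(scheme, -120.0)
        _, pe = propagate_epoch(scheme, 0.0, p0, 5.0, 0.005, method="expm")
        _, pf = propagate_epoch(scheme, 0.0, p0, 5.0, 0.005, method="fixed")
        assert np.max(np.abs(pe - pf)) < 1e-4

    def test_probability_conserved_at_every_sample(self):
        rng = np.random.default_rng(5)
        scheme = random_chain(rng, 5)
        p0 = steady_state(scheme, -100.0)
        for method in ("expm", "fixed"):
            _, p = propagate_epoch(scheme, 10.0, p0, 10.0, 0.01, method=method)
            assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-8

    def test_stationary_start_stays_put(self, equal_chain6):
        ss = steady_state(equal_chain6, -60.0)
        _, p = propagate_epoch(equal_chain6, -60.0, ss, 100.0, 0.1)
        assert np.max(np.abs(p - ss.probabilities)) < 1e-6


class TestHHGates:
    def test_already_at_equilibrium_is_constant(self):
        _, m = hh_gate_timecourse(2.0, 6.0, 0.25, 2.0, 0.01)
        assert m == pytest.approx(0.25)

    def test_pure_opening_closed_form(self):
        t, m = hh_gate_timecourse(1.0, 0.0, 0.0, 5.0, 0.01)
        assert m == pytest.approx(1.0 - np.exp(-t), abs=1e-12)

    def test_frozen_gate_when_both_rates_zero(self):
        _, m = hh_gate_timecourse(0.0, 0.0, 0.3, 1.0, 0.01)
        assert m == pytest.approx(0.3)

    def test_gate_matches_binomial_chain_expansion(self):
        """p independent gates == (p+1)-state chain, to 1e-6 open prob."""
        scheme = HHGatingScheme(3, 0, RateFunction("exponential", 2.0, -20, 25),
                                RateFunction("exponential", 1.0, -20, -25))
        from navsig import HHGateState

        v = -10.0
        m0 = 0.2
        t, course = propagate_epoch(scheme, v, HHGateState(m0), 4.0, 0.01)
        po_gate = course["m"] ** 3
        chain = scheme.to_chain()
        # binomial occupancy over gate-count states at m0
        p0 = np.array([(1 - m0) ** 3, 3 * m0 * (1 - m0) ** 2,
                       3 * m0**2 * (1 - m0), m0**3])
        _, p = propagate_epoch(chain, v, OccupancyState(p0, chain.labels),
                               4.0, 0.01)
        assert np.max(np.abs(po_gate - p[:, -1])) < 1e-6


class TestOpenProbability:
    def test_hh_all_open(self):
        scheme = HHGatingScheme(3, 1, RateFunction("constant", 1.0),
                                RateFunction("constant", 1.0),
                                RateFunction("constant", 1.0),
                                RateFunction("constant", 1.0))
        from navsig import HHGateState
        assert open_probability(scheme, HHGateState(1.0, 1.0)) == 1.0
        assert open_probability(scheme.without_inactivation(),
                                HHGateState(0.5)) == pytest.approx(0.125)

    def test_chain_fully_closed(self, equal_chain6):
        p = np.zeros(equal_chain6.n_states)
        p[0] = 1.0
        state = OccupancyState(p, equal_chain6.labels)
        assert open_probability(equal_chain6, state) == 0.0


class TestMeanLatency:
    def test_equal_rates(self):
        scheme = const_chain((2.0, 0.0), (2.0, 0.0), (2.0, 0.0))
        assert mean_activation_latency(scheme, 0.0).delta == pytest.approx(1.5)

    def test_two_rates(self):
        scheme = const_chain((1.0, 0.0), (2.0, 0.0))
        res = mean_activation_latency(scheme, 0.0)
        assert res.delta == pytest.approx(1.5)
        assert res.contributions == pytest.approx((1.0, 0.5))

    def test_zero_forward_rate_rejected(self):
        scheme = const_chain((1.0, 0.0), (0.0, 0.0))
        with pytest.raises(ValueError, match="latency"):
            mean_activation_latency(scheme, 0.0)

    def test_matches_first_passage_oracle(self):
        """delta equals the absorbing-chain mean first-passage time."""
        rng = np.random.default_rng(42)
        scheme = random_chain(rng, 4, backward=False)
        v = 0.0
        delta = mean_activation_latency(scheme, v).delta
        q = scheme.generator(v)
        n = scheme.open_index
        # oracle: tau = -Q_tt^(-T) 1 over the transient (closed) states
        tau = np.linalg.solve(-q[:n, :n].T, np.ones(n))
        assert delta == pytest.approx(tau[0], rel=1e-12)

    @given(st.floats(-80, 40), st.floats(1, 30))
    @settings(max_examples=40, derandomize=True)
    def test_latency_decreases_with_voltage(self, v, dv_scale):
        """With voltage-increasing forward rates, delta falls with V."""
        fw = tuple(RateFunction("exponential", r0, -20.0, 20.0)
                   for r0 in (1.0, 2.0, 4.0))
        scheme = LinearChainScheme(
            fw, tuple(RateFunction("constant", 0.0) for _ in fw))
        dv = dv_scale
        assert (mean_activation_latency(scheme, v + dv).delta
                < mean_activation_latency(scheme, v).delta)
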