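"""Value computations: beliefs, rollouts, momentum, and model variants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import goalmomentum as gm
from goalmomentum.valuation import (ValuationState, _pros_q_cached,
                                    momentum_update)
from helpers import brute_force_prospective


class TestBeliefUpdate:
    @pytest.mark.parametrize("M,I,alpha,expected", [
        (0.5, 1, 1.0, 1.0),
        (0.5, 0, 0.0, 0.5),
        (0.2, 1, 0.25, 0.4),
    ])
    def test_examples(self, M, I, alpha, expected):
        assert gm.belief_update(M, I, alpha) == pytest.approx(expected)

    def test_asymmetric_rates(self):
        up = gm.belief_update(0.5, 1, 0.4, alpha_neg=0.1)
        down = gm.belief_update(0.5, 0, 0.4, alpha_neg=0.1)
        assert up == pytest.approx(0.7)
        assert down == pytest.approx(0.45)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            gm.belief_update(0.5, 1, 1.5)

    @given(M=st.floats(0, 1), token=st.integers(0, 1), alpha=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_stays_in_unit_interval(self, M, token, alpha):
        assert 0.0 <= gm.belief_update(M, token, alpha) <= 1.0


class TestProspectiveValue:
    def test_certain_one_step_no_discount(self):
        for h in (1, 5, 20):
            assert gm.prospective_value(1.0, 6, 7, 1.0, horizon=h) == \
                pytest.approx(1.0)

    def test_zero_horizon(self):
        assert gm.prospective_value(0.8, 3, 7, 0.9, horizon=0) == 0.0

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            gm.prospective_value(0.5, 8, 7, 0.9)

    @pytest.mark.parametrize("M,gamma,T_minus_s,horizon", [
        (M, g, d, h)
        for M in (0.2, 0.5, 0.8) for g in (0.8, 0.95, 1.0)
        for d in (1, 2, 3) for h in (1, 3, 6)
    ])
    def test_matches_enumeration_oracle(self, M, gamma, T_minus_s, horizon):
        T = 7
        s = T - T_minus_s
        dp = gm.prospective_value(M, s, T, gamma, horizon=horizon)
        assert dp == pytest.approx(
            brute_force_prospective(M, s, T, gamma, horizon), abs=1e-10)

    @pytest.mark.parametrize("M,gamma", [(0.8, 0.95), (0.3, 0.9), (0.6, 0.99)])
    def test_infinite_horizon_closed_form(self, M, gamma):
        for d in (1, 3, 7):
            dp = gm.prospective_value(M, 7 - d, 7, gamma, horizon=500)
            cf = gm.prospective_value_closed_form(M, 7 - d, 7, gamma)
            assert dp == pytest.approx(cf, abs=1e-9)

    def test_one_step_closed_form_value(self):
        # M=0.8, gamma=0.95, one token left: Mγ/(1-(1-M)γ)
        got = gm.prospective_value_closed_form(0.8, 6, 7, 0.95)
        assert got == pytest.approx(0.8 * 0.95 / (1 - 0.2 * 0.95))

    def test_monotone_in_belief_progress_discount(self):
        grid = np.linspace(0.05, 0.95, 8)
        for g in (0.8, 0.95):
            qs = [gm.prospective_value(M, 3, 7, g) for M in grid]
            assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        for M in (0.3, 0.7):
            qs = [gm.prospective_value(M, s, 7, 0.9) for s in range(8)]
            assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
            qg = [gm.prospective_value(M, 3, 7, g) for g in grid]
            assert all(a <= b + 1e-12 for a, b in zip(qg, qg[1:]))

    def test_cached_path_equals_public_dp(self):
        for M in (0.1234, 0.5, 0.9876):
            got = np.array(_pros_q_cached(M, 7, 0.93, 20))
            want = gm.prospective_values_vector(round(M, 4), 7, 0.93, 20)
            assert np.allclose(got, want, atol=1e-12)


class TestRetrospectiveValue:
    def test_at_target(self):
        assert gm.retrospective_value(7, 7, 0.9) == 1.0

    def test_no_discounting(self):
        assert gm.retrospective_value(0, 7, 1.0) == 1.0

    def test_three_steps(self):
        assert gm.retrospective_value(4, 7, 0.9) == pytest.approx(0.729)


class TestMomentum:
    @pytest.mark.parametrize("v,m,b,expected", [
        (0.5, 0.0, 0.1, 0.1),   # the fixed initialization values
        (0.0, 0.7, 0.0, 0.0),
        (1.0, 0.5, 0.25, 0.75),
    ])
    def test_value(self, v, m, b, expected):
        assert gm.momentum_value(v, m, b) == pytest.approx(expected)

    def test_update_directions(self):
        """Early unit progress raises momentum; late unit progress and
        stalling lower it (for γ < 1)."""
        st_ = ValuationState()
        st_.bias = [0.0, 0.0, 0.0]
        momentum_update(st_, 0, 0.2, 0.25, gamma=0.81, alpha=0.1)
        assert st_.bias[0] > 0.0  # delta > 0 just inside the boundary
        st2 = ValuationState()
        st2.bias = [0.0, 0.0, 0.0]
        momentum_update(st2, 0, 0.9, 0.95, gamma=0.8, alpha=0.1)
        assert st2.bias[0] < 0.0  # delta < 0
        st3 = ValuationState()
        momentum_update(st3, 0, 0.5, 0.5, gamma=0.8, alpha=0.1)
        assert st3.bias[0] < 0.1  # no progress: always negative for gamma<1

    def test_sign_condition_examples(self):
        assert gm.momentum_sign_condition(0.2, 0.05, 0.8)   # boundary case
        assert not gm.momentum_sign_condition(0.9, 0.05, 0.8)
        assert gm.momentum_sign_condition(0.0, 0.05, 0.01)

    def test_sign_condition_agrees_with_bias_free_delta(self):
        """γ(m+η) ≥ m iff the bias-free TD error is non-negative, on a grid."""
        eta = 1 / 7
        for m in np.linspace(0, 0.95, 50):
            for gamma in np.linspace(0.6, 1.0, 50):
                st_ = ValuationState()
                st_.bias = [0.0, 0.0, 0.0]
                v0 = st_.speed[0]
                momentum_update(st_, 0, m, m + eta, gamma, alpha=0.5)
                delta_sign = st_.bias[0] >= -1e-12
                assert delta_sign == gm.momentum_sign_condition(m, eta, gamma)

    def test_speed_tracks_progress_probability(self):
        """Over a block-length run from the standard initialization, the
        learned speed v ends higher the more probable unit progress is."""
        eta, alpha, gamma = 0.14, 0.2, 0.95
        means = []
        for p in (0.2, 0.6, 0.9):
            finals = []
            for rep in range(200):
                rng = np.random.default_rng(1000 + rep)
                st_ = ValuationState()
                m = 0.0
                for _ in range(60):
                    token = rng.random() < p
                    m_after = min(m + eta, 1.0) if token else m
                    momentum_update(st_, 0, m, m_after, gamma, alpha)
                    m = m_after if m_after < 1.0 else 0.0
                finals.append(st_.speed[0])
            means.append(np.mean(finals))
        assert means[0] < means[1] < means[2]

    def test_momentum_smoother_than_prospective_after_drop(self):
        """With the token probability dropping 0.6→0.2 at round 15, the
        momentum value decays gradually while the belief-based rollout value
        jumps with individual reinforcements: the momentum trace's
        range-normalized roughness (mean |second difference| / range) is
        smaller for most runs and on average."""
        eta, alpha, gamma = 0.05, 0.4, 0.9
        T = 20

        def traces(seed):
            rng = np.random.default_rng(seed)
            st_ = ValuationState()
            M, m, s = 0.5, 0.0, 0
            mom, pros = [], []
            for t in range(60):
                p = 0.6 if t < 15 else 0.2
                token = rng.random() < p
                m_after = min(m + eta, 1.0 - 1e-9) if token else m
                momentum_update(st_, 0, m, m_after, gamma, alpha)
                m = m_after
                s = min(s + token, T - 1)
                M = gm.belief_update(M, int(token), alpha)
                mom.append(gm.momentum_value(st_.speed[0], m, st_.bias[0]))
                pros.append(gm.prospective_value(M, s, T, gamma))
            return np.asarray(mom), np.asarray(pros)

        def roughness(x):
            return np.abs(np.diff(x, 2)).mean() / (x.max() - x.min())

        r_mom, r_pros = [], []
        for seed in range(30):
            m_, p_ = traces(seed)
            r_mom.append(roughness(m_))
            r_pros.append(roughness(p_))
        assert np.mean(r_mom) < np.mean(r_pros)
        assert np.mean(np.array(r_mom) < np.array(r_pros)) > 0.8


class TestOtherModels:
    def test_td_persistence_is_identity(self):
        assert gm.td_persistence_value(0.8) == 0.8

    def test_hybrid_extremes_and_mix(self):
        assert gm.hybrid_value(0.4, 0.8, 1.0) == 0.4
        assert gm.hybrid_value(0.4, 0.8, 0.0) == 0.8
        assert gm.hybrid_value(0.4, 0.8, 0.5) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            gm.hybrid_value(0.4, 0.8, 1.5)

    def test_hyperbolic_no_discount_and_unit_delay(self):
        assert gm.hyperbolic_prospective_value(0.5, 3, 7, 0.0) == 1.0
        assert gm.hyperbolic_prospective_value(1.0, 6, 7, 1.0) == \
            pytest.approx(0.5)
        assert gm.hyperbolic_prospective_value(0.0, 0, 7, 1.0) < 1e-2

    def test_rw_update(self):
        from goalmomentum.valuation import rw_ck_update
        st_ = ValuationState()
        kernels = [1.0, 0.0, 0.0]
        rw_ck_update(st_, kernels, 0, 1, eta=0.5, alpha_ck=0.3)
        assert st_.rw_values[0] == pytest.approx(0.5)
        assert kernels[0] == pytest.approx(1.0)  # fixed point
        assert kernels[1] == 0.0


def test_free_parameter_counts():
    assert gm.n_free_params("td_persistence") == 5
    assert gm.n_free_params("momentum") == 6
    assert gm.n_free_params("prospective") == 6
    assert gm.n_free_params("hybrid") == 7
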