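"""Latent-goal likelihood, fitting, and model-comparison metrics."""

import math

import numpy as np
import pytest

import goalmomentum as gm
from goalmomentum.fitting import LatentGoalBelief
from goalmomentum.task_env import SUITS, BlockSpec, GameConfig, SuitSpec
from helpers import enumerate_nll_momentum, small_dataset


class TestTransitionMatrix:
    def params(self, **kw):
        base = dict(alpha=0.3, gamma=0.95, switch_cost=0.0, beta_goal=0.0,
                    beta_action=3.0, alpha_ck=0.0)
        base.update(kw)
        return gm.ModelParams("momentum", **base)

    def test_rows_sum_to_one(self):
        T = gm.goal_transition_matrix([0.5, 0.9, 0.1],
                                      self.params(beta_goal=4.0,
                                                  switch_cost=0.4),
                                      [0.2, 0.0, 0.7])
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_indifferent_agent_half_quarter(self):
        """β_g = 0, no cost, no kernel: stay 0.5, each alternative 0.25."""
        T = gm.goal_transition_matrix([0.3, 0.6, 0.9], self.params(),
                                      [0.0, 0.0, 0.0])
        assert np.allclose(np.diag(T), 0.5)
        assert np.allclose(T - np.diag(np.diag(T)),
                           np.full((3, 3), 0.25) - np.diag([0.25] * 3))

    def test_symmetric_values_symmetric_offdiagonals(self):
        T = gm.goal_transition_matrix([0.5, 0.5, 0.5],
                                      self.params(beta_goal=3.0),
                                      [0.0, 0.0, 0.0])
        off = T[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])


class TestBeliefPropagation:
    def test_point_mass_through_identity(self):
        b = LatentGoalBelief([1.0, 0.0, 0.0])
        out = gm.propagate_latent_goal(b, np.eye(3))
        assert np.allclose(out.probs, [1, 0, 0])

    def test_uniform_through_doubly_stochastic(self):
        T = np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25], [0.25, 0.25, 0.5]])
        out = gm.propagate_latent_goal(LatentGoalBelief(np.full(3, 1 / 3)), T)
        assert np.allclose(out.probs, 1 / 3)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(0)
        T1 = rng.dirichlet(np.ones(3), size=3)
        T2 = rng.dirichlet(np.ones(3), size=3)
        b = LatentGoalBelief(rng.dirichlet(np.ones(3)))
        two_step = gm.propagate_latent_goal(
            gm.propagate_latent_goal(b, T1), T2)
        direct = gm.propagate_latent_goal(b, T1 @ T2)
        assert np.allclose(two_step.probs, direct.probs)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            LatentGoalBelief([0.5, 0.2, 0.1])


class TestActionLikelihood:
    def test_point_mass_reduces_to_conditional(self):
        rows = [[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]]
        b = LatentGoalBelief([0.0, 1.0, 0.0])
        assert gm.action_likelihood(b, rows, 0) == pytest.approx(0.1)

    def test_uniform_everything_is_third(self):
        rows = [[1 / 3] * 3] * 3
        b = LatentGoalBelief(np.full(3, 1 / 3))
        assert gm.action_likelihood(b, rows, 2) == pytest.approx(1 / 3)

    def test_floor_on_impossible_observation(self):
        rows = [[1.0, 0.0, 0.0]] * 3
        b = LatentGoalBelief([1.0, 0.0, 0.0])
        assert gm.action_likelihood(b, rows, 2) == pytest.approx(1e-12)


class TestDatasetNLL:
    def test_matches_path_enumeration_on_tiny_dataset(self):
        """Sum-product forward pass equals brute-force enumeration over all
        latent goal paths on a hand-built 3-round dataset."""
        ds = small_dataset(actions=[0, 1, 0], tokens=[1, 0, 0],
                           probes=[-1, -1, 1])
        params = gm.ModelParams("momentum", alpha=0.4, gamma=0.9,
                                switch_cost=0.3, beta_goal=2.5,
                                beta_action=3.5, alpha_ck=0.0)
        got = gm.dataset_nll(ds, "momentum", params)
        want = enumerate_nll_momentum(ds, params)
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_enumeration_longer_with_completion(self):
        ds = small_dataset(actions=[0, 0, 0, 1, 0, 2], tokens=[1, 1, 1, 0, 0, 1],
                           probes=[-1, -1, 0, -1, -1, 2], targets=(3, 7, 7))
        params = gm.ModelParams("momentum", alpha=0.3, gamma=0.95,
                                switch_cost=-0.2, beta_goal=4.0,
                                beta_action=1.5, alpha_ck=0.0)
        got = gm.dataset_nll(ds, "momentum", params)
        want = enumerate_nll_momentum(ds, params)
        assert got == pytest.approx(want, abs=1e-10)

    def test_undecided_probe_contributes_no_term(self):
        ds1 = small_dataset(actions=[0, 1, 0], tokens=[1, 0, 0],
                            probes=[-1, -1, -2])
        ds2 = small_dataset(actions=[0, 1, 0], tokens=[1, 0, 0],
                            probes=[-1, -1, -1])
        params = gm.ModelParams("momentum", alpha=0.4, gamma=0.9,
                                switch_cost=0.3, beta_goal=2.5,
                                beta_action=3.5, alpha_ck=0.1)
        assert gm.dataset_nll(ds1, "momentum", params) == \
            pytest.approx(gm.dataset_nll(ds2, "momentum", params))

    def test_near_deterministic_game_near_zero_nll(self):
        """A sharp belief learner in a deterministic environment produces
        near-delta likelihoods (only the first-round goal is uncertain)."""
        suits = [SuitSpec(s, 7) for s in SUITS]
        blocks = [BlockSpec(1, 90, {"cat": 1.0, "hat": 0.0, "car": 0.0},
                            "cat", "det")]
        cfg = GameConfig("custom", suits, blocks)
        params = gm.ModelParams("td_persistence", alpha=0.9, switch_cost=1.0,
                                beta_goal=10.0, beta_action=10.0,
                                alpha_ck=0.99)
        ds = gm.simulate_participant(cfg, params, seed=0)
        nll = gm.dataset_nll(ds, "td_persistence", params)
        assert nll < 3.0  # ~log 3 for the opening round plus crumbs

    def test_true_params_beat_perturbed_on_average(self, exp1_config):
        true = gm.ModelParams("momentum", alpha=0.5, gamma=0.95,
                              switch_cost=0.6, beta_goal=5.0, beta_action=5.0,
                              alpha_ck=0.2)
        bad = gm.ModelParams("momentum", alpha=0.05, gamma=0.7,
                             switch_cost=-0.6, beta_goal=0.5, beta_action=0.5,
                             alpha_ck=0.8)
        diffs = []
        for seed in range(20):
            ds = gm.simulate_participant(exp1_config, true, seed=seed)
            diffs.append(gm.dataset_nll(ds, "momentum", bad)
                         - gm.dataset_nll(ds, "momentum", true))
        assert np.mean(diffs) > 0

    def test_term_count(self, momentum_dataset):
        assert gm.n_likelihood_terms(momentum_dataset, "momentum") == 540 + 180
        assert gm.n_likelihood_terms(momentum_dataset, "rw_ck") == 540

    def test_filtered_variant_finite_and_different(self, momentum_dataset,
                                                   momentum_params):
        plain = gm.dataset_nll(momentum_dataset, "momentum", momentum_params)
        filt = gm.dataset_nll(momentum_dataset, "momentum", momentum_params,
                              filtered=True)
        assert math.isfinite(filt) and filt != plain

    def test_all_models_finite(self, momentum_dataset):
        for model_id in gm.MODEL_IDS:
            p = gm.sample_params(model_id, rng=np.random.default_rng(5))
            assert math.isfinite(
                gm.dataset_nll(momentum_dataset, model_id, p))


class TestInformationCriteria:
    def test_aic_with_unit_likelihood(self):
        assert gm.aic(0.0, 6) == 12.0

    def test_bic_direct(self):
        assert gm.bic(0.0, 2, 100) == pytest.approx(2 * math.log(100))

    def test_fit_result_consistency(self, momentum_dataset):
        fr = gm.fit(momentum_dataset, "momentum", seed=0, n_starts=5,
                    refine_maxfev=0)
        assert fr.aic == pytest.approx(2 * 6 + 2 * fr.nll)
        assert fr.bic == pytest.approx(6 * math.log(fr.n_terms) + 2 * fr.nll)


class TestFit:
    def test_reproducible_and_beats_true_params(self, exp1_config):
        true = gm.ModelParams("momentum", alpha=0.5, gamma=0.95,
                              switch_cost=0.6, beta_goal=5.0, beta_action=5.0,
                              alpha_ck=0.2)
        ds = gm.simulate_participant(exp1_config, true, seed=31)
        fr1 = gm.fit(ds, "momentum", seed=2, n_starts=30, refine_maxfev=120)
        fr2 = gm.fit(ds, "momentum", seed=2, n_starts=30, refine_maxfev=120)
        assert fr1.nll == fr2.nll
        assert fr1.params.to_dict() == fr2.params.to_dict()
        assert fr1.nll <= gm.dataset_nll(ds, "momentum", true) + 1e-9

    def test_params_inside_box(self, momentum_dataset):
        fr = gm.fit(momentum_dataset, "momentum", seed=1, n_starts=10,
                    refine_maxfev=40)
        for name, (lo, hi) in gm.PARAM_SPECS["momentum"].items():
            assert lo <= getattr(fr.params, name) <= hi


class TestCrossValidation:
    def test_deterministic_positive_and_sane(self, exp1_config):
        true = gm.ModelParams("momentum", alpha=0.5, gamma=0.95,
                              switch_cost=0.6, beta_goal=5.0, beta_action=5.0,
                              alpha_ck=0.2)
        ds = gm.simulate_participant(exp1_config, true, seed=13)
        cv1 = gm.cross_validate(ds, "momentum", n_repeats=2, seed=5,
                                n_starts=8, refine_maxfev=30)
        cv2 = gm.cross_validate(ds, "momentum", n_repeats=2, seed=5,
                                n_starts=8, refine_maxfev=30)
        assert cv1 == cv2
        assert cv1 > 0

    def test_requires_three_blocks(self):
        ds = small_dataset(actions=[0, 1], tokens=[0, 0], probes=[-1, -1])
        with pytest.raises(ValueError):
            gm.cross_validate(ds, "momentum")
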