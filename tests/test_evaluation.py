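"""Fitted-Q evaluation against exact policy evaluation; descriptive
comparisons (frequency shift, pre/post distributions, trajectory overlay)."""

import numpy as np
import pandas as pd
import pytest

from replete.cohort import bin_visit, impute
from replete.evaluation import (
    BEHAVIOR,
    fqe,
    frequency_analysis,
    policy_value_report,
    pre_post_distribution,
    trajectory_overlay,
)
from replete.exact import (
    exact_policy_evaluation,
    random_finite_mdp,
    sample_transitions,
    toy_mdp_spec,
    value_iteration,
)
from replete.mdp import MDPSpec, RewardWeights, build_transitions, catalog_index
from replete.policy import Policy, QFunction, TransitionDataset, fqi, greedy_policy
from .conftest import make_visit

K_AI = RewardWeights(0.07, 0.04, 0.15, 0.74)


class _ArrayPolicy:
    """Deterministic tabular policy over one-hot states (validation only)."""

    def __init__(self, table, catalog):
        self.table = np.asarray(table, dtype=int)
        self.catalog = catalog

    def action_indices(self, states):
        return self.table[np.atleast_2d(states).argmax(axis=1)]


class TestFqeToyMdps:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_solve_policy_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        mdp = random_finite_mdp(5, 3, 0.9, rng)
        samples = sample_transitions(mdp, n_episodes=40, episode_len=15, rng=rng)
        policy = _ArrayPolicy(rng.integers(0, 3, size=5), list(range(3)))
        spec = toy_mdp_spec(mdp)
        res = fqe(policy, samples, spec, n_iterations=250, regressor_spec="tabular", rng_seed=0)
        q_exact = exact_policy_evaluation(mdp, policy.table)
        q_hat = res.q.q_matrix(np.eye(5))
        assert np.abs(q_hat - q_exact).max() <= 1e-6

    def test_constant_reward_approaches_geometric_series(self):
        # every (s, a) pays -0.5 forever: value converges to -0.5/(1-gamma)
        rng = np.random.default_rng(0)
        mdp = random_finite_mdp(4, 2, 0.9, rng)
        mdp.reward[:] = -0.5
        samples = sample_transitions(mdp, n_episodes=30, episode_len=12, rng=rng)
        policy = _ArrayPolicy(np.zeros(4), list(range(2)))
        res = fqe(policy, samples, toy_mdp_spec(mdp), n_iterations=250,
                  regressor_spec="tabular", rng_seed=0)
        assert np.allclose(res.q.q_matrix(np.eye(4)), -0.5 / (1 - 0.9), atol=1e-5)

    def test_behavior_mode_uses_logged_next_actions(self):
        """FQE of the logged behavior equals exact evaluation of the
        behavior policy when behavior is a fixed deterministic rule."""
        rng = np.random.default_rng(1)
        mdp = random_finite_mdp(5, 3, 0.9, rng)
        behavior = rng.integers(0, 3, size=5)
        # exploring starts give full (s, a) coverage while every logged next
        # action follows the deterministic behavior rule
        samples = sample_transitions(mdp, 80, 15, rng, behavior=behavior, epsilon=0.0)
        spec = toy_mdp_spec(mdp)
        res = fqe(BEHAVIOR, samples, spec, n_iterations=250, regressor_spec="tabular", rng_seed=0)
        q_exact = exact_policy_evaluation(mdp, behavior)
        q_hat = res.q.q_matrix(np.eye(5))
        assert np.abs(q_hat - q_exact).max() <= 1e-6


class TestFrequencyAnalysis:
    def _dataset(self, action_idx, n_actions=28):
        from replete.mdp import TransitionSample

        samples = [
            TransitionSample(
                visit_id=f"v{i % 3}", bin_index=i // 3, state=np.array([4.0, float(i)]),
                action_index=a, reward=0.0, reward_features=np.zeros(4),
                next_state=np.array([4.0, float(i + 1)]), next_action_index=0,
            )
            for i, a in enumerate(action_idx)
        ]
        return TransitionDataset(samples, n_actions)

    class _EchoPolicy:
        """Replays a fixed list of actions (state feature 1 is the index)."""

        def __init__(self, actions, catalog):
            self.actions = np.asarray(actions)
            self.catalog = catalog

        def action_indices(self, states):
            return self.actions[np.atleast_2d(states)[:, 1].astype(int)]

    def test_identical_policy_gives_zero_change(self, k_catalog):
        hist = [0, 1, 5, 0, 2, 0]
        data = self._dataset(hist)
        pol = self._EchoPolicy(hist, k_catalog)
        rep = frequency_analysis(data, pol, k_catalog)
        assert rep.repletion_change_pct == 0.0
        assert np.array_equal(rep.historical_counts, rep.policy_counts)

    def test_all_none_policy_is_minus_100(self, k_catalog):
        hist = [0, 1, 5, 0, 2, 0]
        data = self._dataset(hist)
        pol = self._EchoPolicy([0] * 6, k_catalog)
        rep = frequency_analysis(data, pol, k_catalog)
        assert rep.repletion_change_pct == pytest.approx(-100.0)

    def test_zero_historical_repletions_reported_as_undefined(self, k_catalog):
        data = self._dataset([0, 0, 0])
        pol = self._EchoPolicy([0, 1, 0], k_catalog)
        rep = frequency_analysis(data, pol, k_catalog)
        assert rep.repletion_change_pct is None

    def test_counts_conserved_and_route_mix_sums_to_one(self, k_catalog):
        hist = [0, 1, 4, 27, 2, 0, 9]
        data = self._dataset(hist)
        pol = self._EchoPolicy([0, 0, 1, 1, 0, 27, 4], k_catalog)
        rep = frequency_analysis(data, pol, k_catalog)
        assert rep.historical_counts.sum() == rep.n_states == 7
        assert rep.policy_counts.sum() == 7
        assert sum(rep.historical_route_mix.values()) == pytest.approx(1.0)
        assert sum(rep.policy_route_mix.values()) == pytest.approx(1.0)


class TestPrePostDistribution:
    def _visit(self, obs, meds):
        return impute([bin_visit(make_visit(obs=obs, meds=meds))])[0]

    def test_single_low_repletion_counts_as_below(self):
        v = self._visit(
            obs=[(0.0, "K", 3.0), (12.0, "K", 4.0), (17.5, "heart_rate", 80)],
            meds=[(0.0, 0.5, "K-PO", 40.0, "PO")],
        )
        rep = pre_post_distribution([v], "K", (3.5, 5.0))
        assert rep.n_events == 1
        assert rep.frac_within_or_above == 0.0 and rep.frac_below == 1.0
        assert rep.post_levels[0] == pytest.approx(4.0)

    def test_all_above_range_repletions(self):
        v = self._visit(
            obs=[(0.0, "K", 5.5), (6.0, "K", 5.6), (12.0, "K", 5.0), (17.5, "heart_rate", 80)],
            meds=[(0.0, 0.5, "K-PO", 20.0, "PO"), (6.0, 6.5, "K-PO", 20.0, "PO")],
        )
        rep = pre_post_distribution([v], "K", (3.5, 5.0))
        assert rep.frac_above == 1.0 and rep.frac_within_or_above == 1.0

    def test_post_level_skips_bins_before_infusion_end(self):
        # IV over 18-20 h: the 19 h lab is still during the infusion's bin;
        # the first post measurement is the 25 h one
        v = self._visit(
            obs=[(0.0, "K", 3.2), (18.0, "K", 3.3), (19.0, "K", 3.6),
                 (25.0, "K", 4.4), (29.5, "heart_rate", 80)],
            meds=[(18.0, 20.0, "K-IV", 40.0, "IV")],
        )
        rep = pre_post_distribution([v], "K", (3.5, 5.0))
        assert rep.post_levels[-1] == pytest.approx(4.4)

    def test_imputed_cells_never_counted(self):
        # the repletion bin has no K lab; pre must come from the earlier
        # observed bin, not from the carried-forward cell
        v = self._visit(
            obs=[(0.0, "K", 3.1), (23.5, "heart_rate", 80)],
            meds=[(12.0, 12.5, "K-PO", 40.0, "PO")],
        )
        rep = pre_post_distribution([v], "K", (3.5, 5.0))
        assert rep.n_events_with_pre == 1
        assert rep.pre_levels[0] == pytest.approx(3.1)

    def test_fraction_partition(self):
        v = self._visit(
            obs=[(0.0, "K", 3.0), (6.0, "K", 4.0), (12.0, "K", 5.5), (17.5, "heart_rate", 80)],
            meds=[(0.0, 0.5, "K-PO", 20.0, "PO"), (6.0, 6.5, "K-PO", 20.0, "PO"),
                  (12.0, 12.5, "K-PO", 20.0, "PO")],
        )
        rep = pre_post_distribution([v], "K", (3.5, 5.0))
        assert rep.frac_within_or_above + rep.frac_below == pytest.approx(1.0)
        assert 0.0 <= rep.frac_above <= rep.frac_within_or_above


class TestTrajectoryOverlay:
    def _spec(self):
        return MDPSpec(
            electrolyte="K",
            state_features=("K", "age", "admit_weight", "prior_po_level", "prior_iv_level"),
            reward_weights=K_AI,
            gamma=0.9,
        )

    class _NonePolicy:
        def action_indices(self, states):
            return np.zeros(len(np.atleast_2d(states)), dtype=int)

    def test_no_actions_anywhere(self):
        v = impute([bin_visit(make_visit(obs=[(0.0, "K", 4.0), (11.5, "heart_rate", 80)]))])[0]
        df = trajectory_overlay(v, self._NonePolicy(), self._spec())
        assert (df.historical_action == "").all() and (df.policy_action == "").all()

    def test_historical_iv_span_covers_hours_18_to_20(self):
        v = impute([bin_visit(make_visit(
            obs=[(0.0, "K", 4.0), (29.5, "heart_rate", 80)],
            meds=[(18.0, 20.0, "K-IV", 40.0, "IV")],
        ))])[0]
        df = trajectory_overlay(v, self._NonePolicy(), self._spec())
        row = df[df.bin_index == 3].iloc[0]
        assert row.historical_action == "IV5"
        assert (row.historical_iv_start, row.historical_iv_end) == (18.0, 20.0)

    def test_measured_column_masks_imputed_bins(self):
        v = impute([bin_visit(make_visit(
            obs=[(0.0, "K", 4.0), (17.5, "heart_rate", 80)]))])[0]
        df = trajectory_overlay(v, self._NonePolicy(), self._spec())
        assert np.isnan(df.measured_level.iloc[1]) and np.isnan(df.measured_level.iloc[2])
        assert df.imputed_level.notna().all()


def test_policy_value_report_shares_the_sample_set():
    rng = np.random.default_rng(3)
    mdp = random_finite_mdp(4, 2, 0.9, rng)
    samples = sample_transitions(mdp, 30, 12, rng)
    spec = toy_mdp_spec(mdp)
    q = fqi(samples, spec, n_iterations=50, regressor_spec="tabular", rng_seed=0)
    rep = policy_value_report(greedy_policy(q), samples, spec,
                              n_iterations=100, regressor_spec="tabular", rng_seed=0)
    assert rep.learned.n_samples == rep.behavior.n_samples
    d = rep.to_dict()
    assert set(d) >= {"learned_mean_q", "behavior_mean_q", "mean_gap"}
    # the greedy policy of the optimal Q cannot be worth less than the
    # uniform-random logged behavior on a solvable toy problem
    assert rep.mean_gap >= -1e-9
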