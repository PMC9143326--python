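"""Enumerable finite MDPs with exact dynamic-programming solutions.

Used to validate the fitted Q-iteration / fitted-Q evaluation loops: on a
deterministic finite MDP with full state-action coverage and an
exact-interpolation regressor, FQI must reproduce value iteration and FQE
must reproduce the linear-solve policy evaluation to numerical precision.
These solvers work directly from the transition and reward tables and share
no code with the fitted loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdp import TransitionSample


@dataclass
class FiniteMDP:
    """Deterministic finite MDP: next_state[s, a] and reward[s, a]."""

    next_state: np.ndarray  # (S, A) int
    reward: np.ndarray  # (S, A) float
    gamma: float

    @property
    def n_states(self) -> int:
        return self.next_state.shape[0]

    @property
    def n_actions(self) -> int:
        return self.next_state.shape[1]

    def state_vector(self, s: int) -> np.ndarray:
        v = np.zeros(self.n_states)
        v[s] = 1.0
        return v


def random_finite_mdp(
    n_states: int, n_actions: int, gamma: float, rng: np.random.Generator
) -> FiniteMDP:
    """Random deterministic MDP with rewards in [-1, 0] (penalty scale)."""
    nxt = rng.integers(0, n_states, size=(n_states, n_actions))
    rew = -rng.random(size=(n_states, n_actions))
    return FiniteMDP(next_state=nxt, reward=rew, gamma=gamma)


def value_iteration(mdp: FiniteMDP, n_iterations: int = 400, tol: float = 0.0) -> np.ndarray:
    """Exact Q from value iteration (Q0 = 0); returns the (S, A) table."""
    q = np.zeros((mdp.n_states, mdp.n_actions))
    for _ in range(n_iterations):
        v = q.max(axis=1)
        q_new = mdp.reward + mdp.gamma * v[mdp.next_state]
        if tol and np.abs(q_new - q).max() <= tol:
            return q_new
        q = q_new
    return q


def value_iteration_k_steps(mdp: FiniteMDP, k: int) -> np.ndarray:
    """Exactly k dynamic-programming backups from Q0 = 0 (matches k FQI
    iterations with an exact regressor and full coverage)."""
    return value_iteration(mdp, n_iterations=k)


def exact_policy_evaluation(mdp: FiniteMDP, policy: np.ndarray) -> np.ndarray:
    """Q^pi for a deterministic policy (array s -> a) by linear solve."""
    n = mdp.n_states
    # V^pi solves (I - gamma * P_pi) V = r_pi for deterministic dynamics
    r_pi = mdp.reward[np.arange(n), policy]
    p_pi = np.zeros((n, n))
    p_pi[np.arange(n), mdp.next_state[np.arange(n), policy]] = 1.0
    v = np.linalg.solve(np.eye(n) - mdp.gamma * p_pi, r_pi)
    return mdp.reward + mdp.gamma * v[mdp.next_state]


def sample_transitions(
    mdp: FiniteMDP,
    n_episodes: int,
    episode_len: int,
    rng: np.random.Generator,
    behavior: np.ndarray | None = None,
    epsilon: float = 0.0,
) -> list[TransitionSample]:
    """Roll episodes in the finite MDP and emit one-hot-state transition
    samples (no terminal samples: the toy MDP is a continuing task, so every
    sample bootstraps).  ``behavior=None`` acts uniformly at random.  With a
    deterministic ``behavior`` array, episodes use exploring starts (random
    first action for state-action coverage) and then follow the behavior
    rule, deviating randomly with probability ``epsilon``; at epsilon=0 the
    logged next actions are exactly the behavior policy's."""
    samples: list[TransitionSample] = []
    phi = np.zeros(4)
    if behavior is not None:
        # enumerate (s, a) exploring starts round-robin: full coverage is
        # guaranteed, not merely probable
        pairs = [(s, a) for s in range(mdp.n_states) for a in range(mdp.n_actions)]
    for ep in range(n_episodes):
        if behavior is not None:
            s, a0 = pairs[ep % len(pairs)]
        else:
            s, a0 = int(rng.integers(mdp.n_states)), None
        prev: TransitionSample | None = None
        for t in range(episode_len):
            if t == 0 and a0 is not None:
                a = a0
            elif behavior is None or rng.random() < epsilon:
                a = int(rng.integers(mdp.n_actions))
            else:
                a = int(behavior[s])
            s2 = int(mdp.next_state[s, a])
            sample = TransitionSample(
                visit_id=f"ep{ep}",
                bin_index=t,
                state=mdp.state_vector(s),
                action_index=a,
                reward=float(mdp.reward[s, a]),
                reward_features=phi,
                next_state=mdp.state_vector(s2),
            )
            if prev is not None:
                prev.next_action_index = a
            samples.append(sample)
            prev = sample
            s = s2
        # the final logged next action (needed for behavior-policy FQE)
        if prev is not None:
            if behavior is None or rng.random() < epsilon:
                prev.next_action_index = int(rng.integers(mdp.n_actions))
            else:
                prev.next_action_index = int(behavior[s])
    return samples


def toy_mdp_spec(mdp: FiniteMDP):
    """MDPSpec for running the fitted loops on one-hot toy states, with the
    clinical catalog replaced by the toy action indices."""
    from .mdp import MDPSpec, RewardWeights

    return MDPSpec(
        electrolyte="K",
        state_features=tuple(f"s{i}" for i in range(mdp.n_states)),
        reward_weights=RewardWeights(0.25, 0.25, 0.25, 0.25),
        gamma=mdp.gamma,
        catalog_override=list(range(mdp.n_actions)),
    )
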