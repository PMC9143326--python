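"""Offline policy learning via fitted Q-iteration (FQI).

FQI repeatedly regresses bootstrapped Q-targets from a fixed batch of
one-step transitions: iteration 1 fits y = r; iteration k fits

    y = r + gamma * max_a' Q_{k-1}(s', a')          (terminal: y = r)

on inputs [state || one-hot(action)].  The greedy policy reads off the
argmax over the catalog, ties broken by catalog order with NONE first (do
not treat on indifference), and is decoded hierarchically for clinicians:
replete? -> route -> dose/duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import joblib
import numpy as np

from .mdp import MDPSpec, RepletionAction, TransitionSample, catalog_to_frame
from .regressors import make_regressor


class TransitionDataset:
    """Dense array view of a list of transition samples.

    Built once and shared by FQI, FQE, and IRL so that re-pricing rewards
    under new weights or re-running the fitted loops never re-parses the
    samples.
    """

    def __init__(self, samples: Sequence[TransitionSample], n_actions: int):
        if not samples:
            raise ValueError("transition set is empty")
        n = len(samples)
        d = len(samples[0].state)
        self.n_actions = n_actions
        self.states = np.zeros((n, d), dtype=np.float32)
        self.action_idx = np.zeros(n, dtype=np.int64)
        self.rewards = np.zeros(n, dtype=np.float64)
        self.phi = np.zeros((n, 4), dtype=np.float64)
        self.terminal = np.zeros(n, dtype=bool)
        self.next_states = np.zeros((n, d), dtype=np.float32)
        self.next_action_idx = np.full(n, -1, dtype=np.int64)
        self.visit_ids = np.empty(n, dtype=object)
        self.bin_index = np.zeros(n, dtype=np.int64)
        for i, s in enumerate(samples):
            if not (0 <= s.action_index < n_actions):
                raise ValueError(f"sample {i} action index {s.action_index} outside catalog")
            self.states[i] = s.state
            self.action_idx[i] = s.action_index
            self.rewards[i] = s.reward
            self.phi[i] = s.reward_features
            self.terminal[i] = s.terminal
            if s.next_state is not None:
                self.next_states[i] = s.next_state
                if s.next_action_index is not None and s.next_action_index >= 0:
                    self.next_action_idx[i] = s.next_action_index
            self.visit_ids[i] = s.visit_id
            self.bin_index[i] = s.bin_index
        self.nonterminal = ~self.terminal
        # first sample of each visit, for initial-state value estimates
        first = {}
        for i in range(n):
            key = self.visit_ids[i]
            if key not in first or self.bin_index[i] < self.bin_index[first[key]]:
                first[key] = i
        self.initial_idx = np.array(sorted(first.values()))

    @property
    def n(self) -> int:
        return len(self.rewards)

    @property
    def state_dim(self) -> int:
        return self.states.shape[1]

    def xa(self, states: np.ndarray, action_idx: np.ndarray) -> np.ndarray:
        """Encode [state || one-hot(action)] rows."""
        onehot = np.zeros((len(states), self.n_actions), dtype=np.float32)
        onehot[np.arange(len(states)), action_idx] = 1.0
        return np.hstack([states, onehot])

    def x_train(self) -> np.ndarray:
        return self.xa(self.states, self.action_idx)

    def x_next_all_actions(self) -> np.ndarray:
        """All (s', a') encodings for non-terminal samples, action-major
        blocks of shape (n_actions * n_nonterminal, d + n_actions)."""
        sn = self.next_states[self.nonterminal]
        m = len(sn)
        tiled = np.repeat(sn, self.n_actions, axis=0)
        eye = np.tile(np.eye(self.n_actions, dtype=np.float32), (m, 1))
        return np.hstack([tiled, eye])


@dataclass
class QFunction:
    """A fitted state-action value function over a discrete catalog.

    ``action_offsets`` holds the analytically known per-action reward
    component (the route costs); the regressor models the remainder, and
    predictions add the offset back.
    """

    regressor: Any
    catalog: list[RepletionAction]
    gamma: float
    n_iterations: int
    state_dim: int
    feature_names: tuple[str, ...] | None = None
    action_offsets: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_actions(self) -> int:
        return len(self.catalog)

    def _offsets(self) -> np.ndarray:
        if self.action_offsets is None:
            return np.zeros(self.n_actions)
        return np.asarray(self.action_offsets, dtype=float).reshape(self.n_actions)

    def q_matrix(self, states: np.ndarray) -> np.ndarray:
        """Q-values for every catalog action at each state: (N, |A|)."""
        states = np.atleast_2d(np.asarray(states, dtype=np.float32))
        n, k = len(states), self.n_actions
        tiled = np.repeat(states, k, axis=0)
        eye = np.tile(np.eye(k, dtype=np.float32), (n, 1))
        q = self.regressor.predict(np.hstack([tiled, eye]))
        return np.asarray(q, dtype=float).reshape(n, k) + self._offsets()[None, :]

    def q_values(self, states: np.ndarray, action_idx: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=np.float32))
        action_idx = np.asarray(action_idx, dtype=int)
        onehot = np.zeros((len(states), self.n_actions), dtype=np.float32)
        onehot[np.arange(len(states)), action_idx] = 1.0
        raw = np.asarray(self.regressor.predict(np.hstack([states, onehot])), dtype=float)
        return raw + self._offsets()[action_idx]


def fqi(
    samples: Sequence[TransitionSample] | TransitionDataset,
    spec: MDPSpec,
    n_iterations: int = 32,
    regressor_spec: Any = None,
    rng_seed: int = 0,
) -> QFunction:
    """Learn a Q-function from batch transitions by fitted Q-iteration."""
    data = samples if isinstance(samples, TransitionDataset) else TransitionDataset(
        samples, len(spec.catalog)
    )
    return _fqi_core(data, data.rewards, spec, n_iterations, regressor_spec, rng_seed)


def _fqi_core(
    data: TransitionDataset,
    rewards: np.ndarray,
    spec: MDPSpec,
    n_iterations: int,
    regressor_spec: Any,
    rng_seed: int,
) -> QFunction:
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    from .mdp import action_cost_offsets

    catalog = spec.catalog
    offsets = action_cost_offsets(catalog, spec.reward_weights)[:, 0]
    x_train = data.x_train()
    x_next = data.x_next_all_actions()  # fixed across iterations
    nt = data.nonterminal
    fit_shift = offsets[data.action_idx]
    reg = None
    y = rewards.copy()
    for k in range(n_iterations):
        reg = make_regressor(regressor_spec, random_state=rng_seed + k)
        if not np.isfinite(y).all():
            raise FloatingPointError(f"non-finite FQI targets at iteration {k + 1}")
        reg.fit(x_train, y - fit_shift)
        if k == n_iterations - 1:
            break
        q_next = np.asarray(reg.predict(x_next), dtype=float).reshape(-1, data.n_actions)
        q_next += offsets[None, :]
        y = rewards.copy()
        y[nt] += spec.gamma * q_next.max(axis=1)
    return QFunction(
        regressor=reg,
        catalog=catalog,
        gamma=spec.gamma,
        n_iterations=n_iterations,
        state_dim=data.state_dim,
        feature_names=tuple(spec.state_features),
        action_offsets=offsets,
        metadata={
            "n_samples": data.n,
            "rng_seed": rng_seed,
            "regressor_spec": repr(regressor_spec),
            "electrolyte": spec.electrolyte,
        },
    )


@dataclass
class Policy:
    """Greedy readout of a Q-function (deterministic, NONE-first ties)."""

    q: QFunction

    @property
    def catalog(self) -> list[RepletionAction]:
        return self.q.catalog

    def action_indices(self, states: np.ndarray) -> np.ndarray:
        qm = self.q.q_matrix(states)
        # np.argmax takes the first maximizer; catalog order puts NONE first
        return qm.argmax(axis=1)

    def act(self, state: np.ndarray) -> int:
        return int(self.action_indices(np.atleast_2d(state))[0])

    def __call__(self, state: np.ndarray, rng=None) -> int:
        return self.act(state)


def greedy_policy(q: QFunction) -> Policy:
    return Policy(q)


@dataclass
class Recommendation:
    """Hierarchical decoding of one policy decision for clinician review."""

    replete: bool
    route: str | None
    po_dose_mg: float | None
    iv_dose: float | None
    iv_dose_unit: str | None
    iv_duration_h: float | None
    action_index: int
    q_values: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "replete": self.replete,
            "route": self.route,
            "po_dose_mg": self.po_dose_mg,
            "iv_dose": self.iv_dose,
            "iv_dose_unit": self.iv_dose_unit,
            "iv_duration_h": self.iv_duration_h,
            "action_index": self.action_index,
            "q_values": self.q_values,
        }


def recommend(policy: Policy, state: np.ndarray | dict) -> Recommendation:
    """Decode the greedy action at one state into the three-step hierarchy
    (replete? -> route -> dose/duration) with all Q-values for audit."""
    if isinstance(state, dict):
        names = policy.q.feature_names
        if names is None:
            raise ValueError("policy has no recorded feature order; pass an array state")
        missing = [f for f in names if f not in state]
        if missing:
            raise KeyError(f"state is missing features {missing}")
        state = np.array([float(state[f]) for f in names])
    state = np.asarray(state, dtype=float)
    if state.shape != (policy.q.state_dim,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({policy.q.state_dim},)"
        )
    qm = policy.q.q_matrix(state)[0]
    idx = int(qm.argmax())
    action = policy.catalog[idx]
    return Recommendation(
        replete=action.is_repletion,
        route=action.route if action.is_repletion else None,
        po_dose_mg=action.po_dose_mg,
        iv_dose=action.iv_dose,
        iv_dose_unit=action.iv_dose_unit,
        iv_duration_h=action.iv_duration_h,
        action_index=idx,
        q_values={a.label(): float(v) for a, v in zip(policy.catalog, qm)},
    )


def save_policy(q: QFunction, directory: str | Path) -> None:
    """Serialize a policy artifact: regressor dump plus a JSON sidecar with
    the catalog, feature order, gamma, seed, and iteration count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(q.regressor, directory / "regressor.joblib")
    sidecar = {
        "gamma": q.gamma,
        "n_iterations": q.n_iterations,
        "state_dim": q.state_dim,
        "action_offsets": None if q.action_offsets is None else list(map(float, q.action_offsets)),
        "feature_names": list(q.feature_names) if q.feature_names else None,
        "metadata": q.metadata,
        "catalog": catalog_to_frame(q.catalog).to_dict(orient="records"),
        "electrolyte": q.catalog[0].electrolyte,
    }
    (directory / "policy.json").write_text(json.dumps(sidecar, indent=2))


def load_policy(directory: str | Path) -> QFunction:
    from .mdp import action_catalog

    directory = Path(directory)
    sidecar = json.loads((directory / "policy.json").read_text())
    return QFunction(
        regressor=joblib.load(directory / "regressor.joblib"),
        catalog=action_catalog(sidecar["electrolyte"]),
        gamma=sidecar["gamma"],
        n_iterations=sidecar["n_iterations"],
        state_dim=sidecar["state_dim"],
        feature_names=tuple(sidecar["feature_names"]) if sidecar["feature_names"] else None,
        action_offsets=(
            np.array(sidecar["action_offsets"]) if sidecar.get("action_offsets") else None
        ),
        metadata=sidecar["metadata"],
    )
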