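"""Inverse reinforcement learning of the four repletion reward weights.

Recovers the relative weights (IV cost, PO cost, above-range, below-range)
under which observed repletion behavior is near-optimal, via apprenticeship
learning by feature-expectation matching.  The discounted feature
expectation of a policy,

    mu = E[ sum_t gamma^t phi(s_t, a_t, s_{t+1}) ],

is a 4-vector; each candidate policy's mu is estimated model-free by
per-component fitted-Q evaluation on the logged samples (so the procedure
also works on real, non-simulable data), and the matching target is
behavior's mu estimated with the same machinery, so the estimator's
smoothing bias cancels in the comparison.  The projection variant of the
matching loop is used; it permits negative weights, which observed
historical behavior can in fact exhibit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .evaluation import _fitted_q_evaluation_core
from .mdp import MDPSpec, RewardWeights, TransitionSample, normalize_weights
from .policy import Policy, TransitionDataset, _fqi_core, greedy_policy

logger = logging.getLogger(__name__)


@dataclass
class FeatureExpectation:
    """Discounted expected penalty features, averaged over visits."""

    mu: np.ndarray
    gamma: float
    n_visits: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (4,):
            raise ValueError("mu must be a 4-vector")


def behavior_feature_expectations(
    samples: Sequence[TransitionSample] | TransitionDataset,
    gamma: float,
    n_actions: int | None = None,
) -> FeatureExpectation:
    """mu = mean over visits of sum_t gamma^t phi_t (t = step within visit,
    terminal step included)."""
    if isinstance(samples, TransitionDataset):
        data = samples
    else:
        samples = list(samples)
        if not samples:
            raise ValueError("behavior_feature_expectations needs samples")
        k = n_actions if n_actions is not None else int(max(s.action_index for s in samples)) + 1
        data = TransitionDataset(samples, k)
    if data.n == 0:
        raise ValueError("behavior_feature_expectations needs samples")
    mus = []
    order = np.lexsort((data.bin_index, np.array([str(v) for v in data.visit_ids])))
    cur_visit, acc, t = None, None, 0
    for i in order:
        v = data.visit_ids[i]
        if v != cur_visit:
            if acc is not None:
                mus.append(acc)
            cur_visit, acc, t = v, np.zeros(4), 0
        acc = acc + (gamma ** t) * data.phi[i]
        t += 1
    if acc is not None:
        mus.append(acc)
    mu = np.mean(mus, axis=0)
    return FeatureExpectation(mu=mu, gamma=gamma, n_visits=len(mus))


def policy_feature_expectations(
    policy: Policy | str,
    data: TransitionDataset,
    spec: MDPSpec,
    n_iterations: int = 16,
    regressor_spec: Any = None,
    rng_seed: int = 0,
    eval_states: str = "initial",
) -> FeatureExpectation:
    """Model-free estimate of a policy's discounted feature expectations:
    one multi-output FQE over the four phi components, read off under the
    policy's own action choice.  Passing the string ``"behavior"``
    evaluates the logged policy (recorded next actions), which yields a
    behavior mu with the same estimator bias as candidate mus — the
    right-hand side for matching comparisons.

    ``eval_states="initial"`` reads the estimate at each visit's first bin
    (the definitional start-state expectation); ``"all"`` averages the
    feature-to-go over every logged state, an occupancy-weighted variant
    with far lower variance that matching comparisons use."""
    from .mdp import action_cost_offsets

    behavior = isinstance(policy, str)
    if behavior:
        next_a = data.next_action_idx[data.nonterminal]
        if (next_a < 0).any():
            raise ValueError("behavior evaluation needs logged next actions")
    else:
        next_a = policy.action_indices(data.next_states[data.nonterminal])
    offsets = action_cost_offsets(spec.catalog, spec.reward_weights, n_targets=4)
    reg = _fitted_q_evaluation_core(
        data, data.phi, next_a, spec.gamma, n_iterations, regressor_spec, rng_seed,
        offsets=offsets,
    )
    if eval_states == "all":
        s0 = data.states
        a0 = data.action_idx if behavior else policy.action_indices(s0)
        n_eval = data.n
    else:
        s0 = data.states[data.initial_idx]
        a0 = data.action_idx[data.initial_idx] if behavior else policy.action_indices(s0)
        n_eval = len(data.initial_idx)
    x0 = data.xa(s0, a0)
    mu0 = np.asarray(reg.predict(x0), dtype=float) + offsets[a0]
    return FeatureExpectation(mu=mu0.mean(axis=0), gamma=spec.gamma, n_visits=n_eval)


@dataclass
class IRLDiagnostics:
    """Trajectory of the matching loop (for audit and non-convergence
    reporting)."""

    matching_errors: list[float] = field(default_factory=list)
    best_errors: list[float] = field(default_factory=list)
    weights_path: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    degenerate: bool = False
    n_outer_iters: int = 0
    mu_behavior: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "matching_errors": self.matching_errors,
            "best_errors": self.best_errors,
            "weights_path": [w.tolist() for w in self.weights_path],
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_outer_iters": self.n_outer_iters,
            "mu_behavior": None if self.mu_behavior is None else self.mu_behavior.tolist(),
        }


def matching_statistic(
    policy: Policy | str,
    data: TransitionDataset,
    spec: MDPSpec,
    fqe_iterations: int = 10,
    regressor_spec: Any = None,
    rng_seed: int = 0,
) -> np.ndarray:
    """Per-step penalty-feature profile of a policy on the logged states.

    The IV/PO components are exact state-matched usage rates — the action
    cost part of phi is deterministic in the chosen action, so no estimator
    is needed.  The above-/below-range components are discounted exposures
    to-go estimated by two-output FQE at every logged state, scaled by
    (1 - gamma) to a per-step rate so all four components are commensurate.
    Behavior (``policy="behavior"``) uses logged actions throughout, giving
    both sides of a matching comparison the same estimator per component.
    """
    from .mdp import RepletionAction

    behavior = isinstance(policy, str)
    catalog = spec.catalog
    has_iv = np.array(
        [a.has_iv if isinstance(a, RepletionAction) else False for a in catalog], dtype=float
    )
    has_po = np.array(
        [a.has_po if isinstance(a, RepletionAction) else False for a in catalog], dtype=float
    )
    if behavior:
        acts = data.action_idx
        next_a = data.next_action_idx[data.nonterminal]
        if (next_a < 0).any():
            raise ValueError("behavior evaluation needs logged next actions")
    else:
        acts = policy.action_indices(data.states)
        next_a = policy.action_indices(data.next_states[data.nonterminal])
    usage_iv = float(has_iv[acts].mean())
    usage_po = float(has_po[acts].mean())
    reg = _fitted_q_evaluation_core(
        data, data.phi[:, 2:4], next_a, spec.gamma, fqe_iterations, regressor_spec, rng_seed
    )
    x_all = data.xa(data.states, acts)
    togo = np.asarray(reg.predict(x_all), dtype=float).mean(axis=0)
    rate_high, rate_low = (1.0 - spec.gamma) * togo
    return np.array([usage_iv, usage_po, float(rate_high), float(rate_low)])


#: Initial weight proposals: the simplex centroid plus, per component, a
#: moderately dominant point (ratio 7 to the others) and a strongly dominant
#: one (ratio 22).  Interior points keep every route cost positive (a
#: zero-cost proposal makes repletion free, so its "optimal" policy is tie
#: noise).  The two dominance rings matter because the induced policy is
#: driven by penalty-to-cost *ratios* — how eagerly to treat — so the grid
#: must span ratios, not just orderings, for the hull to bracket behavior.
DEFAULT_ANCHORS = (
    (0.25, 0.25, 0.25, 0.25),
    (0.7, 0.1, 0.1, 0.1),
    (0.1, 0.7, 0.1, 0.1),
    (0.1, 0.1, 0.7, 0.1),
    (0.1, 0.1, 0.1, 0.7),
    (0.88, 0.04, 0.04, 0.04),
    (0.04, 0.88, 0.04, 0.04),
    (0.04, 0.04, 0.88, 0.04),
    (0.04, 0.04, 0.04, 0.88),
)


def irl_weights(
    samples: Sequence[TransitionSample] | TransitionDataset,
    spec: MDPSpec,
    fqi_iterations: int = 5,
    fqe_iterations: int = 10,
    regressor_spec: Any = None,
    fqe_regressor_spec: Any = None,
    max_outer_iters: int = 10,
    tol: float = 0.05,
    rng_seed: int = 0,
    anchors: Sequence[Sequence[float]] = DEFAULT_ANCHORS,
) -> tuple[RewardWeights, IRLDiagnostics]:
    """Estimate the reward weights driving logged behavior.

    Projection-style feature matching: propose weights w, learn the optimal
    policy under penalty reward -w.phi by FQI on the behavior samples,
    estimate that policy's feature expectations mu_w by per-component FQE,
    and score the proposal by ||mu_behavior - mu_w||.  The first proposals
    are the fixed ``anchors``; subsequent ones follow the projection update,
    moving w along the residual of projecting mu_behavior onto the convex
    hull of the candidates' feature expectations.  The reported weights are
    the best-scoring proposal (behavior's best single-reward explanation);
    iteration stops when a proposal scores below ``tol`` or after
    ``max_outer_iters`` proposals.  On non-convergence the best-so-far
    weights are returned with ``diagnostics.converged=False`` (never
    silently).  The output is L1-normalized with signs unconstrained.
    """
    data = samples if isinstance(samples, TransitionDataset) else TransitionDataset(
        samples, len(spec.catalog)
    )
    if fqe_regressor_spec is None:
        fqe_regressor_spec = regressor_spec
    diag = IRLDiagnostics()
    mu_direct = behavior_feature_expectations(data, spec.gamma).mu
    if np.allclose(mu_direct, 0.0):
        # no penalties ever observed: weights are unidentifiable
        diag.degenerate = True
        diag.mu_behavior = mu_direct
        logger.warning("IRL: behavior feature expectations are all zero; weights unidentifiable")
        return normalize_weights([0.25, 0.25, 0.25, 0.25]), diag
    # behavior's per-step feature profile, estimated component-wise with
    # the same machinery the candidates get (exact usage rates; FQE range
    # exposures), so estimator bias cancels in the comparison
    mu_b = matching_statistic(
        "behavior", data, spec, fqe_iterations, fqe_regressor_spec, rng_seed + 17
    )
    diag.mu_behavior = mu_b

    # work in psi = -phi space so that "maximize w.psi" = "minimize penalty"
    psi_b = -mu_b

    def policy_psi(w: np.ndarray, k: int) -> np.ndarray:
        rewards = -(data.phi @ w)
        w_spec = MDPSpec(
            electrolyte=spec.electrolyte,
            state_features=spec.state_features,
            reward_weights=RewardWeights(*w),
            gamma=spec.gamma,
            reference_range=spec.reference_range,
            catalog_override=spec.catalog_override,
        )
        # common random numbers: every proposal shares the same inner
        # seeds, so matching-error differences reflect the proposals rather
        # than regression seed draws
        q = _fqi_core(data, rewards, w_spec, fqi_iterations, regressor_spec, rng_seed + 7)
        pol = greedy_policy(q)
        mu_pi = matching_statistic(
            pol, data, w_spec, fqe_iterations, fqe_regressor_spec, rng_seed + 31
        )
        return -mu_pi

    proposals = [np.asarray(a, dtype=float) for a in anchors]
    psi_bar = None
    best_err, best_w = np.inf, None
    for k in range(max_outer_iters):
        if k < len(proposals):
            w = proposals[k]
        else:
            residual = psi_b - psi_bar
            if np.abs(residual).sum() < 1e-10:
                break  # hull contains behavior's mu; nothing left to propose
            w = residual
        w_norm = w / max(np.abs(w).sum(), 1e-12)
        diag.weights_path.append(w_norm)
        psi_pi = policy_psi(w_norm, k)
        err = float(np.linalg.norm(psi_b - psi_pi))
        diag.matching_errors.append(err)
        if err < best_err:
            best_err, best_w = err, w_norm
        diag.best_errors.append(best_err)
        diag.n_outer_iters = k + 1
        if best_err <= tol:
            diag.converged = True
            break
        # project psi_b onto the growing convex hull of candidate-policy
        # feature expectations; the residual proposes the next direction
        if psi_bar is None:
            psi_bar = psi_pi
        else:
            d = psi_pi - psi_bar
            denom = float(d @ d)
            if denom > 1e-12:
                step = float(d @ (psi_b - psi_bar)) / denom
                psi_bar = psi_bar + np.clip(step, 0.0, 1.0) * d
    if not diag.converged:
        logger.warning(
            "IRL did not reach tol=%.3g in %d proposals (best matching error %.3g); "
            "returning the best-so-far weights",
            tol, max_outer_iters, best_err,
        )
    return normalize_weights(best_w), diag
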