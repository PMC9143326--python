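"""Off-policy evaluation and descriptive policy comparison.

Fitted-Q evaluation (FQE) estimates the value of a *fixed* policy from
logged transitions by iterating

    y = r + gamma * Qhat_{k-1}(s', pi(s'))          (terminal: y = r)

Evaluating the historical (behavior) policy substitutes the logged next
action for pi(s').  The descriptive comparisons are state-matched: the
learned policy is queried at the historically visited states, because the
counterfactual trajectory after a deviation is unknowable from retrospective
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .mdp import MDPSpec, RepletionAction, TransitionSample, action_cost_offsets
from .policy import Policy, QFunction, TransitionDataset
from .regressors import make_regressor

BEHAVIOR = "behavior"  # sentinel: evaluate the logged historical policy


def _fitted_q_evaluation_core(
    data: TransitionDataset,
    targets: np.ndarray,
    next_actions: np.ndarray,
    gamma: float,
    n_iterations: int,
    regressor_spec: Any,
    rng_seed: int,
    offsets: np.ndarray | None = None,
):
    """Shared FQE loop; ``targets`` may be (n,) rewards or (n, k) feature
    columns (evaluated jointly with a multi-output regressor).  ``offsets``
    ((|A|,) or (|A|, k)) is the analytically known per-action part of the
    target; the regressor fits the remainder."""
    x_train = data.x_train()
    nt = data.nonterminal
    x_next = data.xa(data.next_states[nt], next_actions)
    if offsets is None:
        offsets = np.zeros((data.n_actions,) + targets.shape[1:])
    fit_shift = offsets[data.action_idx]
    next_shift = offsets[next_actions]
    y = targets.copy()
    reg = None
    for k in range(n_iterations):
        reg = make_regressor(regressor_spec, random_state=rng_seed + 10_000 + k)
        if not np.isfinite(y).all():
            raise FloatingPointError(f"non-finite FQE targets at iteration {k + 1}")
        reg.fit(x_train, y - fit_shift)
        if k == n_iterations - 1:
            break
        q_next = np.asarray(reg.predict(x_next), dtype=float) + next_shift
        y = targets.copy()
        y[nt] = targets[nt] + gamma * q_next
    return reg


def _policy_next_actions(
    data: TransitionDataset, policy: Policy | str
) -> np.ndarray:
    if policy == BEHAVIOR:
        next_a = data.next_action_idx[data.nonterminal]
        if (next_a < 0).any():
            raise ValueError("behavior FQE needs the logged next action on every non-terminal sample")
        return next_a
    return policy.action_indices(data.next_states[data.nonterminal])


@dataclass
class FQEResult:
    """Fitted Qhat^pi estimator plus summary values on the evaluated set."""

    q: QFunction
    policy_label: str
    mean_value_on_pairs: float  # mean Qhat^pi over the logged (s, a) pairs
    mean_initial_value: float  # mean Qhat^pi(s0, pi(s0)) over visits
    values_on_pairs: np.ndarray
    n_samples: int
    gamma: float


def fqe(
    policy: Policy | str,
    samples: Sequence[TransitionSample] | TransitionDataset,
    spec: MDPSpec,
    n_iterations: int = 32,
    regressor_spec: Any = None,
    rng_seed: int = 0,
) -> FQEResult:
    """Estimate the value of ``policy`` (or of the logged historical policy,
    ``policy=BEHAVIOR``) from off-policy transition samples."""
    catalog = spec.catalog
    data = samples if isinstance(samples, TransitionDataset) else TransitionDataset(
        samples, len(catalog)
    )
    next_a = _policy_next_actions(data, policy)
    offsets = action_cost_offsets(catalog, spec.reward_weights)[:, 0]
    reg = _fitted_q_evaluation_core(
        data, data.rewards, next_a, spec.gamma, n_iterations, regressor_spec, rng_seed,
        offsets=offsets,
    )
    q = QFunction(
        regressor=reg,
        catalog=catalog,
        gamma=spec.gamma,
        n_iterations=n_iterations,
        state_dim=data.state_dim,
        feature_names=tuple(spec.state_features),
        action_offsets=offsets,
        metadata={"kind": "fqe", "n_samples": data.n},
    )
    values = q.q_values(data.states, data.action_idx)
    s0 = data.states[data.initial_idx]
    if policy == BEHAVIOR:
        a0 = data.action_idx[data.initial_idx]
    else:
        a0 = policy.action_indices(s0)
    v0 = q.q_values(s0, a0)
    return FQEResult(
        q=q,
        policy_label=BEHAVIOR if policy == BEHAVIOR else "learned",
        mean_value_on_pairs=float(values.mean()),
        mean_initial_value=float(v0.mean()),
        values_on_pairs=values,
        n_samples=data.n,
        gamma=spec.gamma,
    )


@dataclass
class PolicyValueReport:
    """Side-by-side FQE of the learned policy and historical behavior on the
    identical sample set (the Fig-5-style comparison)."""

    learned: FQEResult
    behavior: FQEResult

    @property
    def mean_gap(self) -> float:
        return self.learned.mean_value_on_pairs - self.behavior.mean_value_on_pairs

    def to_dict(self) -> dict:
        return {
            "gamma": self.learned.gamma,
            "n_samples": self.learned.n_samples,
            "learned_mean_q": self.learned.mean_value_on_pairs,
            "behavior_mean_q": self.behavior.mean_value_on_pairs,
            "learned_mean_initial_value": self.learned.mean_initial_value,
            "behavior_mean_initial_value": self.behavior.mean_initial_value,
            "mean_gap": self.mean_gap,
        }


def policy_value_report(
    policy: Policy,
    samples: Sequence[TransitionSample] | TransitionDataset,
    spec: MDPSpec,
    n_iterations: int = 32,
    regressor_spec: Any = None,
    rng_seed: int = 0,
) -> PolicyValueReport:
    data = samples if isinstance(samples, TransitionDataset) else TransitionDataset(
        samples, len(spec.catalog)
    )
    learned = fqe(policy, data, spec, n_iterations, regressor_spec, rng_seed)
    behavior = fqe(BEHAVIOR, data, spec, n_iterations, regressor_spec, rng_seed + 1)
    return PolicyValueReport(learned=learned, behavior=behavior)


@dataclass
class FrequencyReport:
    """Action-frequency comparison: historical log vs the policy queried at
    the same states."""

    action_labels: list[str]
    historical_counts: np.ndarray
    policy_counts: np.ndarray
    n_states: int
    historical_repletions: int
    policy_repletions: int
    repletion_change_pct: float | None  # None when history has no repletions
    historical_route_mix: dict[str, float]
    policy_route_mix: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "historical_repletions": self.historical_repletions,
            "policy_repletions": self.policy_repletions,
            "repletion_change_pct": self.repletion_change_pct,
            "historical_route_mix": self.historical_route_mix,
            "policy_route_mix": self.policy_route_mix,
            "per_action": [
                {"label": lbl, "historical": int(h), "policy": int(p)}
                for lbl, h, p in zip(self.action_labels, self.historical_counts, self.policy_counts)
            ],
        }


def _route_mix(actions: Sequence[RepletionAction], idx: np.ndarray) -> dict[str, float]:
    routes = np.array([actions[i].route for i in idx])
    n = len(routes)
    return {r: float((routes == r).sum()) / n for r in ("NONE", "PO", "IV", "BOTH")}


def frequency_analysis(
    samples: Sequence[TransitionSample] | TransitionDataset,
    policy: Policy,
    catalog: Sequence[RepletionAction] | None = None,
) -> FrequencyReport:
    """Count historical vs policy-recommended actions over the same states."""
    catalog = list(catalog) if catalog is not None else policy.catalog
    data = samples if isinstance(samples, TransitionDataset) else TransitionDataset(
        samples, len(catalog)
    )
    hist_idx = data.action_idx
    pol_idx = policy.action_indices(data.states)
    k = len(catalog)
    hist_counts = np.bincount(hist_idx, minlength=k)
    pol_counts = np.bincount(pol_idx, minlength=k)
    hist_rep = int((hist_idx != 0).sum())
    pol_rep = int((pol_idx != 0).sum())
    change = None if hist_rep == 0 else (pol_rep - hist_rep) / hist_rep * 100.0
    labels = [a.label() if isinstance(a, RepletionAction) else str(a) for a in catalog]
    return FrequencyReport(
        action_labels=labels,
        historical_counts=hist_counts,
        policy_counts=pol_counts,
        n_states=data.n,
        historical_repletions=hist_rep,
        policy_repletions=pol_rep,
        repletion_change_pct=change,
        historical_route_mix=_route_mix(catalog, hist_idx),
        policy_route_mix=_route_mix(catalog, pol_idx),
    )


@dataclass
class PrePostSummary:
    """Distributions of electrolyte levels around historical repletions."""

    pre_levels: np.ndarray
    post_levels: np.ndarray
    n_events: int
    n_events_with_pre: int
    frac_within_or_above: float  # pre-level >= range low
    frac_above: float  # pre-level > range high
    frac_below: float
    frac_post_in_range: float

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_events_with_pre": self.n_events_with_pre,
            "frac_within_or_above": self.frac_within_or_above,
            "frac_above": self.frac_above,
            "frac_below": self.frac_below,
            "frac_post_in_range": self.frac_post_in_range,
            "pre_levels": self.pre_levels.tolist(),
            "post_levels": self.post_levels.tolist(),
        }


def pre_post_distribution(
    binned_visits: Sequence,
    electrolyte: str,
    reference_range: tuple[float, float],
) -> PrePostSummary:
    """Pre- and post-repletion level distributions from real measurements.

    For every historical repletion event (bin with a repletion drug row): the
    pre level is the last *observed* bin value at or before the event bin;
    the post level is the first observed bin value in a bin strictly after
    the bin containing the infusion end.  Imputed cells never count.
    """
    lo, hi = reference_range
    drug_prefix = f"{electrolyte}-"
    pre_list, post_list = [], []
    n_events = 0
    for visit in binned_visits:
        meds = visit.medications
        if not len(meds):
            continue
        mine = meds[meds["drug"].str.startswith(drug_prefix)]
        if not len(mine):
            continue
        observed = visit.mask[electrolyte] if electrolyte in visit.mask else None
        values = visit.features[electrolyte] if electrolyte in visit.features else None
        for b, rows in mine.groupby("bin_index"):
            n_events += 1
            if observed is None:
                continue
            obs_bins = np.flatnonzero(observed.to_numpy())
            pre_bins = obs_bins[obs_bins <= b]
            pre = float(values.iloc[pre_bins[-1]]) if len(pre_bins) else np.nan
            end_bin = int(rows["end_hours"].max() // visit.bin_width)
            post_bins = obs_bins[obs_bins > end_bin]
            post = float(values.iloc[post_bins[0]]) if len(post_bins) else np.nan
            pre_list.append(pre)
            post_list.append(post)
    pre = np.array(pre_list, dtype=float)
    post = np.array(post_list, dtype=float)
    pre_ok = pre[np.isfinite(pre)]
    post_ok = post[np.isfinite(post)]
    n_pre = len(pre_ok)
    frac = lambda x: float(x.sum()) / n_pre if n_pre else float("nan")
    return PrePostSummary(
        pre_levels=pre,
        post_levels=post,
        n_events=n_events,
        n_events_with_pre=n_pre,
        frac_within_or_above=frac(pre_ok >= lo),
        frac_above=frac(pre_ok > hi),
        frac_below=frac(pre_ok < lo),
        frac_post_in_range=(
            float(((post_ok >= lo) & (post_ok <= hi)).sum()) / len(post_ok)
            if len(post_ok)
            else float("nan")
        ),
    )


def trajectory_overlay(visit, policy: Policy, spec: MDPSpec) -> pd.DataFrame:
    """Per-bin table aligning measurements, historical actions, and policy
    recommendations for one visit (the single-trajectory figure layout).

    Columns: bin_index, hour_start, measured_level (NaN when the bin had no
    real measurement), imputed_level, historical_action, policy_action, and
    infusion spans (start/end hours) for IV components of both columns.
    """
    from .mdp import visit_state_actions

    states, actions, a_idx, levels = visit_state_actions(visit, spec)
    pol_idx = policy.action_indices(states)
    catalog = spec.catalog
    observed = (
        visit.mask[spec.electrolyte].to_numpy()
        if spec.electrolyte in visit.mask
        else np.zeros(visit.n_bins, dtype=bool)
    )
    rows = []
    for t in range(visit.n_bins):
        hour = t * visit.bin_width
        hist = actions[t]
        pol = catalog[int(pol_idx[t])]
        rows.append(
            {
                "bin_index": t,
                "hour_start": hour,
                "measured_level": levels[t] if observed[t] else np.nan,
                "imputed_level": levels[t],
                "historical_action": hist.label() if hist.is_repletion else "",
                "policy_action": pol.label() if pol.is_repletion else "",
                "historical_iv_start": hour if hist.has_iv else np.nan,
                "historical_iv_end": hour + hist.iv_duration_h if hist.has_iv else np.nan,
                "policy_iv_start": hour if pol.has_iv else np.nan,
                "policy_iv_end": hour + pol.iv_duration_h if pol.has_iv else np.nan,
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_return(returns: np.ndarray) -> float:
    """Mean discounted return of simulator rollouts (the on-policy check
    against FQE's initial-state value)."""
    return float(np.asarray(returns).mean())
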