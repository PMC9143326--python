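"""Seeded synthetic ICU cohort generator.

Real electrolyte-repletion extracts from hospital EHR systems are not
redistributable, so this module fabricates cohorts with the statistical
structure the downstream analysis assumes:

* first-order mean-reverting serum electrolyte dynamics with an additive,
  immediate dose response to PO/IV repletion and a negative illness drift
  that produces hypo-electrolyte episodes;
* a threshold-driven clinician behavior policy with a configurable tendency
  to replete even when the level is already at or above threshold
  (over-repletion);
* irregular sampling — labs drawn with probability ``measurement_prob`` per
  6-h bin, vitals missing with probability ``missing_prob_vitals``;
* long-format output tables (static / observations / medications) matching
  the ingestion contract of :mod:`replete.cohort`.

The dynamics are deliberately the simplest ones under which "replete only
when the level is low" is the optimal policy, so that learned policies can be
judged against a known ground truth.  Nothing here reproduces the statistics
of any real hospital system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mdp import (
    DEFAULT_REFERENCE_RANGES,
    MDPSpec,
    RepletionAction,
    RewardWeights,
    TransitionSample,
    action_catalog,
    catalog_index,
    reward,
)

BIN_HOURS = 6.0

#: Nuisance vitals/labs emitted as stationary noise: name -> (mean, sd).
NUISANCE_VARIABLES: dict[str, tuple[float, float]] = {
    "heart_rate": (85.0, 12.0),
    "resp_rate": (18.0, 4.0),
    "temp": (37.0, 0.5),
    "spo2": (96.5, 2.0),
    "bp_sys": (120.0, 15.0),
    "bp_dia": (70.0, 10.0),
    "creatinine": (1.1, 0.35),
    "glucose": (130.0, 28.0),
    "hemoglobin": (10.5, 1.4),
}

STATIC_COLUMNS = ["visit_id", "age", "sex", "admit_weight"]
OBSERVATION_COLUMNS = ["visit_id", "time_hours", "variable", "value"]
MEDICATION_COLUMNS = ["visit_id", "start_hours", "end_hours", "drug", "dose", "route"]


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (one electrolyte per cohort)."""

    n_visits: int = 500
    horizon_hours: float = 120.0
    electrolyte: str = "K"
    setpoint: float = 4.0  # healthy attractor, electrolyte units
    reversion_rate: float = 0.25  # fraction of the gap closed per 6-h bin
    illness_drift: float = -0.1  # shift of the attractor while ill
    noise_sd: float = 0.12  # per-bin process noise, electrolyte units
    po_effect_per_unit: float = 0.25  # level gain per PO catalog dose level
    iv_effect_per_unit: float = 0.3  # level gain per IV catalog dose level
    measurement_prob: float = 0.9  # P(a bin contains an electrolyte lab draw)
    missing_prob_vitals: float = 0.2
    reference_range: tuple[float, float] = (3.5, 5.0)
    rng_seed: int = 0
    # abrupt depletion episodes: with probability shock_prob per bin the
    # noise term carries an extra N(shock_mean, shock_sd) drop.  Shocks are
    # sized to overshoot the reference band from any in-range level, so
    # "topping up" an in-range patient cannot prevent a range violation and
    # repleting only when low is the optimal policy.
    shock_prob: float = 0.06
    shock_mean: float = -2.0
    shock_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.reversion_rate <= 1.0:
            raise ValueError("reversion_rate must be in [0, 1]")
        for p in (self.measurement_prob, self.missing_prob_vitals, self.shock_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not self.reference_range[0] < self.reference_range[1]:
            raise ValueError("reference_range must satisfy low < high")
        if self.n_visits <= 0:
            raise ValueError("n_visits must be positive")

    @property
    def horizon_bins(self) -> int:
        return int(self.horizon_hours // BIN_HOURS)


@dataclass(frozen=True)
class BehaviorConfig:
    """Threshold-driven clinician behavior policy.

    Below ``replete_threshold`` a repletion is always ordered; at or above it
    one is ordered with probability ``over_replete_prob`` (the over-repletion
    tendency seen in historical ICU practice).  The route is IV with
    probability ``iv_prob_given_replete``, otherwise PO; the dose tier is
    drawn from ``dose_level_probs``.
    """

    replete_threshold: float = 3.5
    over_replete_prob: float = 0.3
    iv_prob_given_replete: float = 0.25
    dose_level_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    rng_seed: int = 0
    # with this probability a repletion gains the other route's component as
    # well (a PO+IV combination order); IV dose tiers are drawn from
    # iv_dose_level_probs, or uniformly over the catalog's IV levels when
    # None.  Both keep the logged data covering the whole action catalog,
    # which offline policy learning needs.
    both_prob_given_replete: float = 0.05
    iv_dose_level_probs: tuple[float, ...] | None = None
    # probability that a below-threshold level goes unaddressed for one
    # interval (missed or delayed recognition).  Provider-driven care does
    # leave hypo-episodes untreated, and logged data needs some "no action
    # while low" coverage for the below-range penalty to be identifiable
    # from it offline.
    low_miss_prob: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.over_replete_prob, self.iv_prob_given_replete,
                  self.both_prob_given_replete, self.low_miss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.iv_dose_level_probs is not None:
            if any(p < 0 for p in self.iv_dose_level_probs) or abs(sum(self.iv_dose_level_probs) - 1.0) > 1e-9:
                raise ValueError("iv_dose_level_probs must be a distribution")
        if any(p < 0 for p in self.dose_level_probs):
            raise ValueError("dose_level_probs must be non-negative")
        if abs(sum(self.dose_level_probs) - 1.0) > 1e-9:
            raise ValueError("dose_level_probs must sum to 1")


_ELECTROLYTE_DEFAULTS: dict[str, dict] = {
    "K": dict(setpoint=4.0, illness_drift=-0.1, noise_sd=0.12, po_effect_per_unit=0.25,
              iv_effect_per_unit=0.3, reference_range=(3.5, 5.0),
              shock_prob=0.06, shock_mean=-2.0, shock_sd=0.3),
    "Mg": dict(setpoint=2.0, illness_drift=-0.05, noise_sd=0.05, po_effect_per_unit=0.1,
               iv_effect_per_unit=0.12, reference_range=(1.7, 2.3),
               shock_prob=0.05, shock_mean=-0.7, shock_sd=0.12),
    "P": dict(setpoint=3.4, illness_drift=-0.1, noise_sd=0.15, po_effect_per_unit=0.3,
              iv_effect_per_unit=0.4, reference_range=(2.5, 4.5),
              shock_prob=0.06, shock_mean=-2.2, shock_sd=0.4),
}


def draw_process_noise(cfg: SimConfig, rng: np.random.Generator) -> float:
    """Per-bin noise: Gaussian jitter plus an occasional depletion shock."""
    noise = float(rng.normal(0.0, cfg.noise_sd))
    if cfg.shock_prob and rng.random() < cfg.shock_prob:
        noise += float(rng.normal(cfg.shock_mean, cfg.shock_sd))
    return noise


def default_sim_config(electrolyte: str = "K", **overrides) -> SimConfig:
    """Per-electrolyte defaults (K in mEq/L; Mg, P in mg/dL)."""
    params = dict(_ELECTROLYTE_DEFAULTS[electrolyte], electrolyte=electrolyte)
    params.update(overrides)
    return SimConfig(**params)


def default_behavior_config(cfg: SimConfig, **overrides) -> BehaviorConfig:
    params = dict(replete_threshold=cfg.reference_range[0])
    params.update(overrides)
    return BehaviorConfig(**params)


def step_dynamics(level, action: RepletionAction, cfg: SimConfig, noise):
    """One 6-h step of the mean-reverting dose-response dynamics.

    next = level + rho * (setpoint + drift - level)
                 + po_effect * po_level + iv_effect * iv_level + noise

    ``level`` and ``noise`` may be scalars or aligned arrays (a whole
    cohort stepped at once).
    """
    if not (np.all(np.isfinite(level)) and np.all(np.isfinite(noise))):
        raise ValueError(f"step_dynamics needs finite inputs (level={level}, noise={noise})")
    attractor = cfg.setpoint + cfg.illness_drift
    out = (
        level
        + cfg.reversion_rate * (attractor - level)
        + cfg.po_effect_per_unit * action.po_level
        + cfg.iv_effect_per_unit * action.iv_level
        + noise
    )
    return float(out) if np.isscalar(level) or np.ndim(level) == 0 else out


def behavior_action(
    level: float,
    bcfg: BehaviorConfig,
    catalog: Sequence[RepletionAction],
    rng: np.random.Generator,
) -> RepletionAction:
    """Sample the clinician behavior policy's action at one decision point."""
    if not catalog or catalog[0].route != "NONE":
        raise ValueError("catalog must be non-empty with the NONE action first")
    if level < bcfg.replete_threshold:
        replete = rng.random() >= bcfg.low_miss_prob
    else:
        replete = rng.random() < bcfg.over_replete_prob
    if not replete:
        return catalog[0]
    use_iv = rng.random() < bcfg.iv_prob_given_replete
    use_both = rng.random() < bcfg.both_prob_given_replete
    n_po = max(a.po_level for a in catalog)
    n_iv = max(a.iv_level for a in catalog)

    def po_tier() -> int:
        t = 1 + int(rng.choice(len(bcfg.dose_level_probs), p=np.asarray(bcfg.dose_level_probs)))
        return min(t, n_po)

    def iv_tier() -> int:
        if bcfg.iv_dose_level_probs is None:
            return 1 + int(rng.integers(n_iv))
        t = 1 + int(rng.choice(len(bcfg.iv_dose_level_probs), p=np.asarray(bcfg.iv_dose_level_probs)))
        return min(t, n_iv)

    if use_both:
        idx = catalog_index(catalog, "BOTH", po_level=po_tier(), iv_level=iv_tier())
    elif use_iv:
        idx = catalog_index(catalog, "IV", iv_level=iv_tier())
    else:
        idx = catalog_index(catalog, "PO", po_level=po_tier())
    return catalog[idx]


@dataclass
class CohortTables:
    """The three raw EHR tables plus a synthetic ground-truth event log.

    ``event_log`` records the true serum level at every repletion order; it
    exists only for validating downstream estimates and has no real-data
    counterpart.
    """

    static: pd.DataFrame
    observations: pd.DataFrame
    medications: pd.DataFrame
    event_log: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "static": outdir / "static.csv",
            "observations": outdir / "observations.csv",
            "medications": outdir / "medications.csv",
        }
        self.static.to_csv(paths["static"], index=False)
        self.observations.to_csv(paths["observations"], index=False)
        self.medications.to_csv(paths["medications"], index=False)
        self.event_log.to_csv(outdir / "event_log.csv", index=False)
        return paths


def simulate_cohort(cfg: SimConfig, bcfg: BehaviorConfig) -> CohortTables:
    """Generate a seeded cohort of ICU visits as long-format EHR tables.

    Visit lengths are uniform over whole 6-h bins between 18 h and the
    configured horizon (some below the 24-h cohort floor, on purpose, so the
    exclusion funnel has work to do).  Levels evolve per
    :func:`step_dynamics` under the behavior policy; labs report the true
    level at the bin start when drawn.  A vital is always emitted in the
    final bin so the length of stay is recoverable from the event stream.
    """
    if cfg.horizon_hours < 24:
        raise ValueError("horizon_hours must be >= 24 (cohort filter would reject all visits)")
    rng = np.random.default_rng(cfg.rng_seed)
    brng = np.random.default_rng(bcfg.rng_seed + 1_000_003)
    catalog = action_catalog(cfg.electrolyte)
    static_rows, obs_rows, med_rows, event_rows = [], [], [], []
    for v in range(cfg.n_visits):
        visit_id = f"V{v:05d}"
        n_bins = int(rng.integers(3, cfg.horizon_bins + 1))
        age = int(rng.integers(16, 93))
        sex = "F" if rng.random() < 0.5 else "M"
        weight = float(np.clip(rng.normal(80.0, 15.0), 40.0, 160.0))
        if rng.random() < 0.03:
            weight = np.nan
        static_rows.append((visit_id, age, sex, weight))
        level = float(rng.normal(cfg.setpoint, 0.3 * max(cfg.noise_sd, 0.05) / 0.12))
        for t in range(n_bins):
            bin_start = t * BIN_HOURS
            if rng.random() < cfg.measurement_prob:
                obs_rows.append((visit_id, bin_start, cfg.electrolyte, round(level, 4)))
            for var, (mu, sd) in NUISANCE_VARIABLES.items():
                forced_marker = var == "heart_rate" and t == n_bins - 1
                if forced_marker or rng.random() >= cfg.missing_prob_vitals:
                    t_obs = bin_start + (5.5 if forced_marker else float(rng.uniform(0.5, 5.0)))
                    obs_rows.append((visit_id, round(t_obs, 3), var, round(float(rng.normal(mu, sd)), 4)))
            action = behavior_action(level, bcfg, catalog, brng)
            if action.is_repletion:
                event_rows.append(
                    (visit_id, t, bin_start, round(level, 4), action.route, action.po_level, action.iv_level)
                )
                if action.has_po:
                    med_rows.append(
                        (visit_id, bin_start, bin_start + 0.5, f"{cfg.electrolyte}-PO",
                         action.po_dose_mg, "PO")
                    )
                if action.has_iv:
                    med_rows.append(
                        (visit_id, bin_start, bin_start + action.iv_duration_h,
                         f"{cfg.electrolyte}-IV", action.iv_dose, "IV")
                    )
            noise = draw_process_noise(cfg, rng)
            level = step_dynamics(level, action, cfg, noise)
    static = pd.DataFrame(static_rows, columns=STATIC_COLUMNS)
    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    medications = pd.DataFrame(med_rows, columns=MEDICATION_COLUMNS)
    event_log = pd.DataFrame(
        event_rows,
        columns=["visit_id", "bin_index", "time_hours", "true_level", "route", "po_level", "iv_level"],
    )
    return CohortTables(static, observations, medications, event_log)


# ---------------------------------------------------------------------------
# Direct trajectory rollouts (used for Monte-Carlo evaluation and for
# generating behavior data from an arbitrary policy, e.g. in IRL recovery
# experiments).  These bypass the CSV round trip: states are the true
# simulator features, so rewards are exact.
# ---------------------------------------------------------------------------

def rollout_state_features(electrolyte: str) -> tuple[str, ...]:
    """Feature order of rollout states: the serum level first, then the
    previous interval's repletion levels, demographics, and two nuisance
    covariates whose irrelevance the learner should discover."""
    return (electrolyte, "prior_po_level", "prior_iv_level", "age", "admit_weight",
            "heart_rate", "creatinine")


def behavior_policy_fn(bcfg: BehaviorConfig, catalog: Sequence[RepletionAction]) -> Callable:
    """Adapt the behavior policy to the batched rollout interface
    ``fn(states (n, d), rng) -> (n,) catalog indices`` (the serum level is
    state feature 0).  Sampling is vectorized but matches
    :func:`behavior_action` draw for draw in distribution."""
    n_po = max(a.po_level for a in catalog)
    n_iv = max(a.iv_level for a in catalog)
    po_idx = np.array([catalog_index(catalog, "PO", po_level=l) for l in range(1, n_po + 1)])
    iv_idx = np.array([catalog_index(catalog, "IV", iv_level=l) for l in range(1, n_iv + 1)])
    both_idx = np.array(
        [[catalog_index(catalog, "BOTH", po_level=p, iv_level=i) for i in range(1, n_iv + 1)]
         for p in range(1, n_po + 1)]
    )
    po_probs = np.asarray(bcfg.dose_level_probs)
    iv_probs = (
        np.full(n_iv, 1.0 / n_iv)
        if bcfg.iv_dose_level_probs is None
        else np.asarray(bcfg.iv_dose_level_probs)
    )

    def fn(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        levels = np.atleast_2d(states)[:, 0]
        n = len(levels)
        below = levels < bcfg.replete_threshold
        replete = np.where(
            below,
            rng.random(n) >= bcfg.low_miss_prob,
            rng.random(n) < bcfg.over_replete_prob,
        )
        use_iv = rng.random(n) < bcfg.iv_prob_given_replete
        use_both = rng.random(n) < bcfg.both_prob_given_replete
        po_tier = np.minimum(rng.choice(len(po_probs), size=n, p=po_probs) + 1, n_po)
        iv_tier = np.minimum(rng.choice(len(iv_probs), size=n, p=iv_probs) + 1, n_iv)
        out = np.zeros(n, dtype=int)
        out[replete & ~use_both & ~use_iv] = po_idx[po_tier[replete & ~use_both & ~use_iv] - 1]
        out[replete & ~use_both & use_iv] = iv_idx[iv_tier[replete & ~use_both & use_iv] - 1]
        sel = replete & use_both
        out[sel] = both_idx[po_tier[sel] - 1, iv_tier[sel] - 1]
        return out

    return fn


@dataclass
class RolloutResult:
    """Trajectories rolled out in the simulator under a fixed policy."""

    samples: list[TransitionSample]
    returns: np.ndarray  # discounted return per visit (including terminal step)
    n_visits: int
    feature_names: tuple[str, ...]

    @property
    def mean_return(self) -> float:
        return float(self.returns.mean())


def rollout(
    cfg: SimConfig,
    spec: MDPSpec,
    policy_fn: Callable,
    n_visits: int,
    rng_seed: int,
    horizon_bins: int | None = None,
) -> RolloutResult:
    """Roll ``policy_fn`` out in the simulator and emit transition samples.

    Every visit runs for the full horizon; rewards price the *true* next
    level.  The terminal step prices the last bin's own level (no later
    measurement exists), matching the convention of
    :func:`replete.mdp.build_transitions`, so Monte-Carlo returns and
    fitted-Q estimates target the same quantity.
    """
    rng = np.random.default_rng(rng_seed)
    catalog = spec.catalog
    n_bins = horizon_bins if horizon_bins is not None else cfg.horizon_bins
    if n_bins < 2:
        raise ValueError("rollout needs a horizon of at least 2 bins")
    feats = rollout_state_features(cfg.electrolyte)
    hr_mu, hr_sd = NUISANCE_VARIABLES["heart_rate"]
    cr_mu, cr_sd = NUISANCE_VARIABLES["creatinine"]
    po_of = np.array([a.po_level for a in catalog], dtype=float)
    iv_of = np.array([a.iv_level for a in catalog], dtype=float)
    none_action = catalog[0]

    # time-major batch simulation: all visits advance one bin per step
    ages = rng.integers(19, 93, size=n_visits).astype(float)
    weights = np.clip(rng.normal(80.0, 15.0, size=n_visits), 40.0, 160.0)
    levels = rng.normal(cfg.setpoint, 0.3, size=n_visits)
    prior_po = np.zeros(n_visits)
    prior_iv = np.zeros(n_visits)
    all_states = np.zeros((n_bins, n_visits, len(feats)))
    all_actions = np.zeros((n_bins, n_visits), dtype=int)
    all_levels = np.zeros((n_bins + 1, n_visits))
    for t in range(n_bins):
        all_states[t] = np.column_stack(
            [levels, prior_po, prior_iv, ages, weights,
             rng.normal(hr_mu, hr_sd, size=n_visits),
             rng.normal(cr_mu, cr_sd, size=n_visits)]
        )
        all_levels[t] = levels
        a_idx = np.asarray(policy_fn(all_states[t], rng), dtype=int).reshape(n_visits)
        all_actions[t] = a_idx
        noise = rng.normal(0.0, cfg.noise_sd, size=n_visits)
        if cfg.shock_prob:
            hit = rng.random(n_visits) < cfg.shock_prob
            noise = noise + hit * rng.normal(cfg.shock_mean, cfg.shock_sd, size=n_visits)
        levels = (
            step_dynamics(levels, none_action, cfg, noise)
            + cfg.po_effect_per_unit * po_of[a_idx]
            + cfg.iv_effect_per_unit * iv_of[a_idx]
        )
        prior_po, prior_iv = po_of[a_idx], iv_of[a_idx]
    all_levels[n_bins] = levels

    samples: list[TransitionSample] = []
    returns = np.zeros(n_visits)
    for v in range(n_visits):
        g = 0.0
        for t in range(n_bins):
            action = catalog[all_actions[t, v]]
            terminal = t == n_bins - 1
            next_level = all_levels[t + 1, v] if not terminal else all_levels[t, v]
            r, phi = reward(spec.reward_weights, action, float(next_level),
                            spec.reference_range, spec.graded_penalty)
            g += (spec.gamma ** t) * r
            samples.append(
                TransitionSample(
                    visit_id=f"R{v:05d}",
                    bin_index=t,
                    state=all_states[t, v],
                    action_index=int(all_actions[t, v]),
                    reward=r,
                    reward_features=phi,
                    next_state=None if terminal else all_states[t + 1, v],
                    next_action_index=None if terminal else int(all_actions[t + 1, v]),
                )
            )
        returns[v] = g
    return RolloutResult(samples=samples, returns=returns, n_visits=n_visits, feature_names=feats)


def rollout_mdp_spec(cfg: SimConfig, weights: RewardWeights, gamma: float = 0.9) -> MDPSpec:
    """MDPSpec whose state features match :func:`rollout` outputs."""
    return MDPSpec(
        electrolyte=cfg.electrolyte,
        state_features=rollout_state_features(cfg.electrolyte),
        reward_weights=weights,
        gamma=gamma,
        reference_range=cfg.reference_range,
    )
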