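"""End-to-end seeded pipeline: simulate -> load -> select -> bin -> impute ->
split -> transitions -> FQI -> evaluation -> finance, with a run manifest.

Every artifact is reproducible from the config plus the single global seed;
per-stage seeds are derived from it so stages can be re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortFilterSpec,
    bin_visit,
    binned_cohort_to_frame,
    impute,
    load_ehr,
    population_means,
    select_cohort,
    split_cohort,
)
from .evaluation import (
    frequency_analysis,
    policy_value_report,
    pre_post_distribution,
    trajectory_overlay,
)
from .finance import cohort_cost_comparison, cost_model_from_yaml, default_cost_model
from .irl import irl_weights
from .mdp import (
    DEFAULT_REFERENCE_RANGES,
    MDPSpec,
    RewardWeights,
    build_transitions,
    catalog_to_frame,
    normalize_weights,
    transitions_to_frame,
)
from .policy import TransitionDataset, fqi, greedy_policy, save_policy
from .synthetic_ehr import (
    NUISANCE_VARIABLES,
    default_behavior_config,
    default_sim_config,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

#: Table 3-style default training weights per electrolyte (IV, PO, high, low).
DEFAULT_TRAINING_WEIGHTS = {
    "K": (0.07, 0.04, 0.15, 0.74),
    "Mg": (0.01, 0.01, 0.48, 0.48),
    "P": (0.08, 0.07, 0.5, 0.35),
}


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name and code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Single structured configuration for a full run."""

    output_dir: str = "runs/demo"
    seed: int = 0
    electrolyte: str = "K"
    log_level: str = "INFO"

    # data source: simulate, or read the three-table contract from paths
    simulate: bool = True
    n_visits: int = 200
    horizon_hours: float = 120.0
    over_replete_prob: float = 0.3
    static_path: str | None = None
    observations_path: str | None = None
    medications_path: str | None = None

    # cohort
    min_age: float = 18.0
    min_los: float = 24.0
    max_los: float = 192.0
    bin_width: float = 6.0
    train_fraction: float = 0.7
    train_count: int | None = None
    impute_means_on_train_only: bool = True

    # MDP / learning
    gamma: float = 0.9
    reward_weights: tuple[float, float, float, float] | None = None
    reference_range: tuple[float, float] | None = None
    fqi_iterations: int = 16
    fqe_iterations: int = 16
    regressor: dict | None = None

    # IRL
    run_irl: bool = False
    irl_max_outer_iters: int = 6
    irl_tol: float = 0.05
    irl_fqi_iterations: int = 5
    irl_fqe_iterations: int = 8

    # finance
    cost_model_path: str | None = None

    def validate(self) -> None:
        if self.min_los >= self.max_los:
            raise PipelineError("config", "invalid_los", "min_los must be < max_los")
        if not 0 <= self.gamma < 1:
            raise PipelineError("config", "invalid_gamma", "gamma must be in [0, 1)")
        if not self.simulate:
            for p in (self.static_path, self.observations_path, self.medications_path):
                if p is None or not Path(p).exists():
                    raise PipelineError("config", "missing_input", f"input table not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for key in ("reward_weights", "reference_range"):
            v = getattr(cfg, key)
            if v is not None:
                setattr(cfg, key, tuple(v))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _state_features(electrolyte: str) -> tuple[str, ...]:
    return (
        (electrolyte,)
        + tuple(NUISANCE_VARIABLES)
        + ("age", "admit_weight", "prior_po_level", "prior_iv_level")
    )


def _mdp_spec(config: PipelineConfig) -> MDPSpec:
    weights = config.reward_weights or DEFAULT_TRAINING_WEIGHTS[config.electrolyte]
    return MDPSpec(
        electrolyte=config.electrolyte,
        state_features=_state_features(config.electrolyte),
        reward_weights=normalize_weights(weights),
        gamma=config.gamma,
        reference_range=config.reference_range
        or DEFAULT_REFERENCE_RANGES[config.electrolyte],
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.time()
    counts: dict[str, Any] = {}
    spec = _mdp_spec(config)

    # --- simulate or locate inputs -----------------------------------------
    if config.simulate:
        sim_cfg = default_sim_config(
            config.electrolyte,
            n_visits=config.n_visits,
            horizon_hours=config.horizon_hours,
            rng_seed=config.seed,
        )
        bcfg = default_behavior_config(
            sim_cfg, over_replete_prob=config.over_replete_prob, rng_seed=config.seed + 1
        )
        tables = simulate_cohort(sim_cfg, bcfg)
        paths = tables.write(outdir / "data")
        counts["simulated_visits"] = config.n_visits
    else:
        paths = {
            "static": Path(config.static_path),
            "observations": Path(config.observations_path),
            "medications": Path(config.medications_path),
        }

    # --- load + select ------------------------------------------------------
    try:
        visits, drops = load_ehr(paths["static"], paths["observations"], paths["medications"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", "load_failed", str(e)) from e
    counts["loaded_visits"] = len(visits)
    counts["dropped_rows"] = drops

    filter_spec = CohortFilterSpec(
        min_age=config.min_age,
        min_los=config.min_los,
        max_los=config.max_los,
        required_variables=(config.electrolyte,),
        target_electrolyte=config.electrolyte,
    )
    kept, funnel = select_cohort(visits, filter_spec)
    counts["selected_visits"] = len(kept)
    counts["exclusion_funnel"] = funnel
    (outdir / "exclusion_funnel.json").write_text(json.dumps(
        {"input_visits": len(visits), "kept": len(kept), "excluded_by_filter": funnel}, indent=2))
    if len(kept) < 4:
        raise PipelineError("select", "cohort_too_small", f"only {len(kept)} visits survived")

    # --- split, bin, impute -------------------------------------------------
    train_ids, test_ids = split_cohort(
        kept, train_fraction=config.train_fraction, rng_seed=config.seed + 11,
        train_count=config.train_count,
    )
    counts["train_visits"], counts["test_visits"] = len(train_ids), len(test_ids)
    binned = {v.visit_id: bin_visit(v, bin_width=config.bin_width) for v in kept}
    train_set, test_set = set(train_ids), set(test_ids)
    means = (
        population_means([b for k, b in binned.items() if k in train_set])
        if config.impute_means_on_train_only
        else population_means(list(binned.values()))
    )
    try:
        imputed = {b.visit_id: b for b in impute(list(binned.values()), means=means)}
    except ValueError as e:
        raise PipelineError("impute", "unobserved_variable", str(e)) from e
    binned_cohort_to_frame(list(imputed.values())).to_csv(outdir / "binned_cohort.csv", index=False)

    # --- transitions ---------------------------------------------------------
    train_samples = build_transitions([imputed[i] for i in train_ids], spec)
    test_samples = build_transitions([imputed[i] for i in test_ids], spec)
    counts["train_samples"] = len(train_samples)
    counts["test_samples"] = len(test_samples)
    if not train_samples or not test_samples:
        raise PipelineError("transitions", "no_samples", "a split produced zero transition samples")
    transitions_to_frame(train_samples, spec.state_features).to_csv(
        outdir / "transitions_train.csv", index=False)
    transitions_to_frame(test_samples, spec.state_features).to_csv(
        outdir / "transitions_test.csv", index=False)
    catalog_to_frame(spec.catalog).to_json(outdir / "action_catalog.json", orient="records", indent=2)

    # --- FQI -----------------------------------------------------------------
    q = fqi(train_samples, spec, n_iterations=config.fqi_iterations,
            regressor_spec=config.regressor, rng_seed=config.seed + 23)
    policy = greedy_policy(q)
    save_policy(q, outdir / "policy")

    # --- evaluation ----------------------------------------------------------
    test_data = TransitionDataset(test_samples, len(spec.catalog))
    value_report = policy_value_report(
        policy, test_data, spec, n_iterations=config.fqe_iterations,
        regressor_spec=config.regressor, rng_seed=config.seed + 31,
    )
    (outdir / "fqe_report.json").write_text(json.dumps(value_report.to_dict(), indent=2))
    freq = frequency_analysis(test_data, policy, spec.catalog)
    (outdir / "frequency_report.json").write_text(json.dumps(freq.to_dict(), indent=2))
    prepost = pre_post_distribution(
        [imputed[i] for i in test_ids], spec.electrolyte, spec.reference_range)
    (outdir / "pre_post_report.json").write_text(json.dumps(prepost.to_dict(), indent=2))
    overlay_visit = next(
        (imputed[i] for i in test_ids if len(imputed[i].medications)), imputed[test_ids[0]])
    trajectory_overlay(overlay_visit, policy, spec).to_csv(
        outdir / "trajectory_overlay.csv", index=False)
    counts["policy_repletions_test"] = freq.policy_repletions
    counts["historical_repletions_test"] = freq.historical_repletions

    # --- IRL (optional) ------------------------------------------------------
    if config.run_irl:
        weights_hat, diag = irl_weights(
            train_samples, spec,
            fqi_iterations=config.irl_fqi_iterations,
            fqe_iterations=config.irl_fqe_iterations,
            regressor_spec=config.regressor,
            max_outer_iters=config.irl_max_outer_iters,
            tol=config.irl_tol,
            rng_seed=config.seed + 41,
        )
        (outdir / "irl_report.json").write_text(json.dumps({
            "electrolyte": config.electrolyte,
            "historical_weights_hat": list(weights_hat.as_array()),
            "training_weights": list(spec.reward_weights.as_array()),
            "diagnostics": diag.to_dict(),
        }, indent=2))

    # --- finance -------------------------------------------------------------
    model = (cost_model_from_yaml(config.cost_model_path)
             if config.cost_model_path else default_cost_model())
    catalog = spec.catalog
    hist_actions = [catalog[i] for i in test_data.action_idx]
    pol_actions = [catalog[i] for i in policy.action_indices(test_data.states)]
    comparison = cohort_cost_comparison(hist_actions, pol_actions, model, len(test_ids))
    (outdir / "finance_report.json").write_text(json.dumps(comparison.to_dict(), indent=2))

    # --- manifest ------------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", outdir)
    return outdir
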