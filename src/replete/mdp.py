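"""Markov decision process layer for electrolyte repletion.

The repletion task is modelled as an MDP <S, A, P, R, gamma> on 6-hour
decision intervals.  States are numeric patient-feature vectors, actions come
from a discrete per-electrolyte catalog of oral (PO) doses and intravenous
(IV) dose/duration pairs, and the reward is a negated weighted sum of four
binary penalty indicators:

    phi(s, a, s') = ( 1[a has an IV component],
                      1[a has a PO component],
                      1[next electrolyte level above the reference range],
                      1[next electrolyte level below the reference range] )

    R(s, a, s') = -(w_iv*phi1 + w_po*phi2 + w_high*phi3 + w_low*phi4)

The transition law P is never modelled explicitly; it is represented by the
empirical one-step samples produced by :func:`build_transitions`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ELECTROLYTES = ("K", "Mg", "P")

#: Oral dose grid in mg, levels 1..3 per electrolyte.
PO_DOSES_MG: dict[str, tuple[float, ...]] = {
    "K": (20.0, 40.0, 60.0),
    "Mg": (400.0, 800.0, 1200.0),
    "P": (250.0, 500.0, 750.0),
}

#: IV (dose, infusion duration h) grid, levels 1..n per electrolyte.
IV_ENTRIES: dict[str, tuple[tuple[float, float], ...]] = {
    "K": ((20.0, 2.0), (40.0, 4.0), (60.0, 6.0), (20.0, 1.0), (40.0, 2.0), (60.0, 3.0)),
    "Mg": ((0.5, 1.0), (1.0, 1.0), (1.0, 2.0), (1.0, 3.0)),
    "P": ((15.0, 1.0), (30.0, 3.0), (45.0, 6.0)),
}

#: Unit of the IV dose column per electrolyte (K and P dose in mEq, Mg in g).
IV_DOSE_UNIT = {"K": "mEq", "Mg": "g", "P": "mEq"}

#: Default serum reference ranges (K in mEq/L, Mg and P in mg/dL).
DEFAULT_REFERENCE_RANGES = {"K": (3.5, 5.0), "Mg": (1.7, 2.3), "P": (2.5, 4.5)}

#: State-feature columns holding the previous interval's repletion levels.
PRIOR_ACTION_FEATURES = ("prior_po_level", "prior_iv_level")


@dataclass(frozen=True)
class RepletionAction:
    """One element of the discrete per-electrolyte action catalog.

    ``route`` is NONE/PO/IV/BOTH; ``po_level`` and ``iv_level`` index the dose
    grids above (0 = no component on that route).
    """

    electrolyte: str
    route: str
    po_level: int = 0
    iv_level: int = 0

    def __post_init__(self) -> None:
        if self.route == "NONE" and (self.po_level or self.iv_level):
            raise ValueError("NONE action must have zero dose levels")
        if self.route == "PO" and (self.po_level == 0 or self.iv_level != 0):
            raise ValueError("PO action needs po_level>0 and iv_level=0")
        if self.route == "IV" and (self.iv_level == 0 or self.po_level != 0):
            raise ValueError("IV action needs iv_level>0 and po_level=0")
        if self.route == "BOTH" and (self.po_level == 0 or self.iv_level == 0):
            raise ValueError("BOTH action needs both levels > 0")

    @property
    def is_repletion(self) -> bool:
        return self.route != "NONE"

    @property
    def has_po(self) -> bool:
        return self.po_level > 0

    @property
    def has_iv(self) -> bool:
        return self.iv_level > 0

    @property
    def po_dose_mg(self) -> float | None:
        if not self.has_po:
            return None
        return PO_DOSES_MG[self.electrolyte][self.po_level - 1]

    @property
    def iv_dose(self) -> float | None:
        if not self.has_iv:
            return None
        return IV_ENTRIES[self.electrolyte][self.iv_level - 1][0]

    @property
    def iv_duration_h(self) -> float | None:
        if not self.has_iv:
            return None
        return IV_ENTRIES[self.electrolyte][self.iv_level - 1][1]

    @property
    def iv_dose_unit(self) -> str | None:
        return IV_DOSE_UNIT[self.electrolyte] if self.has_iv else None

    def label(self) -> str:
        if self.route == "NONE":
            return "NONE"
        parts = []
        if self.has_po:
            parts.append(f"PO{self.po_level}")
        if self.has_iv:
            parts.append(f"IV{self.iv_level}")
        return "+".join(parts)


def action_catalog(electrolyte: str) -> list[RepletionAction]:
    """Ordered action catalog for one electrolyte.

    Order (fixed contract): NONE, then PO1..PO3, then IV1..IVn, then all
    PO x IV combinations in PO-major order.  Sizes: K 28, Mg 20, P 16.
    """
    if electrolyte not in ELECTROLYTES:
        raise ValueError(f"unknown electrolyte {electrolyte!r}; expected one of {ELECTROLYTES}")
    n_po = len(PO_DOSES_MG[electrolyte])
    n_iv = len(IV_ENTRIES[electrolyte])
    catalog = [RepletionAction(electrolyte, "NONE")]
    catalog += [RepletionAction(electrolyte, "PO", po_level=p) for p in range(1, n_po + 1)]
    catalog += [RepletionAction(electrolyte, "IV", iv_level=i) for i in range(1, n_iv + 1)]
    catalog += [
        RepletionAction(electrolyte, "BOTH", po_level=p, iv_level=i)
        for p in range(1, n_po + 1)
        for i in range(1, n_iv + 1)
    ]
    return catalog


def catalog_index(catalog: Sequence[RepletionAction], route: str, po_level: int = 0, iv_level: int = 0) -> int:
    for i, a in enumerate(catalog):
        if a.route == route and a.po_level == po_level and a.iv_level == iv_level:
            return i
    raise KeyError(f"no catalog action ({route}, po={po_level}, iv={iv_level})")


def catalog_to_frame(catalog: Sequence[RepletionAction]) -> pd.DataFrame:
    """Audit table of the catalog (serialized with the policy artifact)."""
    rows = []
    for i, a in enumerate(catalog):
        rows.append(
            {
                "index": i,
                "label": a.label(),
                "route": a.route,
                "po_level": a.po_level,
                "po_dose_mg": a.po_dose_mg,
                "iv_level": a.iv_level,
                "iv_dose": a.iv_dose,
                "iv_dose_unit": a.iv_dose_unit,
                "iv_duration_h": a.iv_duration_h,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RewardWeights:
    """Relative weights of the four repletion penalties (IV cost, PO cost,
    above-range, below-range); normalized vectors have unit L1 norm."""

    w_iv: float
    w_po: float
    w_high: float
    w_low: float

    def as_array(self) -> np.ndarray:
        return np.array([self.w_iv, self.w_po, self.w_high, self.w_low], dtype=float)

    @property
    def l1_norm(self) -> float:
        return float(np.abs(self.as_array()).sum())


def normalize_weights(raw: Sequence[float] | RewardWeights) -> RewardWeights:
    """Scale a 4-vector to unit L1 norm, preserving signs."""
    arr = raw.as_array() if isinstance(raw, RewardWeights) else np.asarray(raw, dtype=float)
    if arr.shape != (4,):
        raise ValueError("reward weights must be a 4-vector")
    norm = float(np.abs(arr).sum())
    if norm == 0.0:
        raise ValueError("cannot normalize an all-zero weight vector")
    w = arr / norm
    return RewardWeights(*w)


@dataclass
class MDPSpec:
    """Static description of one electrolyte's repletion MDP."""

    electrolyte: str
    state_features: tuple[str, ...]
    reward_weights: RewardWeights
    gamma: float = 0.9
    reference_range: tuple[float, float] | None = None
    graded_penalty: bool = False  # if True, range penalties scale with distance from range
    catalog_override: list | None = None  # replace the Table-2 catalog (validation MDPs)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        feats = tuple(self.state_features)
        if not feats or len(set(feats)) != len(feats):
            raise ValueError("state_features must be non-empty and duplicate-free")
        self.state_features = feats
        if self.reference_range is None:
            self.reference_range = DEFAULT_REFERENCE_RANGES[self.electrolyte]
        lo, hi = self.reference_range
        if not lo < hi:
            raise ValueError("reference_range must satisfy low < high")

    @property
    def catalog(self) -> list[RepletionAction]:
        if self.catalog_override is not None:
            return self.catalog_override
        return action_catalog(self.electrolyte)


def reward_features(
    action: RepletionAction,
    next_level: float,
    reference_range: tuple[float, float],
    graded: bool = False,
) -> np.ndarray:
    """Penalty feature vector phi(s, a, s') = (IV, PO, above, below).

    Binary indicators by default; the graded variant scales the range
    indicators by the distance from the violated bound.
    """
    if not math.isfinite(next_level):
        raise ValueError("next electrolyte level must be finite")
    lo, hi = reference_range
    above = float(next_level > hi)
    below = float(next_level < lo)
    if graded:
        above *= next_level - hi
        below *= lo - next_level
    return np.array([float(action.has_iv), float(action.has_po), above, below])


def reward(
    weights: RewardWeights,
    action: RepletionAction,
    next_level: float,
    reference_range: tuple[float, float],
    graded: bool = False,
) -> tuple[float, np.ndarray]:
    """Reward and its penalty features for one transition."""
    phi = reward_features(action, next_level, reference_range, graded=graded)
    return float(-(weights.as_array() @ phi)), phi


def action_cost_offsets(
    catalog: Sequence, weights: RewardWeights, n_targets: int = 1
) -> np.ndarray:
    """Per-action deterministic target components, shape (|A|, n_targets).

    The route-cost part of the reward (and of the IV/PO penalty features) is
    an exact function of the action alone; fitted-Q loops subtract it from
    regression targets and add it back at prediction, so the approximator
    only has to learn the genuinely stochastic range-penalty dynamics.  For
    n_targets == 1 the column is the reward's action cost; for n_targets == 4
    the columns are the phi components (IV, PO indicators; ranges zero).
    """
    out = np.zeros((len(catalog), n_targets))
    for i, a in enumerate(catalog):
        if not isinstance(a, RepletionAction):
            continue  # validation catalogs (plain indices) have no structure
        if n_targets == 1:
            out[i, 0] = -(weights.w_iv * a.has_iv + weights.w_po * a.has_po)
        else:
            out[i, 0] = float(a.has_iv)
            out[i, 1] = float(a.has_po)
    return out


def encode_historical_action(
    medications: pd.DataFrame, electrolyte: str, catalog: Sequence[RepletionAction] | None = None
) -> RepletionAction:
    """Snap free-form medication rows from one 6-h bin onto the catalog grid.

    Same-route rows are summed (doses, and durations for IV) before snapping.
    PO doses snap to the nearest grid dose; IV rows snap by dose distance
    first, then duration distance; all ties break toward the lower catalog
    level.  Rows whose drug does not match the electrolyte's repletion drugs
    are ignored (with a debug log).
    """
    catalog = list(catalog) if catalog is not None else action_catalog(electrolyte)
    if medications is None or len(medications) == 0:
        return catalog[0]
    po_drug, iv_drug = f"{electrolyte}-PO", f"{electrolyte}-IV"
    known = medications["drug"].isin([po_drug, iv_drug])
    ignored = int((~known).sum())
    if ignored:
        logger.debug("ignored %d medication rows not matching %s repletion", ignored, electrolyte)
    meds = medications[known]
    po_rows = meds[meds["drug"] == po_drug]
    iv_rows = meds[meds["drug"] == iv_drug]

    po_level = 0
    if len(po_rows):
        total = float(po_rows["dose"].sum())
        doses = PO_DOSES_MG[electrolyte]
        dists = [abs(total - d) for d in doses]
        po_level = 1 + min(range(len(doses)), key=lambda i: (dists[i], i))

    iv_level = 0
    if len(iv_rows):
        total_dose = float(iv_rows["dose"].sum())
        total_dur = float((iv_rows["end_hours"] - iv_rows["start_hours"]).sum())
        entries = IV_ENTRIES[electrolyte]
        keys = [(abs(total_dose - d), abs(total_dur - t), i) for i, (d, t) in enumerate(entries)]
        iv_level = 1 + min(keys)[2]

    if po_level and iv_level:
        route = "BOTH"
    elif po_level:
        route = "PO"
    elif iv_level:
        route = "IV"
    else:
        return catalog[0]
    return RepletionAction(electrolyte, route, po_level=po_level, iv_level=iv_level)


@dataclass
class TransitionSample:
    """One <state, action, reward, next state> record.

    Terminal samples (last bin of a visit) carry ``next_state=None``; their
    range-penalty indicators are computed from the same bin's level because no
    later measurement exists.  ``next_action_index`` is the logged action at
    the next decision point (needed to evaluate the historical policy).
    """

    visit_id: object
    bin_index: int
    state: np.ndarray
    action_index: int
    reward: float
    reward_features: np.ndarray
    next_state: np.ndarray | None
    next_action_index: int | None = None

    @property
    def terminal(self) -> bool:
        return self.next_state is None


def recompute_rewards(samples: Iterable[TransitionSample], weights: RewardWeights) -> None:
    """Re-price stored transitions under new weights (phi is weight-free)."""
    w = weights.as_array()
    for s in samples:
        s.reward = float(-(w @ s.reward_features))


def build_transitions(binned_visits: Iterable, spec: MDPSpec) -> list[TransitionSample]:
    """One-step transition samples from fully imputed binned visits.

    The action of bin t is the historical medication record of bin t snapped
    to the catalog; the reward prices the level observed in bin t+1.  The
    state at bin t appends the previous bin's repletion levels when the
    feature list asks for them.  A visit with B >= 2 bins yields B-1
    non-terminal samples plus one terminal sample; visits with < 2 bins are
    skipped (logged).
    """
    catalog = spec.catalog
    lo_hi = spec.reference_range
    samples: list[TransitionSample] = []
    skipped = 0
    for visit in binned_visits:
        n = visit.n_bins
        if n < 2:
            skipped += 1
            continue
        states, actions, a_idx, levels = visit_state_actions(visit, spec, catalog)
        visit_samples: list[TransitionSample] = []
        for t in range(n - 1):
            r, phi = reward(spec.reward_weights, actions[t], levels[t + 1], lo_hi, spec.graded_penalty)
            visit_samples.append(
                TransitionSample(
                    visit_id=visit.visit_id,
                    bin_index=t,
                    state=states[t],
                    action_index=a_idx[t],
                    reward=r,
                    reward_features=phi,
                    next_state=states[t + 1],
                    next_action_index=a_idx[t + 1],
                )
            )
        r, phi = reward(spec.reward_weights, actions[n - 1], levels[n - 1], lo_hi, spec.graded_penalty)
        visit_samples.append(
            TransitionSample(
                visit_id=visit.visit_id,
                bin_index=n - 1,
                state=states[n - 1],
                action_index=a_idx[n - 1],
                reward=r,
                reward_features=phi,
                next_state=None,
            )
        )
        samples.extend(visit_samples)
    if skipped:
        logger.info("build_transitions: skipped %d visits with < 2 bins", skipped)
    return samples


def visit_state_actions(
    visit, spec: MDPSpec, catalog: Sequence[RepletionAction] | None = None
) -> tuple[np.ndarray, list[RepletionAction], list[int], np.ndarray]:
    """Per-bin state matrix, encoded historical actions (objects and catalog
    indices), and the electrolyte level series for one imputed binned visit.
    The state at bin t carries bin t-1's repletion levels when the feature
    list includes the prior-action indicators."""
    catalog = list(catalog) if catalog is not None else spec.catalog
    n = visit.n_bins
    feats = visit.features
    base_feats = [f for f in spec.state_features if f not in PRIOR_ACTION_FEATURES]
    use_prior = any(f in spec.state_features for f in PRIOR_ACTION_FEATURES)
    missing = [f for f in base_feats if f not in feats.columns]
    if missing:
        raise KeyError(f"visit {visit.visit_id} lacks state features {missing}")
    actions = [
        encode_historical_action(visit.medications_in_bin(b), spec.electrolyte, catalog)
        for b in range(n)
    ]
    a_idx = [catalog_index(catalog, a.route, a.po_level, a.iv_level) for a in actions]
    base = feats[base_feats].to_numpy(dtype=float)
    if not np.isfinite(base).all():
        raise ValueError(f"visit {visit.visit_id} has non-finite state features; impute first")
    if use_prior:
        prior = np.zeros((n, 2))
        for t in range(1, n):
            prior[t] = (actions[t - 1].po_level, actions[t - 1].iv_level)
        states = _ordered_state_matrix(spec.state_features, base_feats, base, prior)
    else:
        states = base
    levels = feats[spec.electrolyte].to_numpy(dtype=float)
    return states, actions, a_idx, levels


def _ordered_state_matrix(
    feature_order: Sequence[str], base_feats: Sequence[str], base: np.ndarray, prior: np.ndarray
) -> np.ndarray:
    """Assemble state columns in the exact order of ``feature_order``."""
    cols = {}
    for j, f in enumerate(base_feats):
        cols[f] = base[:, j]
    cols["prior_po_level"], cols["prior_iv_level"] = prior[:, 0], prior[:, 1]
    return np.column_stack([cols[f] for f in feature_order])


def transitions_to_frame(samples: Sequence[TransitionSample], feature_names: Sequence[str]) -> pd.DataFrame:
    """Columnar serialization: one row per sample with phi and both states."""
    rows = []
    for s in samples:
        row = {
            "visit_id": s.visit_id,
            "bin_index": s.bin_index,
            "action_index": s.action_index,
            "reward": s.reward,
            "terminal": s.terminal,
            "next_action_index": -1 if s.next_action_index is None else s.next_action_index,
        }
        for k, v in zip(("phi_iv", "phi_po", "phi_high", "phi_low"), s.reward_features):
            row[k] = v
        for name, v in zip(feature_names, s.state):
            row[f"s.{name}"] = v
        for name in feature_names:
            row[f"s1.{name}"] = np.nan
        if s.next_state is not None:
            for name, v in zip(feature_names, s.next_state):
                row[f"s1.{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def default_state_features() -> tuple[str, ...]:
    """The full 52-covariate clinical state (demographics, vitals, labs,
    prior-interval drug exposures, procedures).  Real deployments configure a
    subset matching their extract; the synthetic generator emits a reduced
    set."""
    static = ("age", "sex", "admit_weight", "icu_flag")
    vitals = ("heart_rate", "resp_rate", "temp", "spo2", "urine_output", "bp_sys", "bp_dia")
    labs = ("K", "Mg", "P", "sodium", "chloride", "anion_gap", "creatinine",
            "hemoglobin", "glucose", "bun", "wbc")
    lab_ind = ("ca_ionized", "cpk", "ldh", "alt", "ast", "pth")
    drugs = ("K_iv", "K_po", "Mg_iv", "Mg_po", "P_iv", "P_po", "Ca_iv", "Ca_po",
             "loop_diuretic", "thiazide", "acetazolamide", "spironolactone", "fluids",
             "vasopressor", "beta_blocker", "ca_blocker", "dextrose", "insulin",
             "kayexalate", "tpn", "pn", "po_nutrition")
    procedures = ("transfusion", "dialysis")
    return static + vitals + labs + lab_ind + drugs + procedures
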