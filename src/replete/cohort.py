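"""Cohort ingestion, selection, 6-hour binning, and imputation.

Raw long-format EHR tables are turned into complete per-visit feature
matrices in four steps:

1. ``load_ehr`` — parse the static / observations / medications tables into
   :class:`PatientVisit` objects (malformed rows dropped and counted).
2. ``select_cohort`` — apply the exclusion funnel: adults (age > 18), length
   of stay between one and eight days, at least one recorded value of every
   required variable, admission weight on file, and at least one repletion
   event of the target electrolyte.
3. ``bin_visit`` — divide the stay into half-open 6-h bins; discard
   clinically nonviable outliers; average the surviving measurements per bin.
4. ``impute`` — last observation carried forward while the source
   measurement is at most 48 h old, population mean otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_ehr import MEDICATION_COLUMNS, OBSERVATION_COLUMNS, STATIC_COLUMNS

logger = logging.getLogger(__name__)

#: Conservative clinically viable bounds per variable (outlier filter).
DEFAULT_PLAUSIBILITY_RANGES: dict[str, tuple[float, float]] = {
    "K": (1.0, 10.0),
    "Mg": (0.3, 10.0),
    "P": (0.3, 20.0),
    "heart_rate": (20.0, 250.0),
    "resp_rate": (4.0, 70.0),
    "temp": (30.0, 43.0),
    "spo2": (50.0, 100.0),
    "bp_sys": (40.0, 280.0),
    "bp_dia": (20.0, 180.0),
    "creatinine": (0.1, 20.0),
    "glucose": (20.0, 1200.0),
    "hemoglobin": (2.0, 25.0),
}


@dataclass
class PatientVisit:
    """One admission: static attributes plus raw timestamped event streams."""

    visit_id: str
    age: float
    sex: str | None
    admit_weight: float
    observations: pd.DataFrame  # time_hours, variable, value
    medications: pd.DataFrame  # start_hours, end_hours, drug, dose, route

    @property
    def length_of_stay(self) -> float:
        """Hours from admission to the latest recorded event (ceil'd to the
        hour).  The synthetic generator guarantees a vital in the final bin,
        so this equals the true stay length on generated data."""
        times = [0.0]
        if len(self.observations):
            times.append(float(self.observations["time_hours"].max()))
        if len(self.medications):
            times.append(float(self.medications["end_hours"].max()))
        return float(math.ceil(max(times)))


@dataclass
class CohortFilterSpec:
    """Exclusion-funnel definition; filters apply in declaration order and a
    dropped visit is attributed to the first filter it fails."""

    min_age: float = 18.0  # kept iff age > min_age (strict)
    min_los: float = 24.0
    max_los: float = 192.0
    required_variables: tuple[str, ...] = ()
    require_admission_weight: bool = True
    target_electrolyte: str = "K"
    require_repletion_event: bool = True

    def __post_init__(self) -> None:
        if not self.min_los < self.max_los:
            raise ValueError("min_los must be < max_los")


def load_ehr(
    static_path: str | Path,
    observations_path: str | Path,
    medications_path: str | Path,
) -> tuple[list[PatientVisit], dict[str, int]]:
    """Read the three-table contract into PatientVisit objects.

    Rows with unparseable numeric fields are dropped and counted per table.
    Missing required columns raise immediately, naming the column.
    """
    static = pd.read_csv(static_path)
    observations = pd.read_csv(observations_path)
    medications = pd.read_csv(medications_path)
    return visits_from_frames(static, observations, medications)


def visits_from_frames(
    static: pd.DataFrame, observations: pd.DataFrame, medications: pd.DataFrame
) -> tuple[list[PatientVisit], dict[str, int]]:
    """In-memory variant of :func:`load_ehr` (same contract)."""
    for name, df, cols in (
        ("static", static, STATIC_COLUMNS),
        ("observations", observations, OBSERVATION_COLUMNS),
        ("medications", medications, MEDICATION_COLUMNS),
    ):
        for col in cols:
            if col not in df.columns:
                raise ValueError(f"{name} table is missing required column {col!r}")

    drops: dict[str, int] = {}

    obs = observations.copy()
    obs["time_hours"] = pd.to_numeric(obs["time_hours"], errors="coerce")
    obs["value"] = pd.to_numeric(obs["value"], errors="coerce")
    ok = obs["time_hours"].notna() & obs["value"].notna() & obs["variable"].notna()
    drops["observations"] = int((~ok).sum())
    obs = obs[ok]

    med = medications.copy()
    for c in ("start_hours", "end_hours", "dose"):
        med[c] = pd.to_numeric(med[c], errors="coerce")
    ok = med["start_hours"].notna() & med["end_hours"].notna() & med["dose"].notna() & med["drug"].notna()
    drops["medications"] = int((~ok).sum())
    med = med[ok]

    st = static.copy()
    st["age"] = pd.to_numeric(st["age"], errors="coerce")
    st["admit_weight"] = pd.to_numeric(st["admit_weight"], errors="coerce")
    ok = st["visit_id"].notna() & ~st["visit_id"].duplicated()
    drops["static"] = int((~ok).sum())
    st = st[ok]

    total_dropped = sum(drops.values())
    if total_dropped:
        logger.info("load_ehr: dropped %d malformed rows (%s)", total_dropped, drops)

    obs_by = {k: g[["time_hours", "variable", "value"]].reset_index(drop=True)
              for k, g in obs.groupby("visit_id", sort=False)}
    med_by = {k: g[["start_hours", "end_hours", "drug", "dose", "route"]].reset_index(drop=True)
              for k, g in med.groupby("visit_id", sort=False)}
    empty_obs = obs.iloc[0:0][["time_hours", "variable", "value"]]
    empty_med = med.iloc[0:0][["start_hours", "end_hours", "drug", "dose", "route"]]

    visits = []
    for row in st.itertuples(index=False):
        visits.append(
            PatientVisit(
                visit_id=str(row.visit_id),
                age=float(row.age) if pd.notna(row.age) else float("nan"),
                sex=getattr(row, "sex", None),
                admit_weight=float(row.admit_weight) if pd.notna(row.admit_weight) else float("nan"),
                observations=obs_by.get(str(row.visit_id), empty_obs),
                medications=med_by.get(str(row.visit_id), empty_med),
            )
        )
    return visits, drops


def select_cohort(
    visits: Iterable[PatientVisit], spec: CohortFilterSpec
) -> tuple[list[PatientVisit], dict[str, int]]:
    """Apply the exclusion funnel; returns kept visits and per-filter counts
    (first-failed-filter attribution, in declaration order)."""
    funnel = {
        "age": 0,
        "min_los": 0,
        "max_los": 0,
        "required_variables": 0,
        "admission_weight": 0,
        "repletion_event": 0,
    }
    kept = []
    drug_prefix = f"{spec.target_electrolyte}-"
    for v in visits:
        if not (v.age > spec.min_age):  # NaN ages fail here too
            funnel["age"] += 1
            continue
        los = v.length_of_stay
        if los < spec.min_los:
            funnel["min_los"] += 1
            continue
        if los > spec.max_los:
            funnel["max_los"] += 1
            continue
        if spec.required_variables:
            observed = set(v.observations["variable"].unique())
            if any(r not in observed for r in spec.required_variables):
                funnel["required_variables"] += 1
                continue
        if spec.require_admission_weight and not np.isfinite(v.admit_weight):
            funnel["admission_weight"] += 1
            continue
        if spec.require_repletion_event:
            if not len(v.medications) or not v.medications["drug"].str.startswith(drug_prefix).any():
                funnel["repletion_event"] += 1
                continue
        kept.append(v)
    return kept, funnel


@dataclass
class BinnedVisit:
    """Per-visit 6-h feature matrix plus the observed-cell mask.

    ``features`` rows are bin indices 0..n_bins-1; before imputation cells
    with no surviving measurement are NaN, afterwards the matrix is complete.
    ``mask`` is True where a real measurement informed the cell.
    """

    visit_id: str
    bin_width: float
    n_bins: int
    features: pd.DataFrame
    mask: pd.DataFrame
    medications: pd.DataFrame  # original med rows plus a bin_index column
    length_of_stay: float
    n_survivor_measurements: int = 0

    def medications_in_bin(self, bin_index: int) -> pd.DataFrame:
        return self.medications[self.medications["bin_index"] == bin_index]


def bin_visit(
    visit: PatientVisit,
    bin_width: float = 6.0,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    static_features: bool = True,
) -> BinnedVisit:
    """Aggregate one visit into half-open [k*w, (k+1)*w) bins.

    Within each bin, values outside the variable's plausibility range are
    discarded and the arithmetic mean of survivors fills the cell; a bin with
    no survivor stays NaN.  Medication rows are assigned to the bin holding
    their start time.  Events at exactly the stay's end are clipped into the
    last bin.  When ``static_features`` is set, age and admission weight are
    replicated as constant (always-observed) columns.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ranges = DEFAULT_PLAUSIBILITY_RANGES if ranges is None else ranges
    los = visit.length_of_stay
    n_bins = max(int(math.ceil(los / bin_width)), 1)

    obs = visit.observations.copy()
    if len(obs):
        lo = obs["variable"].map(lambda v: ranges.get(v, (-np.inf, np.inf))[0])
        hi = obs["variable"].map(lambda v: ranges.get(v, (-np.inf, np.inf))[1])
        viable = (obs["value"] >= lo) & (obs["value"] <= hi)
        obs = obs[viable]
        obs["bin_index"] = np.minimum((obs["time_hours"] // bin_width).astype(int), n_bins - 1)
        cell = obs.groupby(["bin_index", "variable"])["value"].mean().unstack()
        n_survivors = int(len(obs))
    else:
        cell = pd.DataFrame()
        n_survivors = 0
    features = cell.reindex(index=range(n_bins))
    features.index.name = "bin_index"
    mask = features.notna()

    if static_features:
        features["age"] = visit.age
        features["admit_weight"] = visit.admit_weight
        mask["age"] = True
        mask["admit_weight"] = np.isfinite(visit.admit_weight)

    med = visit.medications.copy()
    if len(med):
        med["bin_index"] = np.minimum((med["start_hours"] // bin_width).astype(int), n_bins - 1)
    else:
        med["bin_index"] = pd.Series([], dtype=int)
    return BinnedVisit(
        visit_id=visit.visit_id,
        bin_width=bin_width,
        n_bins=n_bins,
        features=features,
        mask=mask,
        medications=med,
        length_of_stay=los,
        n_survivor_measurements=n_survivors,
    )


def population_means(binned_visits: Sequence[BinnedVisit]) -> pd.Series:
    """Cohort-wide mean of observed bin cells per variable (the imputation
    fallback; typically computed on the training split only)."""
    frames = [v.features.where(v.mask) for v in binned_visits]
    stacked = pd.concat(frames, axis=0)
    return stacked.mean(axis=0)


def impute(
    binned_visits: Sequence[BinnedVisit],
    max_gap_hours: float = 48.0,
    means: pd.Series | None = None,
) -> list[BinnedVisit]:
    """Fill missing cells: carry the last observation forward while its age
    at the bin being filled is at most ``max_gap_hours``, otherwise use the
    population mean.  Observed cells are never altered; masks are preserved.
    """
    if not binned_visits:
        raise ValueError("impute needs at least one visit")
    if means is None:
        means = population_means(binned_visits)
    all_columns = sorted(
        set(means.index) | {c for v in binned_visits for c in v.features.columns}
    )
    out = []
    for v in binned_visits:
        limit = int(max_gap_hours // v.bin_width)
        # a visit may lack a variable entirely; give it the full column set
        feats = v.features.where(v.mask).reindex(columns=all_columns)
        vmask = v.mask.reindex(columns=all_columns, fill_value=False)
        never = [c for c in feats.columns if c not in means.index or pd.isna(means[c])]
        never = [c for c in never if feats[c].isna().any()]
        if never:
            raise ValueError(
                f"cannot impute variable(s) {never}: never observed in the cohort"
            )
        filled = (feats.ffill(limit=limit) if limit > 0 else feats).fillna(means)
        out.append(
            BinnedVisit(
                visit_id=v.visit_id,
                bin_width=v.bin_width,
                n_bins=v.n_bins,
                features=filled,
                mask=vmask,
                medications=v.medications,
                length_of_stay=v.length_of_stay,
                n_survivor_measurements=v.n_survivor_measurements,
            )
        )
    return out


def split_cohort(
    visits: Sequence[PatientVisit] | Sequence[str],
    train_fraction: float | None = 0.7,
    rng_seed: int = 0,
    train_count: int | None = None,
) -> tuple[list[str], list[str]]:
    """Visit-level random train/test partition (disjoint, exhaustive,
    deterministic under the seed).  Either a fraction or an explicit train
    count may be given; the count wins when both are set."""
    ids = [v if isinstance(v, str) else v.visit_id for v in visits]
    if len(set(ids)) != len(ids):
        raise ValueError("visit ids must be unique")
    if train_count is None:
        if train_fraction is None or not 0.0 < train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1) when train_count is not given")
        train_count = int(round(train_fraction * len(ids)))
    if not 0 <= train_count <= len(ids):
        raise ValueError("train_count out of range")
    order = np.random.default_rng(rng_seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    return sorted(shuffled[:train_count]), sorted(shuffled[train_count:])


def binned_cohort_to_frame(binned_visits: Sequence[BinnedVisit]) -> pd.DataFrame:
    """Long-format serialization: visit_id, bin_index, feature, value,
    observed_flag."""
    rows = []
    for v in binned_visits:
        long = v.features.stack(future_stack=True).rename("value").reset_index()
        long.columns = ["bin_index", "feature", "value"]
        obs = v.mask.stack(future_stack=True).rename("observed").reset_index()
        long["observed_flag"] = obs["observed"].to_numpy()
        long.insert(0, "visit_id", v.visit_id)
        rows.append(long)
    return pd.concat(rows, ignore_index=True)
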