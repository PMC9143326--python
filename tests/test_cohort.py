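"""Ingestion, exclusion funnel, binning, imputation, and splitting."""

import math

import numpy as np
import pandas as pd
import pytest

from replete.cohort import (
    CohortFilterSpec,
    bin_visit,
    binned_cohort_to_frame,
    impute,
    load_ehr,
    population_means,
    select_cohort,
    split_cohort,
    visits_from_frames,
)
from replete.synthetic_ehr import default_behavior_config, default_sim_config, simulate_cohort
from .conftest import make_visit


class TestLoadEhr:
    def test_roundtrip_from_generator(self, tmp_path):
        cfg = default_sim_config("K", n_visits=5, rng_seed=1)
        paths = simulate_cohort(cfg, default_behavior_config(cfg, rng_seed=1)).write(tmp_path)
        visits, drops = load_ehr(paths["static"], paths["observations"], paths["medications"])
        assert len(visits) == 5
        assert sum(drops.values()) == 0

    def test_non_numeric_value_row_dropped_and_counted(self, five_visit_frames):
        static, obs, med = five_visit_frames
        obs = pd.concat(
            [obs, pd.DataFrame([("A", 1.0, "K", "not-a-number")], columns=obs.columns)]
        )
        visits, drops = visits_from_frames(static, obs, med)
        assert drops["observations"] == 1
        assert len(visits) == 5

    def test_empty_medications_is_legal(self, five_visit_frames):
        static, obs, med = five_visit_frames
        visits, _ = visits_from_frames(static, obs, med.iloc[0:0])
        assert all(len(v.medications) == 0 for v in visits)

    def test_missing_column_named_in_error(self, five_visit_frames):
        static, obs, med = five_visit_frames
        with pytest.raises(ValueError, match="value"):
            visits_from_frames(static, obs.drop(columns=["value"]), med)


class TestSelectCohort:
    def test_hand_enumerated_funnel(self, five_visits):
        """Ages {17,30,40,50,60} x stays {100,10,300,100,100} h: only the
        age-50 and age-60 visits with 100-h stays survive."""
        kept, funnel = select_cohort(five_visits, CohortFilterSpec())
        assert sorted(v.visit_id for v in kept) == ["D", "E"]
        assert funnel == {
            "age": 1, "min_los": 1, "max_los": 1,
            "required_variables": 0, "admission_weight": 0, "repletion_event": 0,
        }

    def test_first_failed_filter_attribution(self, five_visits):
        # visit A fails both age and LOS bounds; it must be charged to age
        kept, funnel = select_cohort(
            [v for v in five_visits if v.visit_id == "A"], CohortFilterSpec()
        )
        assert funnel["age"] == 1 and funnel["min_los"] == 0

    def test_require_repletion_with_no_medications(self, five_visit_frames):
        static, obs, med = five_visit_frames
        visits, _ = visits_from_frames(static, obs, med.iloc[0:0])
        kept, funnel = select_cohort(visits, CohortFilterSpec())
        assert kept == [] and funnel["repletion_event"] == 2

    def test_all_permissive_spec_keeps_everything(self, five_visits):
        spec = CohortFilterSpec(
            min_age=0.0, min_los=0.0, max_los=math.inf,
            required_variables=(), require_admission_weight=False,
            require_repletion_event=False,
        )
        kept, _ = select_cohort(five_visits, spec)
        assert len(kept) == len(five_visits)

    def test_idempotent(self, five_visits):
        spec = CohortFilterSpec()
        kept1, _ = select_cohort(five_visits, spec)
        kept2, _ = select_cohort(kept1, spec)
        assert [v.visit_id for v in kept1] == [v.visit_id for v in kept2]

    def test_invalid_los_bounds_rejected(self):
        with pytest.raises(ValueError, match="min_los"):
            CohortFilterSpec(min_los=200.0, max_los=100.0)


class TestBinVisit:
    def test_bin_mean_of_two_measurements(self):
        v = make_visit(obs=[(2.0, "K", 3.8), (5.0, "K", 4.0), (11.5, "heart_rate", 80)])
        bv = bin_visit(v)
        assert bv.features.loc[0, "K"] == pytest.approx(3.9)

    def test_nonviable_outlier_discarded(self):
        v = make_visit(obs=[(2.0, "K", 3.8), (5.0, "K", 40.0), (11.5, "heart_rate", 80)])
        bv = bin_visit(v, ranges={"K": (1.0, 10.0)})
        assert bv.features.loc[0, "K"] == pytest.approx(3.8)

    def test_half_open_bins(self):
        v = make_visit(obs=[(6.0, "K", 4.2), (11.5, "heart_rate", 80)])
        bv = bin_visit(v)
        assert np.isnan(bv.features.loc[0, "K"])
        assert bv.features.loc[1, "K"] == pytest.approx(4.2)

    def test_bin_count_for_192h_stay(self):
        v = make_visit(obs=[(0.0, "K", 4.0), (191.5, "heart_rate", 80)])
        assert bin_visit(v).n_bins == 32

    def test_medications_assigned_by_start_time(self):
        v = make_visit(
            obs=[(0.0, "K", 4.0), (23.5, "heart_rate", 80)],
            meds=[(11.0, 13.0, "K-IV", 40.0, "IV")],
        )
        bv = bin_visit(v)
        assert bv.medications_in_bin(1).iloc[0]["drug"] == "K-IV"
        assert len(bv.medications_in_bin(2)) == 0

    def test_survivor_count_mass_preserved(self):
        v = make_visit(
            obs=[(1.0, "K", 3.8), (2.0, "K", 4.0), (8.0, "K", 99.0), (9.0, "K", 4.1),
                 (17.5, "heart_rate", 80)]
        )
        bv = bin_visit(v, ranges={"K": (1.0, 10.0)})
        assert bv.n_survivor_measurements == 4  # the 99.0 was discarded
        assert int(bv.mask["K"].sum()) == 2  # bins 0 and 1 observed


class TestImpute:
    def _visit_with_gap(self, n_bins=12):
        # K observed only in bin 0; heart rate everywhere (for LOS anchoring)
        obs = [(0.0, "K", 4.4)]
        obs += [(6.0 * t + 1.0, "heart_rate", 80.0) for t in range(n_bins)]
        obs.append((6.0 * n_bins - 0.5, "heart_rate", 80.0))
        return make_visit(obs=obs)

    def test_locf_carries_48h_then_population_mean(self):
        """Observed in bin 0, missing after: bins 1-8 (gaps 6-48 h) carry the
        bin-0 value; bin 9 (54 h) takes the population mean."""
        gap_visit = bin_visit(self._visit_with_gap())
        other = bin_visit(make_visit(visit_id="V2", obs=[(0.0, "K", 3.0), (5.5, "heart_rate", 80)]))
        imputed = impute([gap_visit, other])
        k = imputed[0].features["K"]
        assert np.allclose(k.iloc[1:9], 4.4)
        assert k.iloc[9] == pytest.approx((4.4 + 3.0) / 2)  # mean of observed cells

    def test_no_prior_observation_takes_population_mean(self):
        v1 = bin_visit(make_visit(obs=[(1.0, "heart_rate", 80), (11.5, "heart_rate", 82)]))
        v2 = bin_visit(make_visit(visit_id="V2", obs=[(0.0, "K", 3.6), (5.5, "heart_rate", 80)]))
        imputed = impute([v1, v2])
        assert np.allclose(imputed[0].features["K"], 3.6)

    def test_fully_observed_visit_unchanged(self):
        v = bin_visit(make_visit(obs=[(0.0, "K", 4.0), (6.0, "K", 4.2), (11.5, "heart_rate", 80)]))
        imputed = impute([v])[0]
        assert imputed.features.loc[0, "K"] == 4.0
        assert imputed.features.loc[1, "K"] == 4.2

    def test_observed_cells_never_altered_and_mask_preserved(self):
        cfg = default_sim_config("K", n_visits=6, rng_seed=2, measurement_prob=0.5)
        tables = simulate_cohort(cfg, default_behavior_config(cfg, rng_seed=2))
        visits, _ = visits_from_frames(tables.static, tables.observations, tables.medications)
        binned = [bin_visit(v) for v in visits]
        imputed = impute(binned)
        for pre, post in zip(binned, imputed):
            common = [c for c in pre.features.columns]
            for c in common:
                m = pre.mask[c].to_numpy()
                assert np.array_equal(m, post.mask[c].to_numpy()[: len(m)])
                assert np.allclose(
                    pre.features[c].to_numpy()[m], post.features[c].to_numpy()[: len(m)][m]
                )
            assert not post.features.isna().any().any()

    def test_never_observed_variable_raises_named_error(self):
        v = bin_visit(make_visit(obs=[(1.0, "K", 4.0), (5.5, "heart_rate", 80)]))
        v.features["mystery"] = np.nan
        v.mask["mystery"] = False
        with pytest.raises(ValueError, match="mystery"):
            impute([v])


class TestSplitCohort:
    def test_counts_disjoint_exhaustive(self):
        ids = [f"V{i}" for i in range(10)]
        train, test = split_cohort(ids, train_fraction=0.7, rng_seed=0)
        assert len(train) == 7 and len(test) == 3
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_deterministic_under_seed(self):
        ids = [f"V{i}" for i in range(25)]
        assert split_cohort(ids, 0.6, rng_seed=5) == split_cohort(ids, 0.6, rng_seed=5)
        assert split_cohort(ids, 0.6, rng_seed=5) != split_cohort(ids, 0.6, rng_seed=6)

    def test_explicit_train_count_wins(self):
        ids = [f"V{i}" for i in range(10)]
        train, test = split_cohort(ids, train_fraction=0.5, rng_seed=0, train_count=8)
        assert len(train) == 8 and len(test) == 2

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["a", "b"], train_fraction=1.5, rng_seed=0)


def test_binned_cohort_long_format_roundtrip():
    v = bin_visit(make_visit(obs=[(0.0, "K", 4.0), (6.0, "K", 4.2), (11.5, "heart_rate", 80)]))
    frame = binned_cohort_to_frame(impute([v]))
    assert set(frame.columns) == {"visit_id", "bin_index", "feature", "value", "observed_flag"}
    k0 = frame[(frame.feature == "K") & (frame.bin_index == 0)]
    assert k0.value.iloc[0] == 4.0 and bool(k0.observed_flag.iloc[0])
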