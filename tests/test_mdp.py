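"""Action catalog, reward arithmetic, weight normalization, transitions."""

import numpy as np
import pandas as pd
import pytest

from replete.mdp import (
    MDPSpec,
    RepletionAction,
    RewardWeights,
    action_catalog,
    action_cost_offsets,
    build_transitions,
    catalog_index,
    default_state_features,
    encode_historical_action,
    normalize_weights,
    reward,
)
from replete.cohort import bin_visit, impute
from .conftest import make_visit

K_AI = RewardWeights(0.07, 0.04, 0.15, 0.74)
K_RANGE = (3.5, 5.0)


class TestCatalog:
    @pytest.mark.parametrize(
        "electrolyte,size,n_po,n_iv",
        [("K", 28, 3, 6), ("Mg", 20, 3, 4), ("P", 16, 3, 3)],
    )
    def test_sizes_and_composition(self, electrolyte, size, n_po, n_iv):
        cat = action_catalog(electrolyte)
        assert len(cat) == size
        routes = [a.route for a in cat]
        assert routes.count("NONE") == 1 and cat[0].route == "NONE"
        assert routes.count("PO") == n_po
        assert routes.count("IV") == n_iv
        assert routes.count("BOTH") == n_po * n_iv

    def test_k_iv5_is_40meq_over_2h(self, k_catalog):
        a = k_catalog[catalog_index(k_catalog, "IV", iv_level=5)]
        assert (a.iv_dose, a.iv_duration_h, a.iv_dose_unit) == (40.0, 2.0, "mEq")

    def test_mg_iv_entries(self):
        cat = action_catalog("Mg")
        iv = [(a.iv_dose, a.iv_duration_h) for a in cat if a.route == "IV"]
        assert iv == [(0.5, 1.0), (1.0, 1.0), (1.0, 2.0), (1.0, 3.0)]

    def test_unknown_electrolyte_rejected(self):
        with pytest.raises(ValueError, match="electrolyte"):
            action_catalog("Na")

    def test_action_invariants_enforced(self):
        with pytest.raises(ValueError):
            RepletionAction("K", "PO", po_level=0)
        with pytest.raises(ValueError):
            RepletionAction("K", "NONE", po_level=1)
        with pytest.raises(ValueError):
            RepletionAction("K", "BOTH", po_level=1, iv_level=0)


class TestEncodeHistoricalAction:
    def _meds(self, rows):
        return pd.DataFrame(
            rows, columns=["start_hours", "end_hours", "drug", "dose", "route"]
        )

    def test_po_40mg_maps_to_level_2(self):
        a = encode_historical_action(self._meds([(0, 0.5, "K-PO", 40.0, "PO")]), "K")
        assert (a.route, a.po_level) == ("PO", 2)

    def test_empty_rows_give_none(self):
        a = encode_historical_action(self._meds([]), "K")
        assert a.route == "NONE"

    def test_iv_dose_tie_breaks_to_lower_level(self):
        # 30 mEq over 2 h: equidistant from the 20 and 40 mEq entries;
        # the tie goes to the lower dose, and duration 2 h picks IV1
        a = encode_historical_action(self._meds([(0, 2.0, "K-IV", 30.0, "IV")]), "K")
        assert (a.route, a.iv_level, a.iv_dose, a.iv_duration_h) == ("IV", 1, 20.0, 2.0)

    def test_same_route_rows_summed_before_snapping(self):
        a = encode_historical_action(
            self._meds([(0, 0.2, "K-PO", 20.0, "PO"), (1, 1.2, "K-PO", 20.0, "PO")]), "K"
        )
        assert (a.route, a.po_level) == ("PO", 2)

    def test_both_routes_give_both(self):
        a = encode_historical_action(
            self._meds([(0, 0.5, "K-PO", 20.0, "PO"), (0, 2.0, "K-IV", 20.0, "IV")]), "K"
        )
        assert a.route == "BOTH" and a.po_level == 1 and a.iv_level == 1

    def test_unmatched_drugs_ignored(self):
        a = encode_historical_action(self._meds([(0, 0.5, "Mg-PO", 400.0, "PO")]), "K")
        assert a.route == "NONE"

    def test_roundtrip_identity_on_every_catalog_action(self, k_catalog):
        """Encoding an action's own dose rows recovers the action."""
        for a in k_catalog:
            rows = []
            if a.has_po:
                rows.append((0.0, 0.5, "K-PO", a.po_dose_mg, "PO"))
            if a.has_iv:
                rows.append((0.0, a.iv_duration_h, "K-IV", a.iv_dose, "IV"))
            back = encode_historical_action(self._meds(rows), "K", k_catalog)
            assert (back.route, back.po_level, back.iv_level) == (a.route, a.po_level, a.iv_level)


class TestReward:
    def test_none_action_below_range(self, k_catalog):
        r, phi = reward(K_AI, k_catalog[0], 3.2, K_RANGE)
        assert r == pytest.approx(-0.74)
        assert phi.tolist() == [0, 0, 0, 1]

    def test_none_action_in_range_is_zero(self, k_catalog):
        r, phi = reward(K_AI, k_catalog[0], 4.2, K_RANGE)
        assert r == 0.0 and phi.sum() == 0

    def test_both_action_in_range_pays_both_costs(self, k_catalog):
        both = k_catalog[catalog_index(k_catalog, "BOTH", po_level=1, iv_level=1)]
        r, _ = reward(K_AI, both, 4.2, K_RANGE)
        assert r == pytest.approx(-0.11)

    def test_bounded_for_normalized_nonnegative_weights(self, k_catalog):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = normalize_weights(rng.random(4))
            a = k_catalog[rng.integers(len(k_catalog))]
            r, _ = reward(w, a, float(rng.uniform(1, 8)), K_RANGE)
            assert -1.0 <= r <= 0.0

    def test_depends_only_on_action_and_level(self, k_catalog):
        # the reward ignores every state feature except the next level
        r1, _ = reward(K_AI, k_catalog[3], 3.0, K_RANGE)
        r2, _ = reward(K_AI, k_catalog[3], 3.0, K_RANGE)
        assert r1 == r2

    def test_non_finite_level_rejected(self, k_catalog):
        with pytest.raises(ValueError, match="finite"):
            reward(K_AI, k_catalog[0], float("nan"), K_RANGE)

    def test_graded_variant_scales_with_distance(self, k_catalog):
        r_near, _ = reward(K_AI, k_catalog[0], 3.4, K_RANGE, graded=True)
        r_far, _ = reward(K_AI, k_catalog[0], 2.4, K_RANGE, graded=True)
        assert r_far < r_near < 0


class TestNormalizeWeights:
    def test_already_normalized_unchanged(self):
        w = normalize_weights((-0.05, -0.08, 0.20, 0.67))
        assert np.allclose(w.as_array(), [-0.05, -0.08, 0.20, 0.67])

    @pytest.mark.parametrize(
        "raw,expected",
        [((2, 0, 0, 0), (1, 0, 0, 0)), ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25))],
    )
    def test_scaling(self, raw, expected):
        assert np.allclose(normalize_weights(raw).as_array(), expected)

    def test_preserves_signs_and_unit_norm(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            raw = rng.normal(size=4)
            w = normalize_weights(raw)
            assert w.l1_norm == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.sign(w.as_array()) == np.sign(raw))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_weights((0, 0, 0, 0))


def _spec():
    return MDPSpec(
        electrolyte="K",
        state_features=("K", "age", "admit_weight", "prior_po_level", "prior_iv_level"),
        reward_weights=K_AI,
        gamma=0.9,
    )


class TestBuildTransitions:
    def _binned(self, n_bins, meds=()):
        obs = [(6.0 * t, "K", 4.0) for t in range(n_bins)]
        obs.append((6.0 * n_bins - 0.5, "heart_rate", 80.0))
        visit = make_visit(obs=obs, meds=list(meds))
        return impute([bin_visit(visit)])[0]

    def test_sample_count_formula(self):
        bv = self._binned(32)
        samples = build_transitions([bv], _spec())
        assert len(samples) == 32  # 31 non-terminal + 1 terminal
        assert sum(not s.terminal for s in samples) == 31
        assert samples[-1].terminal and samples[-1].next_state is None

    def test_single_bin_visit_skipped(self):
        bv = self._binned(1)
        assert build_transitions([bv], _spec()) == []

    def test_action_and_prior_indicator_alignment(self):
        meds = [(6.0, 6.5, "K-PO", 40.0, "PO")]  # PO2 in bin 1
        bv = self._binned(4, meds)
        spec = _spec()
        samples = build_transitions([bv], spec)
        i_po = spec.state_features.index("prior_po_level")
        assert samples[1].action_index != 0  # bin 1 carries the repletion
        assert samples[2].state[i_po] == 2.0  # bin 2 sees last interval's PO level
        assert samples[1].state[i_po] == 0.0

    def test_reward_prices_next_bin_level(self):
        visit = make_visit(
            obs=[(0.0, "K", 4.0), (6.0, "K", 3.0), (12.0, "K", 4.1), (17.5, "heart_rate", 80)]
        )
        bv = impute([bin_visit(visit)])[0]
        samples = build_transitions([bv], _spec())
        assert samples[0].reward == pytest.approx(-0.74)  # next bin is hypokalemic
        assert samples[1].reward == 0.0

    def test_reward_equals_negated_weighted_features(self):
        bv = self._binned(6, [(0.0, 2.0, "K-IV", 20.0, "IV")])
        for s in build_transitions([bv], _spec()):
            assert s.reward == pytest.approx(-(K_AI.as_array() @ s.reward_features))


def test_action_cost_offsets_match_route_costs(k_catalog):
    off = action_cost_offsets(k_catalog, K_AI)[:, 0]
    for a, o in zip(k_catalog, off):
        assert o == pytest.approx(-(0.07 * a.has_iv + 0.04 * a.has_po))


def test_default_state_feature_list_has_52_entries():
    feats = default_state_features()
    assert len(feats) == 52 and len(set(feats)) == 52


def test_mdp_spec_validation():
    with pytest.raises(ValueError):
        MDPSpec("K", ("K", "K"), K_AI)
    with pytest.raises(ValueError):
        MDPSpec("K", ("K",), K_AI, gamma=1.0)
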