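"""Config-driven cost model for repletion workflows.

Each repletion event is priced as drug cost + staff time (per-task minutes
times role wages) + attributed follow-up lab work (panel price plus the
draw's staff time).  All prices, wages, and task times are configuration:
the shipped defaults are illustrative round numbers for demonstration, not
a reproduction of any hospital's cost accounting, and every monetary output
is a function of the supplied config.  A single (non-tiered) rate applies
per item.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .mdp import IV_ENTRIES, PO_DOSES_MG, RepletionAction

#: Tasks attributable to a repletion event or lab draw.
TASKS = ("order", "prepare", "administer_po", "administer_iv", "monitor_iv", "draw_lab")
ROLES = ("nurse", "pharmacist", "provider", "phlebotomist")

#: Which tasks each route incurs (BOTH sums the PO and IV task sets).
ROUTE_TASKS = {
    "PO": ("order", "prepare", "administer_po"),
    "IV": ("order", "prepare", "administer_iv", "monitor_iv"),
}


@dataclass
class CostModel:
    """Unit prices, wages, and task times for the repletion workflow.

    ``drug_unit_cost`` maps (electrolyte, route, dose_level) -> currency;
    ``staff_minutes`` maps (task, role) -> minutes; ``wage_per_hour`` maps
    role -> currency/h; ``labs_per_repletion`` counts follow-up draws
    attributed to each repletion event.
    """

    drug_unit_cost: dict[tuple[str, str, int], float]
    lab_test_cost: float
    staff_minutes: dict[tuple[str, str], float]
    wage_per_hour: dict[str, float]
    labs_per_repletion: float = 1.0

    def __post_init__(self) -> None:
        bad = [k for k, v in self.drug_unit_cost.items() if v < 0]
        bad += [k for k, v in self.staff_minutes.items() if v < 0]
        bad += [k for k, v in self.wage_per_hour.items() if v < 0]
        if bad or self.lab_test_cost < 0 or self.labs_per_repletion < 0:
            raise ValueError(f"costs and minutes must be non-negative (offending: {bad})")


@dataclass
class CostBreakdown:
    """Itemized currency breakdown; components always sum to the total."""

    drug: float = 0.0
    staff: float = 0.0
    lab: float = 0.0

    @property
    def total(self) -> float:
        return self.drug + self.staff + self.lab

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(self.drug + other.drug, self.staff + other.staff, self.lab + other.lab)

    def to_dict(self) -> dict:
        return {"drug": self.drug, "staff": self.staff, "lab": self.lab, "total": self.total}


def _staff_cost(model: CostModel, tasks: Sequence[str]) -> float:
    cost = 0.0
    for task in tasks:
        for role in ROLES:
            minutes = model.staff_minutes.get((task, role), 0.0)
            if minutes:
                cost += minutes * model.wage_per_hour.get(role, 0.0) / 60.0
    return cost


def event_cost(action: RepletionAction, model: CostModel) -> CostBreakdown:
    """Itemized cost of one repletion decision; the NONE action costs 0."""
    if not action.is_repletion:
        return CostBreakdown()
    out = CostBreakdown()
    for route, level in (("PO", action.po_level), ("IV", action.iv_level)):
        if level == 0:
            continue
        key = (action.electrolyte, route, level)
        if key not in model.drug_unit_cost:
            raise KeyError(f"price table has no entry for {key}")
        out.drug += model.drug_unit_cost[key]
        out.staff += _staff_cost(model, ROUTE_TASKS[route])
    out.lab += model.labs_per_repletion * model.lab_test_cost
    out.staff += model.labs_per_repletion * _staff_cost(model, ("draw_lab",))
    return out


@dataclass
class CostComparison:
    """Historical vs policy-recommended expenditure over the same visits."""

    historical: CostBreakdown
    policy: CostBreakdown
    n_visits: int

    @property
    def savings(self) -> float:
        return self.historical.total - self.policy.total

    @property
    def per_visit_savings(self) -> float:
        return self.savings / self.n_visits if self.n_visits else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_visits": self.n_visits,
            "historical": self.historical.to_dict(),
            "policy": self.policy.to_dict(),
            "savings": self.savings,
            "per_visit_savings": self.per_visit_savings,
        }


def cohort_cost_comparison(
    historical_actions: Sequence[RepletionAction],
    policy_actions: Sequence[RepletionAction],
    model: CostModel,
    n_visits: int,
) -> CostComparison:
    """Total and per-visit expenditure comparison of two action streams over
    the same visits (streams are per decision point)."""
    hist = CostBreakdown()
    pol = CostBreakdown()
    for a in historical_actions:
        hist = hist + event_cost(a, model)
    for a in policy_actions:
        pol = pol + event_cost(a, model)
    return CostComparison(historical=hist, policy=pol, n_visits=n_visits)


def default_cost_model() -> CostModel:
    """Illustrative demonstration prices (documented, not calibrated to any
    payer schedule): drug prices grow with the dose level, IV preparations
    cost more than PO, and one follow-up panel is attributed per event."""
    drug = {}
    for elec, doses in PO_DOSES_MG.items():
        for level in range(1, len(doses) + 1):
            drug[(elec, "PO", level)] = 1.0 + 0.5 * level
    for elec, entries in IV_ENTRIES.items():
        for level in range(1, len(entries) + 1):
            drug[(elec, "IV", level)] = 6.0 + 2.0 * level
    staff = {
        ("order", "provider"): 2.0,
        ("prepare", "pharmacist"): 4.0,
        ("administer_po", "nurse"): 3.0,
        ("administer_iv", "nurse"): 10.0,
        ("monitor_iv", "nurse"): 10.0,
        ("draw_lab", "phlebotomist"): 5.0,
    }
    wages = {"nurse": 40.0, "pharmacist": 60.0, "provider": 120.0, "phlebotomist": 25.0}
    return CostModel(
        drug_unit_cost=drug,
        lab_test_cost=10.0,
        staff_minutes=staff,
        wage_per_hour=wages,
        labs_per_repletion=1.0,
    )


def cost_model_from_yaml(path: str | Path) -> CostModel:
    """Load a cost model from a YAML file with string-keyed maps, e.g.
    ``drug_unit_cost: {"K/PO/1": 1.5, ...}`` and
    ``staff_minutes: {"order/provider": 2}``."""
    raw = yaml.safe_load(Path(path).read_text())
    drug = {}
    for key, v in raw["drug_unit_cost"].items():
        elec, route, level = key.split("/")
        drug[(elec, route, int(level))] = float(v)
    staff = {}
    for key, v in raw["staff_minutes"].items():
        task, role = key.split("/")
        staff[(task, role)] = float(v)
    return CostModel(
        drug_unit_cost=drug,
        lab_test_cost=float(raw["lab_test_cost"]),
        staff_minutes=staff,
        wage_per_hour={k: float(v) for k, v in raw["wage_per_hour"].items()},
        labs_per_repletion=float(raw.get("labs_per_repletion", 1.0)),
    )


def cost_model_to_yaml(model: CostModel, path: str | Path) -> None:
    raw = {
        "drug_unit_cost": {f"{e}/{r}/{l}": v for (e, r, l), v in model.drug_unit_cost.items()},
        "lab_test_cost": model.lab_test_cost,
        "staff_minutes": {f"{t}/{r}": v for (t, r), v in model.staff_minutes.items()},
        "wage_per_hour": dict(model.wage_per_hour),
        "labs_per_repletion": model.labs_per_repletion,
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
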