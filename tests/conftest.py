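"""Shared fixtures: hand-built miniature cohorts and toy MDPs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from replete.cohort import visits_from_frames
from replete.mdp import action_catalog


@pytest.fixture(scope="session")
def k_catalog():
    return action_catalog("K")


def _obs_rows(visit_id, times, variable="K", value=4.0):
    return [(visit_id, t, variable, value) for t in times]


@pytest.fixture()
def five_visit_frames():
    """Five hand-written visits for exercising the exclusion funnel.

    Ages {17, 30, 40, 50, 60}; stays {100, 10, 300, 100, 100} h (the last
    observation pins the stay length); every visit has potassium labs, an
    admission weight, and one repletion order, so only age and stay length
    discriminate.  Hand enumeration: visits 4 and 5 survive the funnel
    (adult, 24-192 h).
    """
    static = pd.DataFrame(
        [
            ("A", 17, "F", 70.0),
            ("B", 30, "M", 80.0),
            ("C", 40, "F", 75.0),
            ("D", 50, "M", 90.0),
            ("E", 60, "F", 65.0),
        ],
        columns=["visit_id", "age", "sex", "admit_weight"],
    )
    los = {"A": 100, "B": 10, "C": 300, "D": 100, "E": 100}
    obs = []
    for vid, l in los.items():
        obs += _obs_rows(vid, [0.0, l / 2, float(l)], "K", 3.9)
    observations = pd.DataFrame(obs, columns=["visit_id", "time_hours", "variable", "value"])
    medications = pd.DataFrame(
        [(vid, 6.0, 6.5, "K-PO", 40.0, "PO") for vid in los],
        columns=["visit_id", "start_hours", "end_hours", "drug", "dose", "route"],
    )
    return static, observations, medications


@pytest.fixture()
def five_visits(five_visit_frames):
    visits, _ = visits_from_frames(*five_visit_frames)
    return visits


def make_visit(visit_id="V1", age=50.0, weight=80.0, obs=None, meds=None):
    """Build one PatientVisit from terse (time, variable, value) tuples."""
    static = pd.DataFrame(
        [(visit_id, age, "F", weight)], columns=["visit_id", "age", "sex", "admit_weight"]
    )
    obs_df = pd.DataFrame(
        [(visit_id, t, var, val) for (t, var, val) in (obs or [])],
        columns=["visit_id", "time_hours", "variable", "value"],
    )
    med_df = pd.DataFrame(
        [(visit_id, s, e, d, dose, r) for (s, e, d, dose, r) in (meds or [])],
        columns=["visit_id", "start_hours", "end_hours", "drug", "dose", "route"],
    )
    visits, _ = visits_from_frames(static, obs_df, med_df)
    return visits[0]
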