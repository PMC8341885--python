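import numpy as np
import pandas as pd
import pytest

import checkrisk as ck
from checkrisk.checklist import ITEM_PREFIX, OUTCOME_COLUMN


@pytest.fixture(scope="session")
def definition():
    return ck.load_default_definition()


@pytest.fixture(scope="session")
def fixtures():
    return ck.load_fixtures()


def make_cohort(definition, responses, outcomes):
    """Build a cohort DataFrame from a list of per-participant response dicts
    (item_id -> 0/1/None) and an outcome list."""
    rows = []
    for i, (resp, y) in enumerate(zip(responses, outcomes)):
        row = {"participant_id": f"P{i:03d}", OUTCOME_COLUMN: y}
        for item_id in definition.item_ids:
            row[f"{ITEM_PREFIX}{item_id}"] = resp.get(item_id, 0)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_cohort(definition):
    responses = [
        {},
        {"attempt_lifetime": 1},
        {"attempt_lifetime": 1, "hosp_lifetime": 1, "ideation_lifetime": 1, "mood_disorder": 1},
        {i: 1 for i in definition.item_ids},
    ]
    return make_cohort(definition, responses, [0, 0, 1, 1])


def brute_force_auc(scores, outcomes):
    """O(n^2) pair-enumeration oracle for the Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    cases = scores[outcomes == 1]
    controls = scores[outcomes == 0]
    total = 0.0
    for x in cases:
        for y in controls:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(cases) * len(controls))
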