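import numpy as np
import pandas as pd
import pytest

import svscore as sv
from svscore.scorecard import ScoreRow, ScoringTable


@pytest.fixture(scope="session")
def toy_cohort():
    """d=6 cohort (5 continuous + 1 binary) with known logistic truth."""
    rng = np.random.default_rng(0)
    n = 600
    schema = [sv.VariableSchema(f"x{i}", "continuous") for i in range(5)]
    schema.append(sv.VariableSchema("b", "binary"))
    vals = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(5)})
    vals["b"] = rng.binomial(1, 0.4, n)
    beta = np.array([1.0, 0.5, 0.0, -0.7, 0.3, 0.6])
    eta = -0.5 + vals.to_numpy(float) @ beta
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    table = sv.CohortTable(schema=schema, values=vals, outcome=y)
    return sv.split_cohort(table, (0.5, 0.25, 0.25), seed=1)


@pytest.fixture(scope="session")
def toy_model(toy_cohort):
    return sv.fit_optimal(toy_cohort.subset("train"))


@pytest.fixture(scope="session")
def small_ehr_cohort():
    """Default 11-variable EHR-like cohort at modest size, split and imputed."""
    table, truth = sv.generate_cohort(sv.default_ehr_spec(3000, seed=5))
    table = sv.impute_training_median(sv.split_cohort(table, seed=2))
    return table, truth


def published_model2_table() -> ScoringTable:
    """The six-variable readmission/death scorecard printed in the source
    study (Model 2), rebuilt row by row as a worked example of score
    arithmetic; per-variable maxima are 33, 21, 19, 10, 8 and 9."""
    R = ScoreRow
    rows = [
        R("ed_visits", "<1", -np.inf, 1, points=0),
        R("ed_visits", "[1, 3)", 1, 3, points=14),
        R("ed_visits", ">=3", 3, np.inf, points=33),
        R("metastatic_cancer", "No", levels=("0",), points=0),
        R("metastatic_cancer", "Yes", levels=("1",), points=21),
        R("age", "<25", -np.inf, 25, points=0),
        R("age", "[25, 45)", 25, 45, points=4),
        R("age", "[45, 75)", 45, 75, points=12),
        R("age", "[75, 85)", 75, 85, points=15),
        R("age", ">=85", 85, np.inf, points=19),
        R("sodium", "<125", -np.inf, 125, points=10),
        R("sodium", "[125, 130)", 125, 130, points=7),
        R("sodium", "[130, 135)", 130, 135, points=4),
        R("sodium", ">=135", 135, np.inf, points=0),
        R("renal_disease", "No", levels=("0",), points=0),
        R("renal_disease", "Yes", levels=("1",), points=8),
        R("ed_triage", "P1", levels=("P1",), points=9),
        R("ed_triage", "P2", levels=("P2",), points=6),
        R("ed_triage", "P3 and P4", levels=("P3", "P4"), points=0),
    ]
    return ScoringTable(
        variables=["ed_visits", "metastatic_cancer", "age", "sodium",
                   "renal_disease", "ed_triage"],
        rows=rows, cap=100,
    )
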