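import numpy as np
import pandas as pd
import pytest

import svscore as sv
from svscore.scorecard import CategorizationError

from conftest import published_model2_table


@pytest.fixture(scope="module")
def ehr_parts(small_ehr_cohort):
    table, truth = small_ehr_cohort
    return (table.subset("train"), table.subset("validation"),
            table.subset("test"), truth)


class TestRandomForestRanking:
    def test_informative_variable_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 5000
        vals = pd.DataFrame({"signal": rng.normal(size=n),
                             "noise": rng.normal(size=n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-1.5 * vals["signal"])), n)
        t = sv.CohortTable(
            schema=[sv.VariableSchema(c, "continuous") for c in vals.columns],
            values=vals, outcome=y)
        assert sv.rank_by_random_forest(t, n_trees=60, seed=1)[0] == "signal"

    def test_deterministic_and_complete(self, ehr_parts):
        train = ehr_parts[0]
        a = sv.rank_by_random_forest(train, n_trees=40, seed=3)
        b = sv.rank_by_random_forest(train, n_trees=40, seed=3)
        assert a == b
        assert sorted(a) == sorted(train.variable_names)


class TestDeriveCuts:
    def test_quantile_cuts_match_empirical_quantiles(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 20_000)
        t = sv.CohortTable(schema=[sv.VariableSchema("u", "continuous"),
                                   sv.VariableSchema("z", "continuous")],
                           values=pd.DataFrame({"u": x, "z": rng.normal(size=x.size)}),
                           outcome=rng.binomial(1, 0.5, x.size))
        cuts = sv.derive_cuts(t, ["u"])
        assert np.allclose(cuts.cuts["u"], [0.05, 0.2, 0.8, 0.95], atol=0.01)

    def test_duplicate_cuts_collapsed(self):
        x = np.zeros(100)
        x[-1] = 50.0
        t = sv.CohortTable(schema=[sv.VariableSchema("c", "continuous")],
                           values=pd.DataFrame({"c": x}),
                           outcome=np.tile([0, 1], 50))
        cuts = sv.derive_cuts(t, ["c"])
        assert len(cuts.cuts["c"]) == 1

    def test_kmeans_cut_at_cluster_midpoint(self):
        x = np.concatenate([np.arange(10.0), np.arange(100.0, 110.0)])
        t = sv.CohortTable(schema=[sv.VariableSchema("k", "continuous")],
                           values=pd.DataFrame({"k": x}),
                           outcome=np.tile([0, 1], 10))
        cuts = sv.derive_cuts(t, ["k"], method="kmeans", k=2)
        assert cuts.cuts["k"] == pytest.approx([54.5])

    def test_constant_variable_rejected(self):
        t = sv.CohortTable(schema=[sv.VariableSchema("c", "continuous")],
                           values=pd.DataFrame({"c": np.ones(10)}),
                           outcome=np.tile([0, 1], 5))
        with pytest.raises(CategorizationError, match="c"):
            sv.derive_cuts(t, ["c"])


class TestScaleRoundPoints:
    def test_stated_arithmetic_example(self):
        """Maxima {1.0, 0.25} with cap 100 scale to points {0,40,80},{0,20}."""
        pts, factor = sv.scale_round_points(
            {"a": np.array([0.0, 0.5, 1.0]), "b": np.array([0.0, 0.25])}, 100)
        assert factor == pytest.approx(80.0)
        assert pts["a"].tolist() == [0, 40, 80]
        assert pts["b"].tolist() == [0, 20]

    def test_single_binary_variable_degenerate_scorecard(self):
        pts, _ = sv.scale_round_points({"b": np.array([0.0, 0.37])}, 100)
        assert pts["b"].tolist() == [0, 100]

    def test_largest_remainder_repair_hits_cap_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            shifted = {f"v{i}": np.sort(rng.uniform(0, 1, rng.integers(2, 6)))
                       for i in range(rng.integers(2, 7))}
            for v in shifted.values():
                v -= v.min()
            pts, _ = sv.scale_round_points(shifted, 100)
            assert sum(p.max() for p in pts.values()) == 100
            assert all((p >= 0).all() and (p.min() == 0) for p in pts.values())


class TestAssignPoints:
    def test_generated_table_invariants(self, ehr_parts):
        train, _, _, truth = ehr_parts
        variables = list(truth.signal_names)
        cuts = sv.derive_cuts(train, variables)
        table = sv.assign_points(train, variables, cuts, cap=100)
        assert table.max_total == 100
        for v in variables:
            pts = [r.points for r in table.rows_for(v)]
            assert min(pts) == 0 and all(p >= 0 for p in pts)

    def test_integer_score_auc_close_to_categorized_model(self, ehr_parts):
        """Rounding to integer points degrades AUC by less than 0.03."""
        import statsmodels.api as sm

        from svscore.scorecard import _categorized_design

        train, val, _, truth = ehr_parts
        variables = list(truth.signal_names)
        cuts = sv.derive_cuts(train, variables)
        table = sv.assign_points(train, variables, cuts, cap=100)
        score_auc = sv.auc(sv.score_cohort(table, val).astype(float), val.outcome)
        X, _, cats, _ = _categorized_design(train, variables, cuts)
        res = sm.Logit(train.outcome,
                       sm.add_constant(X, has_constant="add")).fit(disp=0)
        Xv, _, _, _ = _categorized_design(val, variables, cuts, cats_by_var=cats)
        proba = res.predict(sm.add_constant(Xv, has_constant="add"))
        assert abs(score_auc - sv.auc(proba, val.outcome)) < 0.03


class TestComputeScore:
    def test_published_table_row_maxima_and_invariants(self):
        table = published_model2_table()
        assert table.max_total == 100
        maxima = {v: max(r.points for r in table.rows_for(v))
                  for v in table.variables}
        assert maxima == {"ed_visits": 33, "metastatic_cancer": 21, "age": 19,
                          "sodium": 10, "renal_disease": 8, "ed_triage": 9}
        for v in table.variables:
            assert min(r.points for r in table.rows_for(v)) == 0

    def test_published_table_worked_score_sums(self):
        table = published_model2_table()
        sickest = {"ed_visits": 5, "metastatic_cancer": 1, "age": 90,
                   "sodium": 120, "renal_disease": 1, "ed_triage": "P1"}
        healthiest = {"ed_visits": 0, "metastatic_cancer": 0, "age": 30,
                      "sodium": 140, "renal_disease": 0, "ed_triage": "P3"}
        assert sv.compute_score(table, sickest) == 100
        assert sv.compute_score(table, healthiest) == 4

    def test_interval_convention_closed_below_open_above(self):
        table = published_model2_table()
        base = {"ed_visits": 0, "metastatic_cancer": 0, "sodium": 140,
                "renal_disease": 0, "ed_triage": "P3"}
        assert sv.compute_score(table, {**base, "age": 45}) == 12
        assert sv.compute_score(table, {**base, "age": 44.999}) == 4

    def test_empty_table_scores_zero(self):
        from svscore.scorecard import ScoringTable
        assert sv.compute_score(ScoringTable(variables=[], rows=[], cap=0), {}) == 0

    def test_missing_variable_is_input_error(self):
        with pytest.raises(KeyError):
            sv.compute_score(published_model2_table(), {"age": 40})


class TestParsimony:
    def test_noise_addition_below_threshold_stops_growth(self):
        rng = np.random.default_rng(6)
        n = 4000
        vals = pd.DataFrame({"signal": rng.normal(size=n),
                             "noise": rng.normal(size=n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-1.2 * vals["signal"])), n)
        t = sv.CohortTable(
            schema=[sv.VariableSchema(c, "continuous") for c in vals.columns],
            values=vals, outcome=y)
        t = sv.split_cohort(t, (0.6, 0.2, 0.2), seed=1)
        curve = sv.parsimony_curve(["signal", "noise"], t.subset("train"),
                                   t.subset("validation"))
        assert curve.suggested_size == 1
        assert curve.aucs[1] - curve.aucs[0] < 0.01

    def test_single_variable_ranking(self, ehr_parts):
        train, val = ehr_parts[0], ehr_parts[1]
        curve = sv.parsimony_curve(["ed_visits"], train, val)
        assert len(curve.aucs) == 1 and curve.suggested_size == 1


class TestFineTune:
    def test_identity_override_reproduces_table(self, ehr_parts):
        train, _, _, truth = ehr_parts
        variables = list(truth.signal_names)
        cuts = sv.derive_cuts(train, variables)
        table = sv.assign_points(train, variables, cuts, cap=100)
        same = sv.fine_tune(table, {"sodium": cuts.cuts["sodium"]}, train)
        assert same.to_frame().equals(table.to_frame())

    def test_merging_intervals_reduces_rows(self, ehr_parts):
        train, _, _, truth = ehr_parts
        variables = list(truth.signal_names)
        cuts = sv.derive_cuts(train, variables)
        table = sv.assign_points(train, variables, cuts, cap=100)
        merged_cuts = cuts.cuts["sodium"][1:]        # drop the lowest cut
        tuned = sv.fine_tune(table, {"sodium": merged_cuts}, train)
        assert len(tuned.rows_for("sodium")) == len(table.rows_for("sodium")) - 1
        assert tuned.max_total == 100
        assert min(r.points for r in tuned.rows_for("sodium")) == 0

    def test_non_monotone_override_rejected(self, ehr_parts):
        train, _, _, truth = ehr_parts
        cuts = sv.derive_cuts(train, list(truth.signal_names))
        table = sv.assign_points(train, list(truth.signal_names), cuts, cap=100)
        with pytest.raises(CategorizationError):
            sv.fine_tune(table, {"sodium": [140.0, 130.0]}, train)

    def test_override_leaving_empty_category_rejected(self, ehr_parts):
        train, _, _, truth = ehr_parts
        cuts = sv.derive_cuts(train, list(truth.signal_names))
        table = sv.assign_points(train, list(truth.signal_names), cuts, cap=100)
        lo = float(train.values["sodium"].min())
        with pytest.raises(CategorizationError, match="empty"):
            sv.fine_tune(table, {"sodium": [lo - 10.0, lo - 5.0]}, train)
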