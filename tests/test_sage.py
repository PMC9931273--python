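import numpy as np
import pandas as pd
import pytest

import svscore as sv
from svscore.logistic import LogisticModel, build_encoding
from svscore.sage import _LossGame, _background_sample


@pytest.fixture(scope="module")
def toy_setup(toy_cohort, toy_model):
    val = toy_cohort.subset("validation")
    cfg = sv.SageConfig(eval_rows=100, background_rows=40, n_permutations=300,
                        minibatch=25, seed=4)
    bg = _background_sample(toy_cohort.subset("train"), cfg,
                            np.random.default_rng(9))
    return val.head(100), bg, cfg


class TestSageValues:
    def test_null_player_is_exactly_zero(self, toy_cohort, toy_model, toy_setup):
        ev, bg, cfg = toy_setup
        m = toy_model.with_params(toy_model.packed.copy())
        m.coefficients[2] = 0.0          # zero out x2's block
        v, s = sv.sage_values(m, ev, cfg, background=bg)
        assert v[2] == 0.0 and s[2] == 0.0

    def test_symmetric_variables_get_equal_values(self):
        rng = np.random.default_rng(1)
        n = 400
        vals = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        schema = [sv.VariableSchema(c, "continuous") for c in vals.columns]
        y = rng.binomial(1, 0.4, n)
        t = sv.CohortTable(schema=schema, values=vals, outcome=y)
        m = LogisticModel(intercept=-0.3, coefficients=np.array([0.8, 0.8]),
                          encoding=build_encoding(schema))
        cfg = sv.SageConfig(eval_rows=200, background_rows=50,
                            n_permutations=400, seed=2)
        bg = _background_sample(t, cfg, np.random.default_rng(3))
        v, s = sv.sage_values(m, t.head(200), cfg, background=bg)
        assert abs(v[0] - v[1]) < 3 * np.sqrt(s[0] ** 2 + s[1] ** 2)

    def test_permutation_estimate_matches_exact_enumeration(
            self, toy_model, toy_setup):
        ev, bg, cfg = toy_setup
        v, s = sv.sage_values(toy_model, ev, cfg, background=bg)
        exact = sv.exact_shapley(toy_model, ev, bg)
        for j in range(len(v)):
            tol = 3 * max(s[j], 1e-12)
            assert abs(v[j] - exact[j]) < tol

    def test_efficiency_within_monte_carlo_error(self, toy_model, toy_setup):
        ev, bg, cfg = toy_setup
        v, s = sv.sage_values(toy_model, ev, cfg, background=bg)
        game = _LossGame(toy_model, ev, bg)
        gap = game.coalition_loss(()) - game.coalition_loss(tuple(range(game.d)))
        assert abs(v.sum() - gap) < 3 * np.sqrt((s ** 2).sum())

    def test_se_shrinks_like_sqrt_budget(self, toy_model, toy_setup):
        ev, bg, _ = toy_setup
        ses = {}
        for T in (100, 400):
            cfg = sv.SageConfig(eval_rows=100, background_rows=40,
                                n_permutations=T, minibatch=25, seed=13)
            _, s = sv.sage_values(toy_model, ev, cfg, background=bg,
                                  rng=np.random.default_rng(13))
            ses[T] = np.median(s)
        assert ses[100] / ses[400] == pytest.approx(2.0, rel=0.35)


class TestExactShapley:
    def test_intercept_only_model_all_zero(self, toy_cohort, toy_model, toy_setup):
        ev, bg, _ = toy_setup
        m = toy_model.with_params(
            np.concatenate([[0.3], np.zeros(toy_model.coefficients.size)]))
        assert np.all(sv.exact_shapley(m, ev, bg) == 0.0)

    def test_single_player_gets_the_whole_gap(self):
        rng = np.random.default_rng(5)
        n = 150
        vals = pd.DataFrame({"x": rng.normal(size=n)})
        schema = [sv.VariableSchema("x", "continuous")]
        y = rng.binomial(1, 1 / (1 + np.exp(-vals["x"])), n)
        t = sv.CohortTable(schema=schema, values=vals, outcome=y)
        m = LogisticModel(intercept=0.0, coefficients=np.array([1.0]),
                          encoding=build_encoding(schema))
        bg = t.head(40)
        v = sv.exact_shapley(m, t, bg)
        g = _LossGame(m, t, bg)
        assert v[0] == pytest.approx(g.coalition_loss(()) - g.coalition_loss((0,)),
                                     abs=1e-12)

    def test_three_player_toy_ordering(self):
        """beta=(1, 0.5, 0) on independent normals: v1 > v2 > v3 = 0."""
        rng = np.random.default_rng(6)
        n = 300
        vals = pd.DataFrame({c: rng.normal(size=n) for c in ("a", "b", "c")})
        schema = [sv.VariableSchema(c, "continuous") for c in vals.columns]
        eta = vals.to_numpy(float) @ np.array([1.0, 0.5, 0.0])
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)), n)
        t = sv.CohortTable(schema=schema, values=vals, outcome=y)
        m = LogisticModel(intercept=0.0, coefficients=np.array([1.0, 0.5, 0.0]),
                          encoding=build_encoding(schema))
        v = sv.exact_shapley(m, t, t.head(60))
        assert v[2] == 0.0
        assert v[0] > v[1] > 0

    def test_enumeration_refused_beyond_ten_players(self, small_ehr_cohort):
        table, _ = small_ehr_cohort
        m = sv.fit_optimal(table.subset("train"))
        with pytest.raises(ValueError, match="d=11"):
            sv.exact_shapley(m, table.head(20), table.head(20))


class TestModelReliance:
    @pytest.mark.parametrize("value,flag,expected", [
        (-0.02, True, 0.02),
        (-0.02, False, -0.02),
        (0.05, True, 0.05),
    ])
    def test_absolute_value_rule(self, value, flag, expected):
        vif = sv.VifReport(gvif={"x": 1.0}, dof={"x": 1},
                           comparable={"x": 3.0 if flag else 1.0},
                           flagged={"x": flag})
        mr, se = sv.model_reliance(np.array([value]), np.array([0.01]), vif, ["x"])
        assert mr[0] == pytest.approx(expected)
        assert se[0] == 0.01


class TestEnsembleImportance:
    def test_identical_models_give_identical_rows(self, toy_cohort, toy_model):
        from svscore.rashomon import ModelEnsemble, SamplerConfig
        packed = toy_model.packed
        ens = ModelEnsemble(
            params=np.vstack([packed, packed]),
            losses=np.full(2, toy_model.training_loss),
            loss_ratios=np.ones(2), optimal=toy_model,
            config=SamplerConfig(M=2, eps=0.05, u=1.0, seed=0),
        )
        vif = sv.generalized_vif(toy_cohort.subset("train"))
        cfg = sv.SageConfig(eval_rows=60, background_rows=30, n_permutations=40,
                            seed=3)
        imp = sv.ensemble_importance(ens, toy_cohort.subset("validation"), vif, cfg)
        # same model + same per-model seed derivation -> same estimates
        assert imp.M == 2 and imp.d == 6
        assert np.array_equal(imp.values[0], imp.values[1])
        assert list(imp.to_frame().columns) == [
            "model_id", "variable", "value", "se", "abs_flagged", "loss_ratio"]

    def test_rows_align_with_ensemble_order(self, toy_cohort, toy_model):
        train = toy_cohort.subset("train")
        ens = sv.sample_nearly_optimal(
            toy_model, train, sv.SamplerConfig(M=3, eps=0.05, u=1.0, seed=7))
        vif = sv.generalized_vif(train)
        cfg = sv.SageConfig(eval_rows=50, background_rows=25, n_permutations=30,
                            seed=5)
        imp = sv.ensemble_importance(ens, toy_cohort.subset("validation"), vif, cfg)
        assert np.array_equal(imp.loss_ratios, ens.loss_ratios)
        df = imp.to_frame()
        assert df["model_id"].tolist()[:6] == [0] * 6
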