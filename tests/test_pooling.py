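import subprocess

import numpy as np
import pytest
from scipy import stats

import svscore as sv
from svscore.pooling import PoolingError
from svscore.sage import ImportanceMatrix


def _imp(values, ses, variables=None, flags=None, ratios=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    M, d = values.shape
    return ImportanceMatrix(
        values=values, ses=ses,
        variables=variables or [f"v{j}" for j in range(d)],
        abs_flagged=np.zeros(d, bool) if flags is None else np.asarray(flags),
        loss_ratios=np.linspace(1.0, 1.05, M) if ratios is None else ratios,
    )


class TestPoolRandomEffects:
    def test_homogeneous_inputs_closed_form(self):
        M, c, sigma = 50, 0.3, 0.02
        pooled = sv.pool_random_effects(
            _imp(np.full((M, 1), c), np.full((M, 1), sigma)))
        t = stats.t.ppf(0.975, M - 2)
        assert pooled.mean[0] == pytest.approx(c, abs=1e-12)
        assert pooled.tau2[0] == 0.0
        assert pooled.pi_upper[0] == pytest.approx(c + t * sigma / np.sqrt(M), rel=1e-9)
        assert pooled.pi_lower[0] == pytest.approx(c - t * sigma / np.sqrt(M), rel=1e-9)
        assert pooled.significant[0]

    def test_all_zero_variable_degenerate_pi(self):
        """A variable with zero value in every model gets the zero-length
        PI centered at zero and is non-significant."""
        M = 40
        pooled = sv.pool_random_effects(_imp(np.zeros((M, 1)), np.zeros((M, 1))))
        assert pooled.mean[0] == 0.0
        assert pooled.pi_lower[0] == 0.0 == pooled.pi_upper[0]
        assert not pooled.significant[0]

    def test_dersimonian_laird_recovers_simulated_heterogeneity(self):
        """M=100 draws from N(0.5, tau=0.1) with sigma=0.05."""
        rng = np.random.default_rng(42)
        M, sigma = 100, 0.05
        theta = rng.normal(0.5, 0.1, M)
        y = rng.normal(theta, sigma)
        pooled = sv.pool_random_effects(
            _imp(y.reshape(-1, 1), np.full((M, 1), sigma)))
        assert 0.005 <= pooled.tau2[0] <= 0.02
        assert abs(pooled.mean[0] - 0.5) < 0.03

    def test_agrees_with_reference_meta_analysis(self, tmp_path):
        """Cross-check tau2 / pooled mean / SE against metafor's DL fit."""
        rng = np.random.default_rng(7)
        M = 60
        y = rng.normal(0.2, 0.08, M)
        v = rng.uniform(0.001, 0.004, M)
        pooled = sv.pool_random_effects(_imp(y.reshape(-1, 1),
                                             np.sqrt(v).reshape(-1, 1)))
        script = tmp_path / "dl.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"yi <- c({','.join(map(str, y))})\n"
            f"vi <- c({','.join(map(str, v))})\n"
            "f <- rma(yi=yi, vi=vi, method='DL')\n"
            "cat(f$tau2, as.numeric(f$beta), f$se)\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        tau2_r, mean_r, se_r = map(float, out)
        assert pooled.tau2[0] == pytest.approx(tau2_r, rel=1e-6)
        assert pooled.mean[0] == pytest.approx(mean_r, rel=1e-6)
        assert pooled.se_mean[0] == pytest.approx(se_r, rel=1e-6)

    def test_fixed_effect_reduction_when_tau_zero(self):
        rng = np.random.default_rng(3)
        M = 30
        sig = rng.uniform(0.05, 0.2, M)
        y = rng.normal(0.0, 1e-4, M)      # spread far below sigma -> tau2=0
        pooled = sv.pool_random_effects(_imp(y.reshape(-1, 1), sig.reshape(-1, 1)))
        assert pooled.tau2[0] == 0.0
        w = 1 / sig**2
        assert pooled.mean[0] == pytest.approx(np.sum(w * y) / np.sum(w), rel=1e-9)

    def test_needs_two_models(self):
        with pytest.raises(PoolingError):
            sv.pool_random_effects(_imp([[0.1]], [[0.01]]))


class TestPairwiseWins:
    def test_two_variable_significant_difference(self):
        wins = sv.pairwise_wins(np.array([0.5, 0.1]), np.array([0.1, 0.1]))
        assert wins.tolist() == [1, 0]

    def test_identical_values_no_wins(self):
        wins = sv.pairwise_wins(np.array([0.2, 0.2]), np.array([0.05, 0.05]))
        assert wins.tolist() == [0, 0]

    def test_well_separated_values_full_ladder(self):
        wins = sv.pairwise_wins(np.array([0.4, 0.3, 0.2, 0.1]),
                                np.full(4, 1e-6))
        assert wins.tolist() == [3, 2, 1, 0]

    def test_zero_se_pairs_decided_by_value(self):
        wins = sv.pairwise_wins(np.array([0.0, 0.1]), np.zeros(2))
        assert wins.tolist() == [0, 1]


class TestRankWithinModel:
    @pytest.mark.parametrize("wins,expected", [
        ((3, 3, 1, 0), (1, 1, 3, 4)),
        ((0, 0, 0), (1, 1, 1)),
        ((2, 1, 0), (1, 2, 3)),
    ])
    def test_competition_ranking(self, wins, expected):
        assert tuple(sv.rank_within_model(np.array(wins))) == expected

    def test_rank_is_one_plus_strictly_better(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            wins = rng.integers(0, 6, size=8)
            ranks = sv.rank_within_model(wins)
            for j in range(8):
                assert ranks[j] == 1 + int((wins > wins[j]).sum())


class TestEnsembleRank:
    def _matrix(self):
        rng = np.random.default_rng(5)
        M, d = 30, 4
        base = np.array([0.5, 0.2, 0.05, -0.01])
        values = base + rng.normal(0, 0.005, (M, d))
        ses = np.full((M, d), 0.004)
        return _imp(values, ses, variables=["dom", "mid", "low", "junk"])

    def test_dominant_variable_ranks_first_everywhere(self):
        imp = self._matrix()
        pooled = sv.pool_random_effects(imp)
        rk = sv.ensemble_rank(imp, pooled)
        assert rk.average_rank[0] == 1.0
        assert rk.ordering[0] == "dom"

    def test_filtering_matches_significance(self):
        imp = self._matrix()
        pooled = sv.pool_random_effects(imp)
        rk = sv.ensemble_rank(imp, pooled)
        sig = {v for v, s in zip(pooled.variables, pooled.significant) if s}
        assert set(rk.retained) == sig
        for v, mean in zip(pooled.variables, pooled.mean):
            if mean <= 0:
                assert v not in rk.retained

    def test_ordering_invariant_to_model_permutation(self):
        imp = self._matrix()
        pooled = sv.pool_random_effects(imp)
        order1 = sv.ensemble_rank(imp, pooled).ordering
        perm = np.random.default_rng(9).permutation(imp.M)
        imp2 = _imp(imp.values[perm], imp.ses[perm], variables=imp.variables)
        order2 = sv.ensemble_rank(imp2, sv.pool_random_effects(imp2)).ordering
        assert order1 == order2


class TestPlots:
    def test_plot_files_written_and_degenerate_variable_omitted(
            self, tmp_path, caplog):
        import logging

        M, d = 12, 3
        rng = np.random.default_rng(2)
        values = np.column_stack([
            rng.normal(0.2, 0.01, M), rng.normal(-0.05, 0.01, M), np.zeros(M)])
        ses = np.column_stack([np.full(M, 0.01)] * 2 + [np.zeros(M)])
        imp = _imp(values, ses, variables=["good", "bad", "inert"])
        pooled = sv.pool_random_effects(imp)
        with caplog.at_level(logging.INFO, logger="svscore.pooling"):
            files = sv.plot_importance(pooled, imp, str(tmp_path))
        assert len(files) == 2 and all((tmp_path / f.split("/")[-1]).exists()
                                       for f in files)
        assert any("inert" in r.message for r in caplog.records)
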