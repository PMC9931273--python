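"""End-to-end workflow: cohort -> ensemble importance -> scorecard -> evaluation.

A run executes split → impute → optimal fit → VIF → Rashomon sampling →
per-model SAGE → random-effects pooling → ensemble ranking with
significance filtering (or a random-forest ranking) → parsimony curve →
final scoring table → test-set ROC evaluation, writing every
intermediate artifact plus a manifest so the run can be reproduced
exactly from its config and root seed.  All randomness flows from the
root seed through named substreams (split, sampler, sage, bootstrap).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, impute_training_median, split_cohort
from .logistic import fit_optimal, generalized_vif, logistic_loss
from .metrics import evaluate_scores
from .pooling import ensemble_rank, plot_importance, pool_random_effects
from .rashomon import SamplerConfig, sample_nearly_optimal, tune_scale
from .sage import SageConfig, ensemble_importance
from .scorecard import (assign_points, derive_cuts, parsimony_curve,
                        rank_by_random_forest, score_cohort)

logger = logging.getLogger(__name__)


def _substream(seed: int, name: str) -> int:
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    output_dir: str
    seed: int = 0
    fractions: tuple = (0.7, 0.1, 0.2)
    M: int = 350
    eps: float = 0.05
    u: float = None                  # None -> auto-tune
    sage_eval_rows: int = 3500
    sage_background_rows: int = 512
    sage_permutations: int = 256
    alpha: float = 0.05
    ranking: str = "shapleyvic"      # or "random_forest"
    categorization: str = "quantile"
    quantiles: tuple = (0.05, 0.2, 0.8, 0.95)
    cap: int = 100
    parsimony_threshold: float = 0.01
    n_bootstrap: int = 1000
    rf_trees: int = 100

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunBundle:
    """Artifacts of one pipeline run."""

    config: RunConfig
    cohort: CohortTable
    optimal: "LogisticModel" = None
    vif: "VifReport" = None
    ensemble: "ModelEnsemble" = None
    importance: "ImportanceMatrix" = None
    pooled: "PooledImportance" = None
    ranking: list = None
    ranking_source: str = ""
    parsimony: "ParsimonyCurve" = None
    scoring_table: "ScoringTable" = None
    evaluation: "RocResult" = None
    test_split_checksum: str = ""


def _split_checksum(test: CohortTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(test.outcome).tobytes())
    h.update(pd.util.hash_pandas_object(test.values, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig, cohort: CohortTable,
                 write_plots: bool = True) -> RunBundle:
    """Execute the full workflow on an (unsplit or pre-split) cohort."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    bundle = RunBundle(config=cfg, cohort=cohort)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("split")
        if set(cohort.split_label.unique()) == {"unassigned"}:
            cohort = split_cohort(cohort, cfg.fractions, seed=_substream(cfg.seed, "split"))
        stage("impute")
        cohort = impute_training_median(cohort)
        bundle.cohort = cohort
        cohort.write_split_sidecar(os.path.join(cfg.output_dir, "split_assignment.csv"))
        train, val, test = (cohort.subset(s) for s in ("train", "validation", "test"))
        bundle.test_split_checksum = _split_checksum(test)

        stage("fit_optimal")
        optimal = fit_optimal(train)
        bundle.optimal = optimal
        optimal.to_json(os.path.join(cfg.output_dir, "optimal_model.json"))

        stage("vif")
        vif = generalized_vif(train)
        bundle.vif = vif
        pd.DataFrame({
            "variable": list(vif.gvif), "gvif": list(vif.gvif.values()),
            "df": list(vif.dof.values()), "comparable": list(vif.comparable.values()),
            "flagged": list(vif.flagged.values()),
        }).to_csv(os.path.join(cfg.output_dir, "vif.csv"), index=False)

        if cfg.ranking == "shapleyvic":
            stage("sample_ensemble")
            scfg = SamplerConfig(M=cfg.M, eps=cfg.eps, u=cfg.u or 1.0,
                                 seed=_substream(cfg.seed, "sampler"))
            if cfg.u is None:
                scfg = tune_scale(optimal, train, scfg)
            logger.info("sampler u=%g eps=%g M=%d", scfg.u, scfg.eps, scfg.M)
            ensemble = sample_nearly_optimal(optimal, train, scfg)
            bundle.ensemble = ensemble
            ensemble.to_frame().to_csv(os.path.join(cfg.output_dir, "ensemble.csv"),
                                       index=False)
            with open(os.path.join(cfg.output_dir, "sampler_diagnostics.json"), "w") as fh:
                json.dump(ensemble.diagnostics, fh, indent=2)

            stage("sage")
            sage_cfg = SageConfig(
                eval_rows=min(cfg.sage_eval_rows, val.n),
                background_rows=cfg.sage_background_rows,
                n_permutations=cfg.sage_permutations,
                seed=_substream(cfg.seed, "sage"),
            )
            imp = ensemble_importance(ensemble, val, vif, sage_cfg,
                                      background_data=train)
            bundle.importance = imp
            imp.to_frame().to_csv(os.path.join(cfg.output_dir, "importance.csv"),
                                  index=False)

            stage("pool_and_rank")
            pooled = pool_random_effects(imp)
            ranking_obj = ensemble_rank(imp, pooled, alpha=cfg.alpha)
            bundle.pooled = pooled
            merged = pooled.to_frame().merge(ranking_obj.to_frame(), on="variable")
            merged.to_csv(os.path.join(cfg.output_dir, "pooled_importance.csv"),
                          index=False)
            ranking = ranking_obj.retained
            bundle.ranking_source = "shapleyvic"
            if write_plots:
                plot_importance(pooled, imp, cfg.output_dir)
        else:
            stage("random_forest_ranking")
            ranking = rank_by_random_forest(train, n_trees=cfg.rf_trees,
                                            seed=_substream(cfg.seed, "rf"))
            bundle.ranking_source = "random_forest"
        bundle.ranking = ranking
        if not ranking:
            raise RuntimeError("no variables survived significance filtering")

        stage("parsimony")
        cuts = derive_cuts(train, ranking, method=cfg.categorization,
                           quantiles=cfg.quantiles)
        curve = parsimony_curve(ranking, train, val, cuts=cuts, cap=cfg.cap,
                                threshold=cfg.parsimony_threshold)
        bundle.parsimony = curve
        curve.to_frame().to_csv(os.path.join(cfg.output_dir, "parsimony.csv"),
                                index=False)
        if write_plots:
            _plot_parsimony(curve, cfg.output_dir)

        stage("final_score")
        final_vars = ranking[: curve.suggested_size]
        table = assign_points(train, final_vars, cuts, cap=cfg.cap)
        bundle.scoring_table = table
        table.to_frame().to_csv(os.path.join(cfg.output_dir, "scoring_table.csv"),
                                index=False)
        with open(os.path.join(cfg.output_dir, "scoring_table.md"), "w") as fh:
            fh.write(table.to_markdown() + "\n")

        stage("evaluate")
        scores = score_cohort(table, test).astype(float)
        roc = evaluate_scores(scores, test.outcome, n_resamples=cfg.n_bootstrap,
                              seed=_substream(cfg.seed, "bootstrap"))
        bundle.evaluation = roc
        with open(os.path.join(cfg.output_dir, "evaluation.json"), "w") as fh:
            json.dump({"n_variables": len(final_vars), **roc.to_dict()}, fh, indent=2)

        manifest = {
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "seed_substreams": {name: _substream(cfg.seed, name)
                                for name in ("split", "sampler", "sage", "bootstrap", "rf")},
            "test_split_checksum": bundle.test_split_checksum,
            "final_variables": final_vars,
        }
        with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    return bundle


def _plot_parsimony(curve, out_dir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(curve.variables)), 3.5))
    x = np.arange(1, len(curve.variables) + 1)
    ax.bar(x, curve.aucs, color="#4878a8")
    ax.axvline(curve.suggested_size + 0.5, color="red", ls="--", lw=1)
    ax.set_xticks(x)
    ax.set_xticklabels(curve.variables, rotation=60, ha="right")
    ax.set_ylabel("validation AUC")
    ax.set_ylim(0.5, min(1.0, curve.aucs.max() + 0.05))
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "parsimony.png"), dpi=150)
    plt.close(fig)


def compare_models(bundles: list[RunBundle], test: CohortTable = None) -> pd.DataFrame:
    """Side-by-side test-set comparison of finished runs.

    All bundles must have been evaluated on the same test split
    (verified via the split checksum recorded at run time).
    """
    if not bundles:
        raise ValueError("no bundles to compare")
    checks = {b.test_split_checksum for b in bundles}
    if len(checks) != 1:
        raise ValueError("bundles were evaluated on different test splits")
    rows = []
    for b in bundles:
        r = b.evaluation
        rows.append({
            "ranking": b.ranking_source,
            "n_variables": len(b.scoring_table.variables),
            "auc": r.auc, "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
            "threshold": r.optimal_threshold, "accuracy": r.accuracy,
            "sensitivity": r.sens_at_threshold, "specificity": r.spec_at_threshold,
            "f1": r.f1,
        })
    return pd.DataFrame(rows)
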