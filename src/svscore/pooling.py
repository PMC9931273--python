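"""Pooling ShapleyVIC values across nearly-optimal models.

Per variable, the M (value, SE) pairs are combined by DerSimonian–Laird
random-effects meta-analysis: the between-model heterogeneity tau^2
captures genuine disagreement among well-performing models, and the 95%
prediction interval (PI) — wider than the confidence interval for the
pooled mean — brackets the importance the variable would carry for a
*new* nearly-optimal model.  A variable is significant when its PI lies
entirely above zero; ranking within each model uses pairwise normal
tests on value differences, competition-ranked by win count, then
averaged across models into the ensemble ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sage import ImportanceMatrix

logger = logging.getLogger(__name__)


class PoolingError(ValueError):
    pass


@dataclass
class PooledImportance:
    """Per-variable pooled importance with heterogeneity and 95% PI."""

    variables: list[str]
    mean: np.ndarray
    tau2: np.ndarray
    se_mean: np.ndarray
    pi_lower: np.ndarray
    pi_upper: np.ndarray
    significant: np.ndarray
    M: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variables, "mean": self.mean, "tau2": self.tau2,
            "se": self.se_mean, "pi_lower": self.pi_lower,
            "pi_upper": self.pi_upper, "significant": self.significant,
        })


def pool_random_effects(imp: ImportanceMatrix) -> PooledImportance:
    """DerSimonian–Laird pooling of each variable's M (mr, sigma) pairs.

    Pooled mean uses inverse-variance weights ``1/(sigma^2 + tau^2)``;
    the 95% PI is ``mean ± t_{0.975, M-2} * sqrt(tau^2 + SE_mean^2)``.
    A variable observed at exactly zero with zero SE in every model
    yields the degenerate PI {0} and is non-significant.
    """
    M, d = imp.M, imp.d
    if M < 2:
        raise PoolingError("pooling needs at least 2 models")
    if not np.isfinite(imp.ses).all():
        raise PoolingError("undefined standard errors")
    y = imp.values
    v = imp.ses**2
    mean = np.empty(d)
    tau2 = np.empty(d)
    se_mean = np.empty(d)
    t_crit = stats.t.ppf(0.975, df=M - 2)
    for j in range(d):
        yj, vj = y[:, j], v[:, j]
        if np.all(vj == 0):
            if np.ptp(yj) == 0:
                # degenerate: identical values, no sampling noise
                mean[j], tau2[j], se_mean[j] = yj[0], 0.0, 0.0
            else:
                tau2[j] = float(np.var(yj, ddof=1))
                mean[j] = float(yj.mean())
                se_mean[j] = float(np.sqrt(tau2[j] / M))
            continue
        vj = np.maximum(vj, 1e-300)
        w = 1.0 / vj
        yw = np.sum(w * yj) / np.sum(w)
        Q = np.sum(w * (yj - yw) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2[j] = max(0.0, (Q - (M - 1)) / c) if c > 0 else 0.0
        w_star = 1.0 / (vj + tau2[j])
        mean[j] = np.sum(w_star * yj) / np.sum(w_star)
        se_mean[j] = np.sqrt(1.0 / np.sum(w_star))
    half = t_crit * np.sqrt(tau2 + se_mean**2)
    lower, upper = mean - half, mean + half
    return PooledImportance(
        variables=list(imp.variables), mean=mean, tau2=tau2, se_mean=se_mean,
        pi_lower=lower, pi_upper=upper, significant=lower > 0, M=M,
    )


def pairwise_wins(mr_row: np.ndarray, se_row: np.ndarray,
                  alpha: float = 0.05) -> np.ndarray:
    """Win counts from all ordered pairwise normal tests within one model.

    Variable j beats k when ``(mr_j - mr_k)/sqrt(se_j^2 + se_k^2)``
    exceeds the two-sided ``z_{1-alpha/2}``; pairs with both SEs zero
    fall back to a strict value comparison.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    mr = np.asarray(mr_row, dtype=float)
    se = np.asarray(se_row, dtype=float)
    z = stats.norm.ppf(1 - alpha / 2)
    diff = mr[:, None] - mr[None, :]
    denom = np.sqrt(se[:, None] ** 2 + se[None, :] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, diff / denom, np.nan)
    wins = np.where(denom > 0, stat > z, diff > 0)
    np.fill_diagonal(wins, False)
    return wins.sum(axis=1).astype(int)


def rank_within_model(wins: np.ndarray) -> np.ndarray:
    """Competition ranking on descending win count.

    Tied variables share the smallest available integer; the next
    distinct count gets ``1 + (number of strictly better variables)``.
    """
    wins = np.asarray(wins)
    return np.array([1 + int((wins > w).sum()) for w in wins], dtype=int)


@dataclass
class EnsembleRanking:
    """Per-model ranks, their averages, and the significance-filtered order."""

    variables: list[str]
    rank_matrix: np.ndarray         # M x d integer ranks
    average_rank: np.ndarray
    ordering: list[str]             # all variables, ascending average rank
    retained: list[str]             # significant variables only, same order

    def to_frame(self) -> pd.DataFrame:
        final = {v: i + 1 for i, v in enumerate(self.ordering)}
        return pd.DataFrame({
            "variable": self.variables,
            "avg_rank": self.average_rank,
            "final_rank": [final[v] for v in self.variables],
            "retained": [v in self.retained for v in self.variables],
        }).sort_values("final_rank").reset_index(drop=True)


def ensemble_rank(imp: ImportanceMatrix, pooled: PooledImportance,
                  alpha: float = 0.05) -> EnsembleRanking:
    """Average the within-model ranks into the ensemble variable ranking.

    The final ordering is ascending in average rank (ties broken by the
    higher pooled mean, then by name); the retained list keeps only the
    variables whose 95% PI lies above zero, in that order.
    """
    if list(pooled.variables) != list(imp.variables):
        raise ValueError("pooled result does not match the importance matrix")
    M, d = imp.M, imp.d
    ranks = np.empty((M, d), dtype=int)
    for m in range(M):
        ranks[m] = rank_within_model(pairwise_wins(imp.values[m], imp.ses[m], alpha))
    avg = ranks.mean(axis=0)
    order = sorted(
        range(d), key=lambda j: (avg[j], -pooled.mean[j], imp.variables[j])
    )
    ordering = [imp.variables[j] for j in order]
    sig = {v for v, s in zip(pooled.variables, pooled.significant) if s}
    return EnsembleRanking(
        variables=list(imp.variables), rank_matrix=ranks, average_rank=avg,
        ordering=ordering, retained=[v for v in ordering if v in sig],
    )


def plot_importance(pooled: PooledImportance, imp: ImportanceMatrix,
                    out_dir: str, formats: tuple[str, ...] = ("png",)) -> list[str]:
    """Bar plot of pooled means with 95% PI whiskers, and a violin plot of
    per-model values colored by loss ratio.

    Non-positive pooled means render as grey bars (unimportance); a
    variable with a zero-length degenerate PI at zero carries no
    information and is omitted from the violin plot with a log notice.
    """
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    order = np.argsort(pooled.mean)[::-1]
    written = []

    fig, ax = plt.subplots(figsize=(7, max(3, 0.35 * len(order))))
    names = [pooled.variables[j] for j in order][::-1]
    means = pooled.mean[order][::-1]
    lo = pooled.pi_lower[order][::-1]
    hi = pooled.pi_upper[order][::-1]
    colors = ["#4878a8" if m > 0 else "#9e9e9e" for m in means]
    ax.barh(names, means, color=colors)
    ax.errorbar(means, np.arange(len(names)), xerr=[means - lo, hi - means],
                fmt="none", ecolor="black", capsize=2, lw=0.8)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("pooled ShapleyVIC value (95% prediction interval)")
    fig.tight_layout()
    for ext in formats:
        p = os.path.join(out_dir, f"importance_bar.{ext}")
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)

    degenerate = [
        pooled.variables[j] for j in range(len(pooled.variables))
        if pooled.pi_lower[j] == pooled.pi_upper[j] == 0
    ]
    for name in degenerate:
        logger.info("variable %r had zero importance in all %d models; "
                    "omitted from violin plot", name, imp.M)
    keep = [j for j in order if pooled.variables[j] not in degenerate]
    fig, ax = plt.subplots(figsize=(max(5, 0.5 * len(keep)), 4.5))
    data = [imp.values[:, j] for j in keep]
    parts = ax.violinplot(data, showextrema=False, widths=0.8)
    cmap = matplotlib.colormaps["viridis"]
    # color each violin by the mean loss ratio of its models weighted by value
    # spread position; simple convention: color by ensemble-average loss ratio
    shade = (imp.loss_ratios - imp.loss_ratios.min()) / max(
        np.ptp(imp.loss_ratios), 1e-12
    )
    for body in parts["bodies"]:
        body.set_facecolor(cmap(float(shade.mean())))
        body.set_alpha(0.7)
    ax.scatter(
        np.repeat(np.arange(1, len(keep) + 1), imp.M),
        np.concatenate(data),
        c=np.tile(imp.loss_ratios, len(keep)), cmap="viridis", s=4, alpha=0.5,
    )
    ax.set_xticks(range(1, len(keep) + 1))
    ax.set_xticklabels([pooled.variables[j] for j in keep], rotation=60, ha="right")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("per-model ShapleyVIC value")
    fig.tight_layout()
    for ext in formats:
        p = os.path.join(out_dir, f"importance_violin.{ext}")
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)
    return written
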