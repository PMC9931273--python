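"""Rejection sampling of nearly-optimal logistic models.

A coefficient vector is "nearly optimal" when its training logistic loss
exceeds the minimum loss by at most a fraction ``eps`` (5% by default).
Candidates are drawn from a multivariate normal centred at the MLE with
covariance ``u * Sigma_hat`` (``Sigma_hat`` the inverse observed
information, intercept sampled jointly with the slopes) and kept iff
their re-evaluated training loss falls inside the band.  The isotropic
multiplier ``u`` is the single exploration knob: small ``u`` hugs the
optimum, large ``u`` probes the band's outer edge at the cost of a lower
acceptance rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable
from .logistic import LogisticModel, design_matrix, mean_logistic_loss

_EPS = np.finfo(float).eps


class SamplerError(RuntimeError):
    """Draw budget exhausted before the ensemble filled."""


class TuningError(ValueError):
    """Scale tuning asked for an empty or invalid loss band."""


@dataclass(frozen=True)
class SamplerConfig:
    M: int = 350
    eps: float = 0.05
    u: float = 1.0
    max_draws: int = None       # default 2000 * M
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M >= 2 required")
        if not self.eps > 0:
            raise TuningError("eps must be positive (the loss band is (1, 1+eps])")
        if not self.u > 0:
            raise ValueError("u must be positive")
        if self.max_draws is None:
            object.__setattr__(self, "max_draws", 2000 * self.M)


@dataclass
class ModelEnsemble:
    """M accepted coefficient vectors with their training losses.

    ``loss_ratio[m] = loss[m] / loss_optimal`` lies in [1, 1+eps] for
    every member (draws tying the optimum are kept).  ``diagnostics``
    records draws attempted, acceptance rate, and the occupancy histogram
    of the loss band's deciles.
    """

    params: np.ndarray          # M x (1+k) packed (intercept, slopes)
    losses: np.ndarray
    loss_ratios: np.ndarray
    optimal: LogisticModel
    config: SamplerConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.params.shape[0]

    def model(self, m: int) -> LogisticModel:
        return self.optimal.with_params(self.params[m])

    def to_frame(self) -> pd.DataFrame:
        cols = ["(intercept)"] + list(self.optimal.encoding.columns)
        df = pd.DataFrame(self.params, columns=cols)
        df.insert(0, "model_id", np.arange(self.M))
        df.insert(1, "loss", self.losses)
        df.insert(2, "loss_ratio", self.loss_ratios)
        return df


def _batch_losses(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Training loss of each packed parameter row (vectorized over draws)."""
    eta = theta[:, 0][None, :] + X @ theta[:, 1:].T    # n x batch
    p = np.clip(expit(eta), _EPS, 1 - _EPS)
    return -np.mean(y[:, None] * np.log(p) + (1 - y)[:, None] * np.log1p(-p), axis=0)


def sample_nearly_optimal(optimal: LogisticModel, train: CohortTable,
                          cfg: SamplerConfig) -> ModelEnsemble:
    """Fill an ensemble of M models inside the ``(1, 1+eps]`` loss band.

    Deterministic given ``cfg.seed``; raises :class:`SamplerError` with
    the observed acceptance rate when ``max_draws`` is exhausted first
    (the usual fix is a smaller ``u``, or :func:`tune_scale`).
    """
    if optimal.covariance is None:
        raise ValueError("optimal model carries no MLE covariance; refit with fit_optimal")
    X, _ = design_matrix(train, optimal.encoding)
    y = train.outcome
    loss_opt = optimal.training_loss
    cutoff = (1.0 + cfg.eps) * loss_opt

    rng = np.random.default_rng(cfg.seed)
    mean = optimal.packed
    cov = cfg.u * optimal.covariance
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(mean)))

    accepted, acc_losses = [], []
    attempted = 0
    batch = max(64, min(4096, 4 * cfg.M))
    while len(accepted) < cfg.M and attempted < cfg.max_draws:
        b = min(batch, cfg.max_draws - attempted)
        draws = mean + rng.standard_normal((b, len(mean))) @ chol.T
        attempted += b
        losses = _batch_losses(draws, X, y)
        ok = losses <= cutoff
        accepted.extend(draws[ok])
        acc_losses.extend(losses[ok])

    n_acc = len(accepted)
    rate = n_acc / attempted if attempted else 0.0
    if n_acc < cfg.M:
        raise SamplerError(
            f"accepted only {n_acc}/{cfg.M} models in {attempted} draws "
            f"(acceptance rate {rate:.2%}); decrease u (current {cfg.u:g}) or raise max_draws"
        )
    params = np.asarray(accepted[: cfg.M])
    losses = np.asarray(acc_losses[: cfg.M])
    ratios = losses / loss_opt
    deciles = np.histogram(ratios, bins=np.linspace(1.0, 1.0 + cfg.eps, 11))[0]
    return ModelEnsemble(
        params=params,
        losses=losses,
        loss_ratios=ratios,
        optimal=optimal,
        config=cfg,
        diagnostics={
            "draws_attempted": attempted,
            "acceptance_rate": rate,
            "band_decile_occupancy": deciles.tolist(),
        },
    )


def _pilot_quintile_occupancy(optimal: LogisticModel, X: np.ndarray, y: np.ndarray,
                              u: float, eps: float, seed: int,
                              pilot: int = 50, max_draws: int = 20000) -> tuple[int, float]:
    rng = np.random.default_rng(seed)
    mean = optimal.packed
    chol = np.linalg.cholesky(u * optimal.covariance + 1e-12 * np.eye(len(mean)))
    cutoff = (1.0 + eps) * optimal.training_loss
    ratios = []
    attempted = 0
    while len(ratios) < pilot and attempted < max_draws:
        draws = mean + rng.standard_normal((500, len(mean))) @ chol.T
        attempted += 500
        losses = _batch_losses(draws, X, y)
        ratios.extend(losses[losses <= cutoff] / optimal.training_loss)
    if not ratios:
        return 0, 0.0
    ratios = np.asarray(ratios[:pilot])
    counts = np.histogram(ratios, bins=np.linspace(1.0, 1.0 + eps, 6))[0]
    return int((counts > 0).sum()), len(ratios) / attempted


def tune_scale(optimal: LogisticModel, train: CohortTable, cfg: SamplerConfig,
               u_grid: np.ndarray = None) -> SamplerConfig:
    """Pick the smallest ``u`` whose pilot sample spans the whole loss band.

    Runs a 50-draw pilot for each candidate ``u`` (ascending, by default
    a geometric grid from 0.25 upward) and returns the first whose
    accepted loss ratios occupy all five quintiles of ``(1, 1+eps]``.
    The search stops early once proposals stop landing in the band at
    all; if no candidate achieves full occupancy, the best found is
    returned with a warning.
    """
    if not cfg.eps > 0:
        raise TuningError("eps must be positive")
    if u_grid is None:
        u_grid = 0.25 * 2.0 ** np.arange(21)
    u_grid = np.sort(np.atleast_1d(np.asarray(u_grid, dtype=float)))
    X, _ = design_matrix(train, optimal.encoding)
    y = train.outcome
    best_u, best_occ = float(u_grid[0]), -1
    dry_streak = 0
    for i, u in enumerate(u_grid):
        occ, _rate = _pilot_quintile_occupancy(
            optimal, X, y, float(u), cfg.eps, seed=cfg.seed + 7919 * (i + 1)
        )
        if occ > best_occ:
            best_u, best_occ = float(u), occ
        if occ == 5:
            return replace(cfg, u=float(u))
        dry_streak = dry_streak + 1 if occ == 0 else 0
        if dry_streak >= 2:
            break
    import warnings

    warnings.warn(
        f"no u in {u_grid.tolist()} occupied all 5 band quintiles; "
        f"best u={best_u:g} covered {best_occ}",
        stacklevel=2,
    )
    return replace(cfg, u=best_u)
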