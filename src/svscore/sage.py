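"""Shapley-based global importance (SAGE) per model, with uncertainty.

Each variable is a player in the cooperative game ``v(S) = L_empty - L_S``,
where ``L_S`` is the mean logistic loss of the model's predictions when
the variables outside ``S`` are marginalized out: the prediction for a
case is averaged over background draws substituted into the unknown
columns (the interventional/marginal convention).  The Shapley value of
this game is the variable's SAGE importance; it is estimated here by
permutation sampling with a Monte-Carlo standard error, and — for small
dimension — computed exactly by full subset enumeration as an oracle.

All dummy columns of one categorical variable act as a single player, so
importance is reported per clinical variable, not per indicator column.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable
from .logistic import LogisticModel, VifReport, design_matrix
from .rashomon import ModelEnsemble

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class SageConfig:
    """Monte-Carlo budgets for the per-model SAGE estimate.

    ``eval_rows`` — number of evaluation cases (the leading rows of the
    supplied evaluation split, by convention the validation set).
    ``background_rows`` — size of the background sample that realises the
    marginal distribution of unknown variables.
    ``n_permutations`` — number of Monte-Carlo iterations; each draws one
    fresh permutation applied to a ``minibatch`` of evaluation cases
    (cases are cycled in reshuffled epochs so all are covered equally).
    The SE of each value scales as 1/sqrt(n_permutations) and reflects
    both permutation and evaluation-case sampling noise.
    """

    eval_rows: int = 3500
    background_rows: int = 512
    n_permutations: int = 256
    minibatch: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.eval_rows, self.background_rows,
               self.n_permutations, self.minibatch) <= 0:
            raise ValueError("all SAGE budgets must be positive")
        if self.background_rows < 2:
            raise ValueError("background sample must have at least 2 rows")


class _LossGame:
    """Marginalized-loss game for one model on fixed eval/background samples.

    Precomputes per-variable linear-predictor contributions so that the
    loss of any coalition costs one ``n_eval x n_background`` expit.
    """

    def __init__(self, model: LogisticModel, eval_data: CohortTable,
                 background: CohortTable):
        Xe, _ = design_matrix(eval_data, model.encoding)
        Xb, _ = design_matrix(background, model.encoding)
        names = eval_data.variable_names
        beta = model.coefficients
        self.E = np.column_stack([
            Xe[:, list(model.encoding.blocks[n])] @ beta[list(model.encoding.blocks[n])]
            for n in names
        ])
        self.C = np.column_stack([
            Xb[:, list(model.encoding.blocks[n])] @ beta[list(model.encoding.blocks[n])]
            for n in names
        ])
        self.y = eval_data.outcome.astype(float)
        self.intercept = model.intercept
        self.d = len(names)
        self.names = names

    def loss(self, in_sum: np.ndarray, out_sum: np.ndarray,
             y: np.ndarray) -> float:
        """Mean loss over cases with case-side contribution ``in_sum`` and
        background-side contribution ``out_sum`` (one per background row);
        the marginalized prediction averages over the background draws."""
        eta = self.intercept + in_sum[:, None] + out_sum[None, :]
        p = expit(eta).mean(axis=1)
        p = np.clip(p, _EPS, 1 - _EPS)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))

    def coalition_loss(self, members: tuple[int, ...]) -> float:
        mask = np.zeros(self.d, dtype=bool)
        mask[list(members)] = True
        return self.loss(self.E[:, mask].sum(axis=1),
                         self.C[:, ~mask].sum(axis=1), self.y)


def _background_sample(eval_data: CohortTable, cfg: SageConfig,
                       rng: np.random.Generator) -> CohortTable:
    n = eval_data.n
    k = min(cfg.background_rows, n)
    idx = rng.choice(n, size=k, replace=False)
    return CohortTable(
        schema=eval_data.schema,
        values=eval_data.values.iloc[idx].reset_index(drop=True),
        outcome=eval_data.outcome[idx],
    )


def sage_values(model: LogisticModel, eval_data: CohortTable, cfg: SageConfig,
                background: CohortTable = None,
                rng: np.random.Generator = None) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling SAGE estimate for one model.

    Returns ``(values, standard_errors)`` aligned with the schema order.
    Each Monte-Carlo iteration draws one random permutation of the
    variables and a minibatch of evaluation cases (cases cycle through
    the evaluation sample in reshuffled epochs, so every case is
    covered equally); the permutation is walked player by player, and a
    variable's increment is the drop in marginalized loss when it
    becomes known.  A variable whose coefficient block is exactly zero
    contributes an exactly-zero increment in every iteration (the
    null-player axiom holds exactly, not just in expectation).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eval_rows = eval_data.head(min(cfg.eval_rows, eval_data.n))
    if background is None:
        background = _background_sample(eval_data, cfg, rng)
    game = _LossGame(model, eval_rows, background)
    d = game.d
    n_eval = game.E.shape[0]
    mb = min(cfg.minibatch, n_eval)
    deltas = np.empty((cfg.n_permutations, d))
    out_full = game.C.sum(axis=1)
    stream: list[int] = []
    for t in range(cfg.n_permutations):
        if len(stream) < mb:
            stream.extend(rng.permutation(n_eval).tolist())
        idx = np.asarray(stream[:mb])
        del stream[:mb]
        E_mb, y_mb = game.E[idx], game.y[idx]
        order = rng.permutation(d)
        in_sum = np.zeros(mb)
        out_sum = out_full.copy()
        loss_prev = game.loss(in_sum, out_sum, y_mb)
        for j in order:
            ej, cj = E_mb[:, j], game.C[:, j]
            if not (ej.any() or cj.any()):
                deltas[t, j] = 0.0      # null player: predictions unchanged
                continue
            in_sum = in_sum + ej
            out_sum = out_sum - cj
            loss_new = game.loss(in_sum, out_sum, y_mb)
            deltas[t, j] = loss_prev - loss_new
            loss_prev = loss_new
    values = deltas.mean(axis=0)
    ses = deltas.std(axis=0, ddof=1) / np.sqrt(cfg.n_permutations)
    return values, ses


def exact_shapley(model: LogisticModel, eval_data: CohortTable,
                  background: CohortTable) -> np.ndarray:
    """Exact Shapley values of the marginalized-loss game by 2^d enumeration.

    Only feasible for d <= 10; serves as the independent oracle for the
    permutation estimator.  Satisfies efficiency exactly:
    ``sum_j value_j == L_empty - L_full``.
    """
    d = eval_data.d
    if d > 10:
        raise ValueError(f"exact enumeration refused for d={d} > 10")
    game = _LossGame(model, eval_data, background)
    losses = {}
    players = tuple(range(d))
    for size in range(d + 1):
        for S in combinations(players, size):
            losses[S] = game.coalition_loss(S)
    values = np.zeros(d)
    for j in players:
        others = tuple(p for p in players if p != j)
        for size in range(d):
            w = factorial(size) * factorial(d - size - 1) / factorial(d)
            for S in combinations(others, size):
                Sj = tuple(sorted(S + (j,)))
                values[j] += w * (losses[S] - losses[Sj])
    return values


def model_reliance(values: np.ndarray, ses: np.ndarray,
                   vif: VifReport, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Collinearity-adjusted model reliance: |SAGE| for VIF-flagged variables.

    Variables whose generalized VIF comparable score exceeds 2 take the
    absolute SAGE value (collinearity can push a genuinely used
    variable's raw SAGE value negative); all others keep the signed
    value.  Standard errors are unchanged.
    """
    flags = vif.flags(names)
    mr = np.where(flags, np.abs(values), values)
    return mr, np.asarray(ses, dtype=float)


@dataclass
class ImportanceMatrix:
    """M x d ShapleyVIC values and standard errors for a model ensemble."""

    values: np.ndarray          # M x d model-reliance values (mr)
    ses: np.ndarray             # M x d standard errors (sigma)
    variables: list[str]
    abs_flagged: np.ndarray     # d bool, VIF>2 gate
    loss_ratios: np.ndarray     # M, carried from the ensemble

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format: (model_id, variable, value, se, abs_flagged, loss_ratio)."""
        rows = []
        for m in range(self.M):
            for j, v in enumerate(self.variables):
                rows.append((m, v, self.values[m, j], self.ses[m, j],
                             bool(self.abs_flagged[j]), self.loss_ratios[m]))
        return pd.DataFrame(
            rows, columns=["model_id", "variable", "value", "se",
                           "abs_flagged", "loss_ratio"],
        )


def ensemble_importance(ensemble: ModelEnsemble, eval_data: CohortTable,
                        vif: VifReport, cfg: SageConfig,
                        background_data: CohortTable = None) -> ImportanceMatrix:
    """SAGE values + collinearity adjustment for every ensemble member.

    Per-model seeds are derived from ``cfg.seed`` and a hash of the
    model's own coefficient vector, so results depend on neither
    execution order nor ensemble position (identical members yield
    identical rows); the background sample is drawn once (from
    ``cfg.seed``) out of ``background_data`` — conventionally the
    training split, the models' reference distribution; the evaluation
    data when omitted — and shared by all models so their games are
    identical and poolable.
    """
    if ensemble.M == 0:
        raise ValueError("empty ensemble")
    names = eval_data.variable_names
    eval_rows = eval_data.head(min(cfg.eval_rows, eval_data.n))
    background = _background_sample(
        background_data if background_data is not None else eval_data,
        cfg, np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB6)))
    )
    M, d = ensemble.M, len(names)
    values = np.empty((M, d))
    ses = np.empty((M, d))
    for m in range(M):
        digest = hashlib.sha256(
            np.ascontiguousarray(ensemble.params[m]).tobytes()).digest()
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, int.from_bytes(digest[:4], "big"))))
        try:
            v, s = sage_values(ensemble.model(m), eval_rows, cfg,
                               background=background, rng=rng)
        except Exception as exc:
            raise RuntimeError(f"SAGE failed for model_id={m}: {exc}") from exc
        values[m], ses[m] = model_reliance(v, s, vif, names)
    return ImportanceMatrix(
        values=values, ses=ses, variables=names,
        abs_flagged=vif.flags(names), loss_ratios=ensemble.loss_ratios.copy(),
    )
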