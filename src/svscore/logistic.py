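"""Optimal logistic model, logistic loss, and collinearity diagnostics.

The "optimal" model is the plain maximum-likelihood logistic regression
on all candidate predictors; its per-observation mean negative
log-likelihood is the reference loss for the nearly-optimal (Rashomon)
band, and its generalized variance inflation factors gate the
absolute-SAGE rule for collinear variables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import CohortTable, VariableSchema

_GRAD_TOL = 1e-8
_EPS = np.finfo(float).eps


class FitError(RuntimeError):
    """Separation, singular design, or non-convergence."""


class DiagnosticsError(RuntimeError):
    """Collinearity diagnostics cannot be computed."""


@dataclass(frozen=True)
class DesignEncoding:
    """Dummy encoding of the schema: variable -> block of design columns.

    Each categorical variable with L levels yields L-1 indicator columns
    against its first declared level as reference; continuous and binary
    variables map to a single column.  Column 0 of the full design is the
    intercept; ``blocks`` index into the slope columns only.
    """

    columns: tuple[str, ...]                  # slope column names, in order
    blocks: dict                              # variable name -> tuple of column indices
    reference_levels: dict                    # categorical variable -> reference level

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def dof(self, variable: str) -> int:
        return len(self.blocks[variable])


def build_encoding(schema: list[VariableSchema]) -> DesignEncoding:
    columns: list[str] = []
    blocks: dict = {}
    refs: dict = {}
    for s in schema:
        start = len(columns)
        if s.vtype == "categorical":
            refs[s.name] = s.levels[0]
            columns.extend(f"{s.name}[{lev}]" for lev in s.levels[1:])
        else:
            columns.append(s.name)
        blocks[s.name] = tuple(range(start, len(columns)))
    return DesignEncoding(columns=tuple(columns), blocks=blocks, reference_levels=refs)


def design_matrix(table: CohortTable, encoding: DesignEncoding = None) -> tuple[np.ndarray, DesignEncoding]:
    """Dummy-encoded slope design (no intercept column)."""
    if encoding is None:
        encoding = build_encoding(table.schema)
    cols = []
    for s in table.schema:
        x = table.values[s.name]
        if s.vtype == "categorical":
            for lev in s.levels[1:]:
                cols.append((x == lev).to_numpy(dtype=float))
        else:
            v = x.to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"missing values in {s.name!r}; impute first")
            cols.append(v)
    X = np.column_stack(cols) if cols else np.empty((table.n, 0))
    return X, encoding


@dataclass
class LogisticModel:
    """Intercept + slope vector over a :class:`DesignEncoding`."""

    intercept: float
    coefficients: np.ndarray
    encoding: DesignEncoding
    training_loss: float = np.nan
    covariance: np.ndarray = None       # MLE covariance of (intercept, slopes)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.encoding.n_columns,):
            raise ValueError("coefficient vector does not match encoding")
        if not np.isfinite(self.coefficients).all() or not np.isfinite(self.intercept):
            raise ValueError("non-finite coefficients")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coefficients

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        X, _ = design_matrix(table, self.encoding)
        return expit(self.linear_predictor(X))

    def with_params(self, theta: np.ndarray) -> "LogisticModel":
        """New model from a packed (intercept, slopes) vector; loss unset."""
        return LogisticModel(
            intercept=float(theta[0]), coefficients=theta[1:],
            encoding=self.encoding, covariance=self.covariance,
        )

    @property
    def packed(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coefficients])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficients": dict(zip(self.encoding.columns, self.coefficients)),
                    "reference_levels": self.encoding.reference_levels,
                    "training_loss": self.training_loss,
                },
                fh,
                indent=2,
            )


def mean_logistic_loss(eta: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood in nats; probabilities clipped off {0,1}."""
    p = np.clip(expit(eta), _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def logistic_loss(model: LogisticModel, data: CohortTable) -> float:
    """Mean logistic loss of ``model`` on ``data`` (nats per observation)."""
    X, _ = design_matrix(data, model.encoding)
    return mean_logistic_loss(model.linear_predictor(X), data.outcome)


def fit_optimal(train: CohortTable) -> LogisticModel:
    """Maximum-likelihood logistic fit on all candidate predictors.

    Deterministic Newton fit; raises :class:`FitError` on separation or a
    rank-deficient design, naming the offending columns where possible.
    """
    X, encoding = design_matrix(train)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify dependent columns via QR pivoting on the slope design
        _, r = np.linalg.qr(Xc)
        diag = np.abs(np.diag(r))
        bad = [
            (["(intercept)"] + list(encoding.columns))[i]
            for i in np.flatnonzero(diag < 1e-8 * diag.max())
        ]
        raise FitError(f"design matrix is rank-deficient; dependent columns near {bad}")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(train.outcome, Xc).fit(disp=0, maxiter=200, method="newton",
                                                  tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
        raise FitError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    grad = np.asarray(res.model.score(params), dtype=float) / train.n
    if not np.all(np.abs(grad) < 1e-4) or np.abs(params).max() > 1e3:
        big = [(["(intercept)"] + list(encoding.columns))[i]
               for i in np.flatnonzero(np.abs(params) > 1e3)]
        raise FitError(
            f"fit did not converge (max |grad|={np.abs(grad).max():.2e}); "
            f"possible separation in columns {big or 'unknown'}"
        )
    model = LogisticModel(
        intercept=float(params[0]),
        coefficients=params[1:],
        encoding=encoding,
        covariance=np.asarray(res.cov_params(), dtype=float),
    )
    model.training_loss = logistic_loss(model, train)
    return model


@dataclass(frozen=True)
class VifReport:
    """Generalized VIFs per variable with the Fox–Monette comparable score.

    ``comparable`` is (GVIF^(1/(2 df)))^2, which reduces to the classical
    VIF for single-column variables and puts multi-level categoricals on
    the same scale; ``flagged`` marks comparable score > 2, the gate for
    the absolute-SAGE model-reliance rule.
    """

    gvif: dict
    dof: dict
    comparable: dict
    flagged: dict

    def flags(self, names: list[str]) -> np.ndarray:
        return np.array([self.flagged[n] for n in names], dtype=bool)


def generalized_vif(train: CohortTable) -> VifReport:
    """Determinant-ratio GVIF on the dummy-encoded, centred design."""
    if train.d < 2:
        raise DiagnosticsError("VIF needs at least two variables")
    X, encoding = design_matrix(train)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if (sd == 0).any():
        const = [encoding.columns[i] for i in np.flatnonzero(sd == 0)]
        raise DiagnosticsError(f"constant design columns: {const}")
    R = np.corrcoef(Xc, rowvar=False)
    det_R = np.linalg.det(R)
    if det_R <= 0:
        raise DiagnosticsError("singular predictor correlation matrix")
    gvif, dof, comparable, flagged = {}, {}, {}, {}
    for s in train.schema:
        idx = np.asarray(encoding.blocks[s.name], dtype=int)
        rest = np.setdiff1d(np.arange(X.shape[1]), idx)
        det_block = np.linalg.det(R[np.ix_(idx, idx)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)]) if len(rest) else 1.0
        g = det_block * det_rest / det_R
        df = len(idx)
        comp = g ** (1.0 / df)        # == (GVIF^(1/(2 df)))^2
        gvif[s.name] = float(g)
        dof[s.name] = df
        comparable[s.name] = float(comp)
        flagged[s.name] = bool(comp > 2)
    return VifReport(gvif=gvif, dof=dof, comparable=comparable, flagged=flagged)
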