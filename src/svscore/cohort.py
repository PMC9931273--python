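"""Typed cohort tables: loading, validation, splitting and imputation.

A cohort is a flat table of patient encounters with one binary outcome
column and a declared schema of candidate predictors (continuous,
binary, or categorical with ordered levels).  Every downstream stage —
model fitting, Rashomon sampling, Shapley importance, score building —
consumes the :class:`CohortTable` produced here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

VTYPES = ("continuous", "binary", "categorical")
SPLITS = ("train", "validation", "test")


class SchemaError(ValueError):
    """Schema declaration or schema/file mismatch."""


class DataError(ValueError):
    """Values violate the declared schema (e.g. non-binary outcome)."""


class SplitError(ValueError):
    """A requested split is degenerate."""


class ImputationError(ValueError):
    """Training split carries no information to impute from."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one candidate predictor.

    Parameters
    ----------
    name : str
        Column name in the input table.
    vtype : {"continuous", "binary", "categorical"}
        Variable type.  Binary variables must be coded {0, 1};
        categorical variables take values from ``levels``.
    levels : tuple of str, optional
        Ordered category labels (categorical only, at least two).
    unit : str, optional
        Free-text unit annotation (e.g. ``"mmol/L"``).
    """

    name: str
    vtype: str
    levels: tuple[str, ...] = ()
    unit: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise SchemaError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.vtype == "categorical":
            if len(self.levels) < 2:
                raise SchemaError(f"categorical {self.name!r} needs >=2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"duplicate levels for {self.name!r}")
        elif self.levels:
            raise SchemaError(f"levels given for non-categorical {self.name!r}")
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))


def schema_from_config(path_or_list) -> list[VariableSchema]:
    """Read a variable schema from a YAML/JSON config file or a list of dicts."""
    if isinstance(path_or_list, (str,)):
        with open(path_or_list) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = path_or_list
    if isinstance(raw, dict):
        raw = raw.get("variables", raw)
    out = []
    for item in raw:
        out.append(
            VariableSchema(
                name=item["name"],
                vtype=item["vtype"],
                levels=tuple(item.get("levels", ()) or ()),
                unit=item.get("unit", ""),
            )
        )
    names = [s.name for s in out]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")
    return out


@dataclass
class CohortTable:
    """Typed encounter-level predictor matrix with a binary outcome.

    Attributes
    ----------
    schema : list of VariableSchema
    values : pandas.DataFrame
        One column per schema variable, in schema order.
    outcome : numpy.ndarray
        Binary {0, 1} vector aligned with ``values`` rows.
    split_label : pandas.Series
        Per-row label in {"train", "validation", "test", "unassigned"}.
    imputation_medians : dict
        Training-split medians recorded by :func:`impute_training_median`,
        for reuse on new data.
    """

    schema: list[VariableSchema]
    values: pd.DataFrame
    outcome: np.ndarray
    split_label: pd.Series = None
    imputation_medians: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise SchemaError(f"columns absent from table: {missing}")
        self.values = self.values[names].reset_index(drop=True)
        self.outcome = np.asarray(self.outcome)
        if not np.isin(self.outcome, [0, 1]).all():
            raise DataError("outcome must be coded {0,1}")
        self.outcome = self.outcome.astype(np.int64)
        if len(self.outcome) != len(self.values):
            raise DataError("outcome length does not match table")
        if self.split_label is None:
            self.split_label = pd.Series(["unassigned"] * len(self.values))
        self.split_label = pd.Series(self.split_label).reset_index(drop=True)
        for s in self.schema:
            col = self.values[s.name]
            if s.vtype == "binary":
                ok = col.dropna().isin([0, 1]).all()
                if not ok or col.isna().any():
                    raise DataError(f"binary variable {s.name!r} must be coded {{0,1}} with no missing")
            elif s.vtype == "categorical":
                if col.isna().any():
                    raise DataError(f"missing values in categorical {s.name!r} are not imputable")
                bad = ~col.astype(str).isin(s.levels)
                if bad.any():
                    raise DataError(f"undeclared levels in {s.name!r}: {sorted(col[bad].unique())}")
                self.values[s.name] = col.astype(str)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def d(self) -> int:
        return len(self.schema)

    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def subset(self, split: str) -> "CohortTable":
        """Return the rows carrying the given split label, as a new table."""
        mask = (self.split_label == split).to_numpy()
        return CohortTable(
            schema=self.schema,
            values=self.values.loc[mask].reset_index(drop=True),
            outcome=self.outcome[mask],
            split_label=self.split_label[mask].reset_index(drop=True),
            imputation_medians=dict(self.imputation_medians),
        )

    def head(self, k: int) -> "CohortTable":
        """Leading ``k`` rows, preserving order (used for the SAGE evaluation sample)."""
        return CohortTable(
            schema=self.schema,
            values=self.values.iloc[:k].reset_index(drop=True),
            outcome=self.outcome[:k],
            split_label=self.split_label.iloc[:k].reset_index(drop=True),
            imputation_medians=dict(self.imputation_medians),
        )

    def write_split_sidecar(self, path: str) -> None:
        pd.DataFrame({"row_id": np.arange(self.n), "split": self.split_label}).to_csv(
            path, index=False
        )


def load_cohort(path: str, schema: list[VariableSchema], outcome_col: str = "outcome",
                sep: str = None) -> tuple[CohortTable, pd.DataFrame]:
    """Load a delimited cohort file against a declared schema.

    Rows whose categorical values fall outside the declared levels are
    rejected (not silently coerced); the rejection report lists them.

    Returns
    -------
    (CohortTable, DataFrame)
        The typed table and a rejection report with columns
        ``(row, variable, value)`` — empty when every row parses.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    names = [s.name for s in schema]
    missing = [c for c in names + [outcome_col] if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path} lacks columns {missing}")
    rejects = []
    keep = np.ones(len(df), dtype=bool)
    for s in schema:
        if s.vtype == "categorical":
            col = df[s.name].astype(str)
            bad = ~col.isin(s.levels)
            for i in np.flatnonzero(bad.to_numpy()):
                rejects.append({"row": int(i), "variable": s.name, "value": col.iloc[i]})
            keep &= ~bad.to_numpy()
    report = pd.DataFrame(rejects, columns=["row", "variable", "value"])
    df = df.loc[keep].reset_index(drop=True)
    outcome = pd.to_numeric(df[outcome_col], errors="raise").to_numpy()
    if not np.isin(outcome[~np.isnan(outcome.astype(float))], [0, 1]).all():
        raise DataError(f"outcome column {outcome_col!r} contains non-binary values")
    table = CohortTable(schema=schema, values=df[names], outcome=outcome)
    return table, report


def split_cohort(table: CohortTable, fractions=(0.7, 0.1, 0.2), seed: int = 0,
                 stratify: bool = False) -> CohortTable:
    """Randomly partition the cohort into train / validation / test.

    Sizes are the rounded targets: train gets ``floor(n*f1)``, validation
    ``floor(n*f2)``, test the remainder, so the three labels always
    partition the table exactly.  Simple (unstratified) random sampling
    by default; ``stratify=True`` splits within each outcome class.
    """
    f = np.asarray(fractions, dtype=float)
    if len(f) != 3 or (f <= 0).any() or abs(f.sum() - 1) > 1e-9:
        raise SplitError("fractions must be three positive numbers summing to 1")
    rng = np.random.default_rng(seed)
    labels = np.empty(table.n, dtype=object)

    def assign(idx: np.ndarray) -> None:
        perm = rng.permutation(idx)
        n = len(perm)
        n_tr, n_va = int(np.floor(n * f[0])), int(np.floor(n * f[1]))
        labels[perm[:n_tr]] = "train"
        labels[perm[n_tr:n_tr + n_va]] = "validation"
        labels[perm[n_tr + n_va:]] = "test"

    if stratify:
        for y in (0, 1):
            assign(np.flatnonzero(table.outcome == y))
    else:
        assign(np.arange(table.n))

    for split in SPLITS:
        pos = int(table.outcome[labels == split].sum())
        if (labels == split).sum() == 0 or pos < 2:
            raise SplitError(
                f"{split} split would contain {pos} outcome-positive rows (<2)"
            )
    return CohortTable(
        schema=table.schema,
        values=table.values,
        outcome=table.outcome,
        split_label=pd.Series(labels),
        imputation_medians=dict(table.imputation_medians),
    )


def impute_training_median(table: CohortTable) -> CohortTable:
    """Replace missing continuous values with the training-split median.

    The median is computed on the training rows only and applied to all
    three splits; an even number of training values uses the mean of the
    two middle order statistics.  Medians are recorded on the returned
    table for reuse on new data.  Missing categorical or binary values
    are a schema violation upstream, never imputed.
    """
    if set(table.split_label.unique()) - {"train", "validation", "test"}:
        raise ImputationError("split labels must be assigned before imputation")
    values = table.values.copy()
    medians = {}
    train_mask = (table.split_label == "train").to_numpy()
    for s in table.schema:
        if s.vtype != "continuous":
            continue
        col = values[s.name].astype(float)
        if not col.isna().any():
            continue
        train_vals = col[train_mask].dropna()
        if train_vals.empty:
            raise ImputationError(f"continuous {s.name!r} entirely missing in training")
        med = float(train_vals.median())
        medians[s.name] = med
        values[s.name] = col.fillna(med)
    return CohortTable(
        schema=table.schema,
        values=values,
        outcome=table.outcome,
        split_label=table.split_label,
        imputation_medians={**table.imputation_medians, **medians},
    )


def apply_recorded_medians(table: CohortTable, medians: dict) -> CohortTable:
    """Impute new data with medians recorded from a development cohort."""
    values = table.values.copy()
    for name, med in medians.items():
        if name in values.columns:
            values[name] = values[name].astype(float).fillna(med)
    return CohortTable(
        schema=table.schema, values=values, outcome=table.outcome,
        split_label=table.split_label, imputation_medians=dict(medians),
    )
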