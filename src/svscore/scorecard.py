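"""Integer-point scorecards from a ranked variable list.

The construction follows the standard scorecard recipe for binary
outcomes: categorize continuous variables (training quantiles or 1-D
k-means), fit a logistic regression on the categorized design, shift
each variable's category coefficients so its smallest is 0, scale all
variables by a single global factor so the maximum attainable total
equals a configured cap (100 by default), and round to nonnegative
integers with a largest-remainder repair so the cap is hit exactly.
A patient's risk score is the sum of the points matching their values;
intervals follow the "[A, B)" convention (closed below, open above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, VariableSchema
from .logistic import FitError
from .metrics import auc


class CategorizationError(ValueError):
    pass


@dataclass
class CutVector:
    """Interior cut points per continuous variable; level order per categorical.

    ``cuts[name]`` is a strictly increasing list; with cuts (c1..ck) the
    variable is binned into ``(-inf, c1), [c1, c2), ..., [ck, inf)``.
    """

    cuts: dict = field(default_factory=dict)        # name -> list of floats
    level_order: dict = field(default_factory=dict)  # name -> tuple of levels

    def __post_init__(self) -> None:
        for name, c in self.cuts.items():
            c = [float(x) for x in c]
            if any(b <= a for a, b in zip(c, c[1:])):
                raise CategorizationError(f"cuts for {name!r} must be strictly increasing")
            self.cuts[name] = c


def _interval_label(lo: float, hi: float) -> str:
    if np.isneginf(lo):
        return f"<{hi:g}"
    if np.isposinf(hi):
        return f">={lo:g}"
    return f"[{lo:g}, {hi:g})"


@dataclass
class ScoreRow:
    variable: str
    label: str
    lower: float = np.nan       # continuous intervals only
    upper: float = np.nan
    levels: tuple = ()          # categorical: the levels mapping to this row
    points: int = 0


@dataclass
class ScoringTable:
    """Interval/level -> integer-point map, the deliverable risk score.

    Invariants: every variable has a 0-point category, all points are
    nonnegative integers, and the maximum attainable total equals the
    configured cap exactly.
    """

    variables: list[str]
    rows: list[ScoreRow]
    cap: int
    provenance: dict = field(default_factory=dict)

    def rows_for(self, variable: str) -> list[ScoreRow]:
        return [r for r in self.rows if r.variable == variable]

    @property
    def max_total(self) -> int:
        return sum(
            max((r.points for r in self.rows_for(v)), default=0) for v in self.variables
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"variable": r.variable, "interval_lower": r.lower,
             "interval_upper": r.upper, "level": "/".join(r.levels),
             "label": r.label, "points": r.points}
            for r in self.rows
        ])

    def to_markdown(self) -> str:
        lines = ["| Variable | Interval | Points |", "| --- | --- | --- |"]
        for v in self.variables:
            for i, r in enumerate(self.rows_for(v)):
                lines.append(f"| {v if i == 0 else ''} | {r.label} | {r.points} |")
        return "\n".join(lines)


def _encode_rf(table: CohortTable) -> np.ndarray:
    cols = []
    for s in table.schema:
        x = table.values[s.name]
        if s.vtype == "categorical":
            lut = {lev: i for i, lev in enumerate(s.levels)}
            cols.append(x.map(lut).to_numpy(dtype=float))
        else:
            cols.append(x.to_numpy(dtype=float))
    return np.column_stack(cols)


def rank_by_random_forest(train: CohortTable, n_trees: int = 100,
                          seed: int = 0) -> list[str]:
    """Impurity-decrease variable ranking from a random forest classifier.

    Fits on the raw (uncategorized) variables, categorical levels coded
    by their declared order; returns variable names in descending
    importance.  Deterministic given the seed.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = _encode_rf(train)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, train.outcome)
    order = np.argsort(rf.feature_importances_)[::-1]
    return [train.schema[i].name for i in order]


DEFAULT_QUANTILES = (0.05, 0.2, 0.8, 0.95)


def derive_cuts(train: CohortTable, variables: list[str],
                method: str = "quantile", quantiles=DEFAULT_QUANTILES,
                k: int = 5, seed: int = 0) -> CutVector:
    """Automatic categorization cuts for the continuous variables in ``variables``.

    ``quantile``: interior cuts at the stated training quantiles
    (default 5th/20th/80th/95th percentiles, giving five bins);
    ``kmeans``: 1-D k-means on the training values, cuts at midpoints
    between sorted cluster centers.  Duplicate cuts are collapsed.
    """
    schema = {s.name: s for s in train.schema}
    cv = CutVector()
    for name in variables:
        s = schema[name]
        if s.vtype == "categorical":
            cv.level_order[name] = s.levels
            continue
        if s.vtype == "binary":
            continue
        x = train.values[name].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise CategorizationError(f"variable {name!r} has <2 distinct values")
        if method == "quantile":
            q = np.asarray(quantiles, dtype=float)
            if not ((q > 0).all() and (q < 1).all() and (np.diff(q) > 0).all()):
                raise CategorizationError("quantiles must be increasing in (0,1)")
            cuts = np.quantile(x, q)
        elif method == "kmeans":
            from sklearn.cluster import KMeans

            if k < 2:
                raise CategorizationError("k-means needs k >= 2")
            km = KMeans(n_clusters=min(k, len(np.unique(x))), n_init=10,
                        random_state=seed).fit(x.reshape(-1, 1))
            centers = np.sort(km.cluster_centers_.ravel())
            cuts = (centers[:-1] + centers[1:]) / 2
        else:
            raise CategorizationError(f"unknown categorization method {method!r}")
        cuts = np.unique(cuts)
        cv.cuts[name] = [float(c) for c in cuts]
    return cv


def _categories(schema: VariableSchema, cuts: CutVector):
    """List of (label, matcher-metadata) categories for one variable."""
    if schema.vtype == "categorical":
        order = cuts.level_order.get(schema.name, schema.levels)
        return [("level", (lev,), lev) for lev in order]
    if schema.vtype == "binary":
        return [("level", ("0",), "No"), ("level", ("1",), "Yes")]
    c = cuts.cuts.get(schema.name, [])
    edges = [-np.inf] + list(c) + [np.inf]
    return [("interval", (edges[i], edges[i + 1]),
             _interval_label(edges[i], edges[i + 1]))
            for i in range(len(edges) - 1)]


def _category_codes(x: pd.Series, schema: VariableSchema, cats) -> np.ndarray:
    if schema.vtype == "categorical":
        lut = {}
        for i, (_, levels, _) in enumerate(cats):
            for lev in levels:
                lut[lev] = i
        return x.map(lut).to_numpy()
    if schema.vtype == "binary":
        return x.to_numpy(dtype=int)
    edges = np.array([c[1][0] for c in cats[1:]])
    return np.searchsorted(edges, x.to_numpy(dtype=float), side="right")


def _merge_empty(cats, codes: np.ndarray, name: str):
    """Merge training-empty categories into the adjacent lower one."""
    while True:
        counts = np.bincount(codes, minlength=len(cats))
        empty = np.flatnonzero(counts == 0)
        if len(empty) == 0 or len(cats) == 1:
            return cats, codes
        i = int(empty[0])
        j = i - 1 if i > 0 else 1
        lo, hi = min(i, j), max(i, j)
        a, b = cats[lo], cats[hi]
        if a[0] == "interval":
            merged = ("interval", (a[1][0], b[1][1]),
                      _interval_label(a[1][0], b[1][1]))
        else:
            merged = ("level", a[1] + b[1], f"{a[2]}/{b[2]}")
        warnings.warn(
            f"category {cats[i][2]!r} of {name!r} is empty in training; "
            f"merged with its neighbour", stacklevel=3,
        )
        cats = cats[:lo] + [merged] + cats[hi + 1:]
        codes = np.where(codes >= hi, codes - 1, codes)


def _categorized_design(table: CohortTable, variables: list[str], cuts: CutVector,
                        cats_by_var: dict = None):
    """Dummy design over categorized variables; first category is reference.

    When ``cats_by_var`` is None (training), categories empty in training
    are merged into their lower neighbour and the final category lists
    are returned for reuse on validation/test data.
    """
    schema = {s.name: s for s in table.schema}
    fit_mode = cats_by_var is None
    if fit_mode:
        cats_by_var = {}
    blocks, names = [], []
    codes_by_var = {}
    for name in variables:
        s = schema[name]
        if fit_mode:
            cats = _categories(s, cuts)
            codes = _category_codes(table.values[name], s, cats)
            cats, codes = _merge_empty(cats, codes, name)
            cats_by_var[name] = cats
        else:
            cats = cats_by_var[name]
            codes = _recode(table.values[name], s, cats)
        codes_by_var[name] = codes
        for i in range(1, len(cats)):
            blocks.append((codes == i).astype(float))
            names.append((name, i))
    X = np.column_stack(blocks) if blocks else np.empty((table.n, 0))
    return X, names, cats_by_var, codes_by_var


def _recode(x: pd.Series, schema: VariableSchema, cats) -> np.ndarray:
    if cats[0][0] == "level":
        if schema.vtype == "binary":
            vals = pd.Series(x).astype(float).astype(int).astype(str)
        else:
            vals = x.astype(str)
        lut = {}
        for i, (_, levels, _) in enumerate(cats):
            for lev in levels:
                lut[str(lev)] = i
        codes = vals.map(lut)
        if codes.isna().any():
            bad = sorted(vals[codes.isna()].unique())
            raise CategorizationError(f"values {bad} of {schema.name!r} match no category")
        return codes.to_numpy(dtype=int)
    edges = np.array([c[1][0] for c in cats[1:]])
    return np.searchsorted(edges, x.to_numpy(dtype=float), side="right")


def scale_round_points(shifted: dict, cap: int, order: list[str] = None
                       ) -> tuple[dict, float]:
    """Scale shifted per-category coefficients to integer points summing to cap.

    ``shifted`` maps variable -> nonnegative coefficient vector whose
    minimum is 0.  One global factor scales the summed per-variable
    maxima to ``cap``; each variable's maximum is then integerized by
    largest remainder so the maxima sum to ``cap`` exactly, and the
    remaining categories are rounded to the nearest integer (clipped to
    the variable's maximum).  Returns the integer points per variable
    and the scale factor.
    """
    if order is None:
        order = list(shifted)
    maxima = np.array([float(np.max(shifted[v])) for v in order])
    total = maxima.sum()
    if total <= 0:
        raise FitError("no variable carries any effect; cannot scale points")
    factor = cap / total
    scaled_max = maxima * factor
    int_max = np.floor(scaled_max).astype(int)
    remainder = scaled_max - int_max
    deficit = cap - int_max.sum()
    for j in np.argsort(remainder)[::-1][: int(round(deficit))]:
        int_max[j] += 1
    out = {}
    for v_idx, name in enumerate(order):
        c = np.asarray(shifted[name], dtype=float) * factor
        pts = np.rint(c).astype(int)
        pts[int(np.argmax(shifted[name]))] = int_max[v_idx]
        out[name] = np.clip(pts, 0, int_max[v_idx])
    return out, factor


def assign_points(train: CohortTable, variables: list[str], cuts: CutVector,
                  cap: int = 100) -> ScoringTable:
    """Fit, shift, scale and round the categorized logistic model into points.

    Within each variable the minimum category coefficient is subtracted
    (so its reference row scores 0); one global factor scales the summed
    per-variable maxima to ``cap``; rounding drift on the maxima is
    repaired by largest remainder so the maximum attainable total is
    exactly ``cap``.
    """
    if not variables:
        return ScoringTable(variables=[], rows=[], cap=cap)
    X, names, cats_by_var, _ = _categorized_design(train, variables, cuts)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(train.outcome, Xc).fit(disp=0, maxiter=200, method="newton")
    except Exception as exc:
        raise FitError(f"categorized refit failed: {exc}") from exc
    beta = np.asarray(res.params)[1:]
    if not np.isfinite(beta).all() or np.abs(beta).max(initial=0) > 50:
        raise FitError("categorized refit shows separation (diverging coefficients)")

    coef_by_var = {}
    for name in variables:
        n_cat = len(cats_by_var[name])
        c = np.zeros(n_cat)
        for col, (vname, i) in enumerate(names):
            if vname == name:
                c[i] = beta[col]
        coef_by_var[name] = c - c.min()

    points_by_var, factor = scale_round_points(coef_by_var, cap,
                                               order=list(variables))

    rows = []
    for name in variables:
        pts = points_by_var[name]
        for (kind, meta, label), p in zip(cats_by_var[name], pts):
            if kind == "interval":
                rows.append(ScoreRow(variable=name, label=label,
                                     lower=meta[0], upper=meta[1], points=int(p)))
            else:
                rows.append(ScoreRow(variable=name, label=label,
                                     levels=tuple(str(m) for m in meta), points=int(p)))
    return ScoringTable(
        variables=list(variables), rows=rows, cap=cap,
        provenance={
            "cuts": {v: cuts.cuts.get(v, []) for v in variables},
            "refit_coefficients": {v: coef_by_var[v].tolist() for v in variables},
            "scale_factor": factor,
        },
    )


def compute_score(table: ScoringTable, patient: dict) -> int:
    """Total integer score: sum of matched interval/level points."""
    total = 0
    for v in table.variables:
        if v not in patient:
            raise KeyError(f"patient record lacks variable {v!r}")
        val = patient[v]
        rows = table.rows_for(v)
        candidates = {str(val)}
        try:
            candidates.add(str(int(float(val))))
        except (TypeError, ValueError):
            pass
        matched = None
        for r in rows:
            if r.levels:
                if candidates & set(r.levels):
                    matched = r
                    break
            else:
                lo = -np.inf if np.isnan(r.lower) else r.lower
                hi = np.inf if np.isnan(r.upper) else r.upper
                if lo <= float(val) < hi:
                    matched = r
                    break
        if matched is None:
            raise RuntimeError(f"value {val!r} of {v!r} matched no scorecard row")
        total += matched.points
    return total


def score_cohort(table: ScoringTable, cohort: CohortTable) -> np.ndarray:
    """Vector of integer scores for every row of a cohort."""
    schema = {s.name: s for s in cohort.schema}
    total = np.zeros(cohort.n, dtype=int)
    for v in table.variables:
        rows = table.rows_for(v)
        cats = []
        for r in rows:
            if r.levels:
                cats.append(("level", r.levels, r.label))
            else:
                cats.append(("interval", (r.lower, r.upper), r.label))
        codes = _recode(cohort.values[v], schema[v], cats)
        pts = np.array([r.points for r in rows])
        total += pts[codes]
    return total


@dataclass
class ParsimonyCurve:
    """Validation AUC as each ranked variable enters the score."""

    variables: list[str]
    aucs: np.ndarray
    suggested_size: int
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_variables": np.arange(1, len(self.variables) + 1),
            "variable_added": self.variables, "validation_auc": self.aucs,
        })


def parsimony_curve(ranked: list[str], train: CohortTable, val: CohortTable,
                    cuts: CutVector = None, cap: int = 100,
                    threshold: float = 0.01, method: str = "quantile") -> ParsimonyCurve:
    """Grow the score one ranked variable at a time and track validation AUC.

    The suggested size is the smallest prefix after which the next
    variable's AUC increment falls below ``threshold`` (default 1%); the
    full curve is retained so users can override the suggestion.
    """
    if not ranked:
        raise ValueError("ranking is empty")
    if cuts is None:
        cuts = derive_cuts(train, ranked, method=method)
    aucs = np.empty(len(ranked))
    for i in range(1, len(ranked) + 1):
        try:
            tab = assign_points(train, ranked[:i], cuts, cap=cap)
        except Exception as exc:
            raise RuntimeError(f"parsimony step {i} ({ranked[:i]}): {exc}") from exc
        aucs[i - 1] = auc(score_cohort(tab, val).astype(float), val.outcome)
    suggested = len(ranked)
    for i in range(1, len(ranked)):
        if aucs[i] - aucs[i - 1] < threshold:
            suggested = i
            break
    return ParsimonyCurve(variables=list(ranked), aucs=aucs,
                          suggested_size=suggested, threshold=threshold)


def fine_tune(table: ScoringTable, overrides: dict, train: CohortTable) -> ScoringTable:
    """Re-categorize with user-supplied cuts and re-assign points.

    ``overrides`` maps variable name -> strictly increasing cut list;
    variables not mentioned keep their automatic cuts.  An override
    leaving a training-empty category raises, naming the interval.
    """
    cuts = CutVector(
        cuts={**{v: list(c) for v, c in table.provenance.get("cuts", {}).items() if c}},
    )
    for v, c in overrides.items():
        c = [float(x) for x in c]
        if any(b <= a for a, b in zip(c, c[1:])):
            raise CategorizationError(f"override cuts for {v!r} must be strictly increasing")
        cuts.cuts[v] = c
    schema = {s.name: s for s in train.schema}
    for v in overrides:
        s = schema[v]
        cats = _categories(s, cuts)
        codes = _category_codes(train.values[v], s, cats)
        counts = np.bincount(codes, minlength=len(cats))
        for i in np.flatnonzero(counts == 0):
            raise CategorizationError(
                f"override for {v!r} leaves interval {cats[i][2]!r} empty in training"
            )
    return assign_points(train, table.variables, cuts, cap=table.cap)
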