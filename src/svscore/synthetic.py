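"""EHR-like synthetic cohorts with known ground truth.

Real hospital cohorts behind published risk scores are rarely shareable,
so every stage of this package is exercised on generated cohorts whose
true data-generating process is recorded: a mix of continuous vitals and
labs (normal / log-normal), utilisation counts (Poisson), binary
comorbidities (Bernoulli), ordered categorical variables (multinomial),
one deliberately collinear pair, and a logistic outcome model with
planted signal and pure-noise variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable, VariableSchema


class GenerationError(ValueError):
    """The generator spec produced a degenerate cohort (outcome prevalence 0 or 1)."""


@dataclass(frozen=True)
class VariableSpec:
    """One generated variable: schema + sampling distribution + true effect.

    ``dist`` is one of ``normal(mu, sd)``, ``lognormal(mu, sd)``,
    ``poisson(lam)``, ``bernoulli(p)``, ``multinomial(p1..pL)``.
    ``beta`` is the true coefficient on the standardized column (scalar),
    or one coefficient per non-reference level for categoricals.
    """

    schema: VariableSchema
    dist: str
    params: tuple
    beta: tuple = (0.0,)


@dataclass(frozen=True)
class CollinearPair:
    """A child variable built as a correlated copy of a continuous parent.

    child = rho * z_parent + sqrt(1 - rho^2) * noise on the standardized
    scale, which targets a classical VIF of 1/(1-rho^2) for the pair.
    """

    parent: str
    child: str
    rho: float


@dataclass(frozen=True)
class GeneratorSpec:
    n: int
    signal_vars: tuple[VariableSpec, ...]
    noise_vars: tuple[VariableSpec, ...]
    collinear_pairs: tuple[CollinearPair, ...] = ()
    intercept: float = -1.62
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.signal_vars or not self.noise_vars:
            raise ValueError("need at least one signal and one noise variable")
        for pair in self.collinear_pairs:
            if not abs(pair.rho) < 1:
                raise ValueError("|rho| must be < 1")


@dataclass(frozen=True)
class GroundTruth:
    """True coefficients on the dummy-encoded design, plus bookkeeping."""

    coefficients: dict              # column name -> true beta (standardized scale)
    intercept: float
    signal_names: tuple[str, ...]
    noise_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)


def _draw(dist: str, params: tuple, n: int, rng: np.random.Generator,
          levels: tuple = ()) -> np.ndarray:
    if dist == "normal":
        mu, sd = params
        return rng.normal(mu, sd, n)
    if dist == "lognormal":
        mu, sd = params
        return rng.lognormal(mu, sd, n)
    if dist == "poisson":
        (lam,) = params
        return rng.poisson(lam, n).astype(float)
    if dist == "bernoulli":
        (p,) = params
        return rng.binomial(1, p, n).astype(float)
    if dist == "multinomial":
        p = np.asarray(params, dtype=float)
        p = p / p.sum()
        idx = rng.choice(len(p), size=n, p=p)
        return np.asarray(levels, dtype=object)[idx]
    raise ValueError(f"unknown distribution {dist!r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def generate_cohort(spec: GeneratorSpec) -> tuple[CohortTable, GroundTruth]:
    """Sample a cohort and its outcome from the declared generating process.

    Continuous/count columns contribute to the linear predictor on the
    standardized scale (so stated effect sizes are comparable across
    variables); categorical columns contribute per-level effects against
    the first level as reference.  The outcome is
    ``Bernoulli(expit(intercept + x' beta))``.
    """
    rng = np.random.default_rng(spec.seed)
    all_vars = list(spec.signal_vars) + list(spec.noise_vars)
    by_name = {v.schema.name: v for v in all_vars}
    child_names = {p.child for p in spec.collinear_pairs}

    columns: dict[str, np.ndarray] = {}
    eta = np.full(spec.n, float(spec.intercept))
    coef: dict[str, float] = {}

    for v in all_vars:
        if v.schema.name in child_names:
            continue
        columns[v.schema.name] = _draw(
            v.dist, v.params, spec.n, rng, levels=v.schema.levels
        )

    for pair in spec.collinear_pairs:
        parent = columns[pair.parent]
        z = _standardize(parent.astype(float))
        noise = rng.normal(size=spec.n)
        columns[pair.child] = pair.rho * z + np.sqrt(1 - pair.rho**2) * noise

    for v in all_vars:
        x = columns[v.schema.name]
        if v.schema.vtype == "categorical":
            betas = v.beta
            if len(betas) != len(v.schema.levels) - 1:
                raise ValueError(
                    f"{v.schema.name!r}: need {len(v.schema.levels) - 1} level effects"
                )
            for lev, b in zip(v.schema.levels[1:], betas):
                eta += np.where(x == lev, float(b), 0.0)
                coef[f"{v.schema.name}[{lev}]"] = float(b)
        else:
            b = float(v.beta[0] if isinstance(v.beta, (tuple, list)) else v.beta)
            eta += b * _standardize(x.astype(float))
            coef[v.schema.name] = b

    y = rng.binomial(1, expit(eta))
    prev = y.mean()
    if prev in (0.0, 1.0):
        raise GenerationError(
            f"outcome prevalence is {prev:.0%}; adjust intercept "
            f"(linear predictor range [{eta.min():.2f}, {eta.max():.2f}])"
        )

    schema = [v.schema for v in all_vars]
    table = CohortTable(schema=schema, values=pd.DataFrame(columns), outcome=y)
    truth = GroundTruth(
        coefficients=coef,
        intercept=float(spec.intercept),
        signal_names=tuple(v.schema.name for v in spec.signal_vars),
        noise_names=tuple(v.schema.name for v in spec.noise_vars),
        metadata={
            "n": spec.n,
            "seed": spec.seed,
            "prevalence": float(prev),
            "distributions": {
                v.schema.name: {"dist": v.dist, "params": list(v.params)}
                for v in all_vars
            },
            "collinear_pairs": [
                {"parent": p.parent, "child": p.child, "rho": p.rho}
                for p in spec.collinear_pairs
            ],
        },
    )
    return table, truth


def signal_noise_spec(n: int, seed: int = 0) -> GeneratorSpec:
    """Ten-variable recovery fixture: 5 planted signals, 5 pure noise.

    Same variable flavours as :func:`default_ehr_spec` but without the
    collinear pair, for studying signal/noise separation (significance
    filtering and ensemble ordering) in isolation.
    """
    spec = default_ehr_spec(max(n, 500), seed=seed)
    noise = tuple(v for v in spec.noise_vars if v.schema.name != "chloride")
    return GeneratorSpec(
        n=n, signal_vars=spec.signal_vars, noise_vars=noise,
        collinear_pairs=(), intercept=spec.intercept, seed=seed,
    )


def default_ehr_spec(n: int, seed: int = 0) -> GeneratorSpec:
    """Canonical 11-variable fixture emulating an EHR extract.

    Five signal variables (a prior-ED-visit count, a continuous lab, a
    binary comorbidity, a three-level triage category, a continuous
    vital), five pure-noise variables of matching flavours, and one
    rho=0.8 collinear copy of the signal lab so the VIF>2 code path is
    exercised.  Effect sizes |beta| in [0.3, 1.0] on the standardized
    scale; intercept -1.62 targets a realistic ~16.5% outcome rate.
    """
    if n < 500:
        raise ValueError("n >= 500 required for a stable default cohort")
    c = VariableSchema
    signal = (
        VariableSpec(c("ed_visits", "continuous", unit="count"), "poisson", (1.2,), (1.0,)),
        VariableSpec(c("sodium", "continuous", unit="mmol/L"), "normal", (138.0, 4.0), (-0.6,)),
        VariableSpec(c("renal_disease", "binary"), "bernoulli", (0.15,), (0.5,)),
        VariableSpec(
            c("triage", "categorical", levels=("P3", "P2", "P1")),
            "multinomial", (0.5, 0.35, 0.15), (0.4, 0.8),
        ),
        VariableSpec(c("resp_rate", "continuous", unit="breaths/min"), "normal", (18.0, 3.0), (0.3,)),
    )
    noise = (
        VariableSpec(c("heart_rate", "continuous", unit="bpm"), "normal", (80.0, 12.0), (0.0,)),
        VariableSpec(c("glucose", "continuous", unit="mmol/L"), "lognormal", (1.8, 0.3), (0.0,)),
        VariableSpec(c("prior_surgery", "continuous", unit="count"), "poisson", (0.4,), (0.0,)),
        VariableSpec(c("pud", "binary"), "bernoulli", (0.08,), (0.0,)),
        VariableSpec(
            c("ward_class", "categorical", levels=("A", "B", "C")),
            "multinomial", (0.3, 0.4, 0.3), (0.0, 0.0),
        ),
        # collinear child of the sodium lab; zero own effect
        VariableSpec(c("chloride", "continuous", unit="std"), "normal", (0.0, 1.0), (0.0,)),
    )
    return GeneratorSpec(
        n=n,
        signal_vars=signal,
        noise_vars=noise,
        collinear_pairs=(CollinearPair(parent="sodium", child="chloride", rho=0.8),),
        intercept=-1.62,
        seed=seed,
    )
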