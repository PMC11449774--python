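"""Covariate-adjusted logistic models of retinopathy on FBG indices.

The outcome is binary (retinopathy yes/no), so the "multinomial"
regression of a two-category outcome collapses to ordinary binary
logistic regression; fits are maximum likelihood via Newton's method
(statsmodels).  Odds ratios are reported per unit or per 1 cohort-SD
increase depending on the predictor's declared scaling, with Wald 95%
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import CLASSICAL_COVARIATES
from .indices import DEFAULT_SCALING

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_logistic",
    "extract_or",
    "build_model_grid",
    "INDEX_TERMS",
]

#: the seven FBG index predictors, in reporting order
INDEX_TERMS = ("fbg_baseline", "sd", "cv", "vim", "arv_pct", "m_fbg", "cum_load")


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic model: ordered predictor terms plus scaling map.

    ``scaling`` maps a term to ``per_unit`` or ``per_cohort_sd``; terms
    absent from the map default to ``per_unit``.
    """

    name: str
    terms: tuple
    outcome: str = "dr_status"
    scaling: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"model {self.name!r}: duplicate terms")
        if self.outcome in self.terms:
            raise ValueError(f"model {self.name!r}: outcome among predictors")


@dataclass
class ModelFit:
    """A fitted logistic model with everything downstream needs."""

    spec: ModelSpec
    params: pd.Series           # log-odds scale, includes "const"
    cov: pd.DataFrame           # parameter covariance (Wald)
    log_likelihood: float
    n: int
    k: int                      # parameter count incl. intercept
    predicted_risks: np.ndarray
    converged: bool


def _design_matrix(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = {}
    for term in spec.terms:
        if term not in data.columns:
            raise ValueError(f"model {spec.name!r}: term {term!r} not in data")
        x = pd.to_numeric(data[term], errors="raise").to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"model {spec.name!r}: term {term!r} has missing values")
        scheme = spec.scaling.get(term, "per_unit")
        if scheme == "per_cohort_sd":
            sd = np.std(x, ddof=1)
            if not sd > 0:
                raise ValueError(f"term {term!r}: zero cohort SD, cannot scale")
            x = x / sd
        elif scheme != "per_unit":
            raise ValueError(f"term {term!r}: unknown scaling {scheme!r}")
        cols[term] = x
    X = pd.DataFrame(cols, index=data.index)
    return sm.add_constant(X, has_constant="add")


def fit_logistic(data: pd.DataFrame, spec: ModelSpec, maxiter: int = 100) -> ModelFit:
    """Maximum-likelihood binary logistic fit of ``spec`` on ``data``.

    ``data`` must contain the outcome column and every term, with no
    missing values (impute first).  Deterministic given inputs.  Perfect
    separation and non-convergence raise descriptive errors.
    """
    y = pd.to_numeric(data[spec.outcome], errors="raise").to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} must be 0/1")
    if y.min() == y.max():
        raise ValueError(f"outcome {spec.outcome!r} has a single class")
    X = _design_matrix(data, spec)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise ValueError(
            f"model {spec.name!r}: logistic fit failed ({exc}); "
            "check for a perfectly separating predictor"
        ) from exc
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise ValueError(
            f"model {spec.name!r}: no convergence after {maxiter} iterations "
            f"(|grad| = {np.abs(res.model.score(res.params)).max():.3g})"
        )
    # absurd coefficient scale is the practical signature of quasi-separation
    if np.abs(res.params.drop(labels=["const"], errors="ignore")).max() > 50:
        big = res.params.drop(labels=["const"], errors="ignore").abs().idxmax()
        raise ValueError(
            f"model {spec.name!r}: term {big!r} appears to separate the outcome"
        )
    return ModelFit(
        spec=spec,
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index,
                         columns=res.params.index),
        log_likelihood=float(res.llf),
        n=int(len(y)),
        k=int(X.shape[1]),
        predicted_risks=np.asarray(res.predict(X), dtype=float),
        converged=converged,
    )


def extract_or(fit: ModelFit, term: str) -> tuple[float, float, float]:
    """Odds ratio and Wald 95% CI for one term, on its declared scaling."""
    if term not in fit.params.index:
        raise ValueError(f"term {term!r} not in model {fit.spec.name!r}")
    coef = float(fit.params[term])
    se = float(np.sqrt(fit.cov.loc[term, term]))
    return (
        float(np.exp(coef)),
        float(np.exp(coef - 1.96 * se)),
        float(np.exp(coef + 1.96 * se)),
    )


def build_model_grid(
    index_terms: tuple = INDEX_TERMS,
    classical: tuple = CLASSICAL_COVARIATES,
    scaling: dict | None = None,
) -> list[ModelSpec]:
    """The model grid for the discrimination comparison.

    With the full set of seven indices this yields 18 specs, in reporting
    order: the classical-risk-factor model; classical plus each single
    index; and the ten index combinations examined in the comparison
    (pairs and triples built around baseline FBG and the cumulative load).
    Restricting ``index_terms`` keeps only specs whose indices are all
    available.
    """
    scaling = dict(DEFAULT_SCALING if scaling is None else scaling)
    combos = [
        ("fbg_baseline", "sd"),
        ("fbg_baseline", "cv"),
        ("fbg_baseline", "cum_load"),
        ("sd", "cum_load"),
        ("cv", "cum_load"),
        ("arv_pct", "cum_load"),
        ("fbg_baseline", "sd", "cum_load"),
        ("fbg_baseline", "cv", "cum_load"),
        ("fbg_baseline", "vim", "cum_load"),
        ("fbg_baseline", "arv_pct", "cum_load"),
    ]
    available = set(index_terms)
    specs = [ModelSpec(name="classical", terms=tuple(classical), scaling=scaling)]
    for idx in INDEX_TERMS:
        if idx in available:
            specs.append(
                ModelSpec(
                    name=f"classical+{idx}",
                    terms=tuple(classical) + (idx,),
                    scaling=scaling,
                )
            )
    for combo in combos:
        if set(combo) <= available:
            specs.append(
                ModelSpec(
                    name="classical+" + "+".join(combo),
                    terms=tuple(classical) + combo,
                    scaling=scaling,
                )
            )
    return specs
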