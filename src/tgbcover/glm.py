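"""Binomial-logit GLMs for cover fractions, candidate enumeration and AIC
selection.

Tree (T) and grass (G) cover fractions are modelled with a binomial error
distribution and logit link against the standardized predictors MAR, SI,
lambda_w, alpha_w and log_afi. The candidate set comprises, per response:

* hierarchical polynomials of one predictor up to the cubic (3 specs per
  predictor);
* every combination of two or more predictors with linear terms only,
  excluding combinations containing both alpha_w and lambda_w (which are
  tied through the wet-season water balance);
* the intercept-only model.

With the five predictors and the alpha_w/lambda_w exclusion this gives
15 + 18 + 1 = 34 models. Models are ranked by AIC; goodness of fit is the
explained deviance ``pseudo-R2 = 1 - D_m / D_0``.

A likelihood for fractional cover needs a binomial denominator; cover is
treated as a proportion out of ``n_trials`` (default 100, percent-cover
granularity). Absolute AIC values depend on that choice but AIC rankings
and coefficient estimates are the quantities of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PREDICTORS",
    "EXCLUDED_PAIR",
    "ModelSpec",
    "FitResult",
    "ModelSelection",
    "standardize",
    "enumerate_models",
    "design_matrix",
    "fit_binomial_glm",
    "select_models",
    "parabola_extremum",
    "ParabolaExtremum",
]

PREDICTORS = ("MAR", "SI", "lambda_w", "alpha_w", "log_afi")
#: alpha_w and lambda_w are linked by the water-balance identity and never
#: appear together in a candidate model.
EXCLUDED_PAIR = ("alpha_w", "lambda_w")
DEFAULT_N_TRIALS = 100


def term_name(predictor: str, power: int) -> str:
    return predictor if power == 1 else f"{predictor}^{power}"


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: response and ordered (predictor, power) terms.

    The intercept is always present and is not listed among the terms; an
    empty term tuple is the intercept-only model.
    """

    response: str
    terms: tuple[tuple[str, int], ...] = ()

    @classmethod
    def polynomial(cls, response: str, predictor: str, degree: int) -> "ModelSpec":
        if not 1 <= degree <= 3:
            raise ValueError("polynomial degree must be 1, 2 or 3")
        return cls(response, tuple((predictor, k) for k in range(1, degree + 1)))

    @classmethod
    def linear(cls, response: str, predictors: Sequence[str]) -> "ModelSpec":
        return cls(response, tuple((p, 1) for p in predictors))

    @classmethod
    def intercept_only(cls, response: str) -> "ModelSpec":
        return cls(response, ())

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(term_name(p, k) for p, k in self.terms)

    @property
    def predictors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p, _ in self.terms:
            seen.setdefault(p)
        return tuple(seen)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def label(self) -> str:
        rhs = " + ".join(("1",) + self.term_names)
        return f"{self.response} ~ {rhs}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_models(
    response: str,
    predictors: Sequence[str] = PREDICTORS,
    excluded_pair: tuple[str, str] | None = EXCLUDED_PAIR,
    max_degree: int = 3,
) -> list[ModelSpec]:
    """The candidate model set, in deterministic order.

    Intercept-only first, then single-predictor polynomials (degree 1..3
    per predictor, in predictor order), then linear multi-predictor
    combinations by size and predictor order, skipping combinations that
    contain both members of ``excluded_pair``.
    """
    predictors = tuple(predictors)
    if len(predictors) < 1:
        raise ValueError("at least one predictor is required")
    if excluded_pair is not None and not set(excluded_pair) <= set(predictors):
        raise ValueError(f"excluded pair {excluded_pair} not among predictors")
    specs = [ModelSpec.intercept_only(response)]
    for p in predictors:
        for degree in range(1, max_degree + 1):
            specs.append(ModelSpec.polynomial(response, p, degree))
    for size in range(2, len(predictors) + 1):
        for combo in combinations(predictors, size):
            if excluded_pair is not None and set(excluded_pair) <= set(combo):
                continue
            specs.append(ModelSpec.linear(response, combo))
    return specs


def standardize(
    table: pd.DataFrame, columns: Sequence[str] = PREDICTORS
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center and scale columns to mean 0, sd 1 (sample sd, ddof=1).

    Returns the transformed copy and the per-column (mean, sd) needed to
    map model coefficients back to natural units.
    """
    table = table.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"predictor {col!r} is constant; cannot standardize")
        table[col] = (x - mean) / sd
        params[col] = (mean, sd)
    return table, params


def design_matrix(spec: ModelSpec, table: pd.DataFrame) -> np.ndarray:
    """Intercept column plus one column per term (powers of standardized
    predictors), in spec order."""
    n = len(table)
    cols = [np.ones(n)]
    for predictor, power in spec.terms:
        if predictor not in table.columns:
            raise ValueError(f"predictor {predictor!r} not in table")
        cols.append(table[predictor].to_numpy(dtype=float) ** power)
    return np.column_stack(cols)


@dataclass(frozen=True)
class FitResult:
    """A fitted candidate model."""

    spec: ModelSpec
    coefficients: dict[str, float]  # keyed 'intercept' then term names
    stderr: dict[str, float]
    deviance: float
    null_deviance: float
    aic: float
    llf: float
    nobs: int
    n_trials: int
    mu: np.ndarray = field(repr=False)  # fitted mean proportions
    resid_deviance: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def pseudo_r2(self) -> float:
        """Explained deviance 1 - D_m/D_0 (0 for the intercept-only model)."""
        if self.spec.n_terms == 0 or self.null_deviance <= 1e-10:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


def _successes(fractions: np.ndarray, n_trials: int) -> np.ndarray:
    counts = np.rint(fractions * n_trials)
    return np.clip(counts, 0, n_trials)


def fit_binomial_glm(
    spec: ModelSpec,
    table: pd.DataFrame,
    n_trials: int = DEFAULT_N_TRIALS,
) -> FitResult:
    """Fit one candidate by IRLS maximum likelihood.

    The response column (fractions in [0, 1]) is converted to success
    counts out of ``n_trials`` and fitted as a binomial GLM with logit
    link. Predictors are used as found in ``table`` (standardize first
    for comparable coefficient magnitudes).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    y = table[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("response fractions must lie in [0, 1]")
    X = design_matrix(spec, table)
    if len(table) < X.shape[1] + 2:
        raise ValueError("too few rows for the number of model terms")
    k = _successes(y, n_trials)
    endog = np.column_stack([k, n_trials - k])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit()
    names = ("intercept",) + spec.term_names
    return FitResult(
        spec=spec,
        coefficients=dict(zip(names, (float(v) for v in res.params))),
        stderr=dict(zip(names, (float(v) for v in res.bse))),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        aic=float(res.aic),
        llf=float(res.llf),
        nobs=len(table),
        n_trials=n_trials,
        mu=np.asarray(res.mu),
        resid_deviance=np.asarray(res.resid_deviance),
        converged=bool(getattr(res, "converged", True)),
    )


@dataclass(frozen=True)
class ModelSelection:
    """AIC ranking of the full candidate set for one response/range case."""

    fits: tuple[FitResult, ...]  # sorted by (AIC, n_terms, enumeration order)
    intercept_aic: float

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    @property
    def retained(self) -> tuple[FitResult, ...]:
        """Models with AIC strictly below the intercept-only model."""
        return tuple(f for f in self.fits if f.aic < self.intercept_aic)

    def to_frame(self) -> pd.DataFrame:
        best_aic = self.best.aic
        rows = []
        for f in self.fits:
            rows.append(
                {
                    "model": f.spec.label,
                    "n_terms": f.spec.n_terms,
                    "aic": f.aic,
                    "delta_aic": f.aic - best_aic,
                    "pseudo_r2": f.pseudo_r2,
                    "coefficients": "; ".join(
                        f"{k}={v:.4f}" for k, v in f.coefficients.items()
                    ),
                }
            )
        return pd.DataFrame(rows)


def select_models(fits: Sequence[FitResult]) -> ModelSelection:
    """Rank candidate fits by AIC (ties: fewer terms, then input order)."""
    fits = list(fits)
    intercept = [f for f in fits if f.spec.n_terms == 0]
    if not intercept:
        raise ValueError("the candidate set must include the intercept-only model")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].spec.n_terms, i))
    return ModelSelection(
        fits=tuple(fits[i] for i in order), intercept_aic=intercept[0].aic
    )


@dataclass(frozen=True)
class ParabolaExtremum:
    """Vertex of a quadratic single-predictor fit on the logit scale."""

    predictor: str
    standardized: float  # vertex location in standardized units
    natural: float  # vertex location in the predictor's natural units
    kind: str  # 'minimum' or 'maximum'


def parabola_extremum(
    fit: FitResult, standardize_params: Mapping[str, tuple[float, float]]
) -> ParabolaExtremum:
    """Location of the extremum of a quadratic fit, in natural units.

    For ``logit = a + b*z + c*z**2`` the vertex is at ``z* = -b/(2c)``;
    ``standardize_params`` maps it back as ``mean + sd*z*``. Labelled a
    minimum when the quadratic coefficient is positive.
    """
    quads = [(p, k) for p, k in fit.spec.terms if k == 2]
    if len(quads) != 1:
        raise ValueError("fit must contain exactly one quadratic term")
    predictor = quads[0][0]
    b = fit.coefficients.get(term_name(predictor, 1), 0.0)
    c = fit.coefficients[term_name(predictor, 2)]
    if c == 0:
        raise ValueError("zero quadratic coefficient: no extremum")
    z = -b / (2.0 * c)
    mean, sd = standardize_params[predictor]
    return ParabolaExtremum(
        predictor=predictor,
        standardized=z,
        natural=mean + sd * z,
        kind="minimum" if c > 0 else "maximum",
    )
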