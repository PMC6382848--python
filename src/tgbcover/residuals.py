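"""Deviance-residual analysis of intra-seasonal predictor collinearity.

Because wet-season rainfall frequency (lambda_w) and intensity (alpha_w)
are correlated with MAR, SI and log10(AFI), a term for one of them in a
best cover model may only proxy those variables. The check: regress the
cover fraction on {MAR, SI, log_afi} (binomial-logit) and the
intra-seasonal variable on the same three predictors (ordinary least
squares, for which deviance residuals are raw residuals), then correlate
the two deviance-residual vectors. A large squared correlation means the
intra-seasonal variable carries cover information beyond the three shared
drivers; a small one means its apparent effect is mediated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glm import DEFAULT_N_TRIALS, FitResult, ModelSpec, design_matrix, fit_binomial_glm

__all__ = ["ResidualPair", "deviance_residuals", "residual_r2"]

#: The shared drivers removed from both sides of the comparison.
BASE_PREDICTORS = ("MAR", "SI", "log_afi")


@dataclass(frozen=True)
class ResidualPair:
    """Matched deviance-residual vectors and their squared correlation."""

    response: str
    intra_var: str
    veg_residuals: np.ndarray
    pred_residuals: np.ndarray
    r2: float
    degenerate: bool = False  # True when the predictor-side residuals vanish


def deviance_residuals(fit: FitResult) -> np.ndarray:
    """Signed square roots of the per-observation deviance contributions;
    their sum of squares equals the residual deviance."""
    return fit.resid_deviance


def residual_r2(
    table: pd.DataFrame,
    response: str,
    intra_var: str,
    n_trials: int = DEFAULT_N_TRIALS,
    base_predictors: Sequence[str] = BASE_PREDICTORS,
) -> ResidualPair:
    """Squared correlation between cover and intra-seasonal-variable
    residuals after removing the shared drivers from both.

    ``intra_var`` is normally ``'lambda_w'`` or ``'alpha_w'``. When the
    intra-seasonal variable is fully determined by the base predictors the
    pair is flagged degenerate and ``r2`` reported as 0.
    """
    if intra_var in base_predictors:
        raise ValueError("intra_var must not be among the base predictors")
    if len(table) < 10:
        raise ValueError("at least 10 rows are required")
    veg_spec = ModelSpec.linear(response, tuple(base_predictors))
    veg_fit = fit_binomial_glm(veg_spec, table, n_trials=n_trials)
    veg_res = deviance_residuals(veg_fit)

    # OLS of the intra-seasonal variable on the same three predictors;
    # for the normal family deviance residuals are the raw residuals.
    X = design_matrix(ModelSpec.linear(intra_var, tuple(base_predictors)), table)
    y = table[intra_var].to_numpy(dtype=float)
    ols = sm.OLS(y, X).fit()
    pred_res = np.asarray(ols.resid)

    scale = np.sqrt(np.mean(pred_res**2))
    if not np.isfinite(scale) or scale < 1e-10 * max(1.0, float(np.std(y))):
        return ResidualPair(response, intra_var, veg_res, pred_res, 0.0, True)
    r = np.corrcoef(veg_res, pred_res)[0, 1]
    return ResidualPair(response, intra_var, veg_res, pred_res, float(r * r))
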