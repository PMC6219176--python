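"""OLS engine and exhaustive best-subset search.

Model development fits ordinary least squares regressions of recorded
estimated foetal weight on candidate predictors, and ranks every non-empty
predictor subset by the usual selection statistics:

* ``R^2``     coefficient of determination,
* ``S``       residual standard deviation (grams),
* Mallows Cp  ``SSE_subset / MSE_full - n + 2p`` (p = parameter count,
              intercept included) against the full candidate model,
* VIF         ``1 / (1 - R^2_j)`` per predictor, regressing predictor j on
              its co-predictors.

Subsets whose maximum VIF exceeds a hard threshold are flagged excluded
(severe multicollinearity) and always rank after clean subsets; the
remaining ranking is by minimal S, then |Cp - p|, then fewer predictors.
The fitting itself is delegated to statsmodels behind the
:class:`OlsFit` surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad

from .errors import (
    CollinearityError,
    DegenerateInputError,
    ValidationFailure,
)

#: conventional multicollinearity bounds: warn above the first, exclude
#: above the second
VIF_WARN = 10.0
VIF_EXCLUDE = 100.0

#: significance annotation tiers
SIGNIFICANCE_TIERS = ((0.0005, "***"), (0.05, "**"), (0.1, "*"))


def significance_stars(p: float) -> str:
    for level, stars in SIGNIFICANCE_TIERS:
        if p < level:
            return stars
    return ""


@dataclass
class OlsFit:
    """Fitted linear model with the selection statistics attached."""

    predictor_names: list[str]
    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    r_squared: float
    s: float  # residual standard deviation, grams
    anova_f_p: float
    t_p: np.ndarray  # per-coefficient partial p-values, intercept first
    residuals: np.ndarray
    sse: float
    nobs: int
    vif: Optional[dict[str, float]] = None
    mallows_cp: Optional[float] = None
    normality_p: Optional[float] = None

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(design))] + [design[c].to_numpy(float) for c in self.predictor_names]
        )
        return X @ self.coefficients

    def summary_row(self) -> dict:
        return {
            "predictors": "+".join(self.predictor_names),
            "r_squared": self.r_squared,
            "s": self.s,
            "mallows_cp": self.mallows_cp,
            "max_vif": max(self.vif.values()) if self.vif else None,
            "anova_f_p": self.anova_f_p,
        }


def _as_design(design) -> pd.DataFrame:
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
        design.columns = [f"x{j + 1}" for j in range(design.shape[1])]
    return design.astype(float)


def _dependent_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns adding no rank beyond the previous ones (incl. intercept)."""
    n = X.shape[0]
    basis = [np.ones(n)]
    dependent = []
    for j, name in enumerate(names):
        candidate = np.column_stack(basis + [X[:, j]])
        if np.linalg.matrix_rank(candidate) == len(basis):
            dependent.append(name)
        else:
            basis.append(X[:, j])
    return dependent


def fit_ols(design, response, normality_method: str = "anderson") -> OlsFit:
    """Least-squares fit of ``response`` (grams) on the predictor table."""
    design = _as_design(design)
    y = np.asarray(response, dtype=float)
    n, p = design.shape
    if len(y) != n:
        raise ValidationFailure("response length does not match the design")
    if n < p + 2:
        raise ValidationFailure(
            f"need at least predictors + 2 = {p + 2} rows, got {n}"
        )
    X = design.to_numpy()
    dependent = _dependent_columns(X, design.columns)
    if dependent:
        raise CollinearityError(dependent)

    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    resid = np.asarray(res.resid)
    s = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0

    fit = OlsFit(
        predictor_names=list(design.columns),
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        r_squared=float(res.rsquared),
        s=s,
        anova_f_p=float(res.f_pvalue),
        t_p=np.asarray(res.pvalues),
        residuals=resid,
        sse=float(res.ssr),
        nobs=n,
    )
    if p >= 2:
        fit.vif = vif(design)
    if n >= 8 and np.ptp(resid) > 0:
        fit.normality_p = residual_normality(resid, method=normality_method)
    return fit


def vif(design) -> dict[str, float]:
    """Variance inflation factors; perfect collinearity reports +inf."""
    design = _as_design(design)
    if design.shape[1] < 2:
        raise ValidationFailure("VIF needs at least 2 non-intercept predictors")
    X = design.to_numpy()
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j] - X[:, j].mean()
        Z = np.delete(X, j, axis=1)
        Z = np.column_stack([np.ones(len(X)), Z])
        beta, *_ = np.linalg.lstsq(Z, X[:, j], rcond=None)
        sse = float(np.sum((X[:, j] - Z @ beta) ** 2))
        sst = float(np.sum(yj**2))
        if sst == 0:
            raise DegenerateInputError(f"predictor {name!r} is constant")
        r2 = 1.0 - sse / sst
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def mallows_cp(subset_fit: OlsFit, full_model_mse: float, n: int) -> float:
    """Cp = SSE_subset / MSE_full - n + 2p  (p includes the intercept)."""
    if full_model_mse <= 0:
        raise DegenerateInputError("full-model MSE must be positive for Cp")
    return float(subset_fit.sse / full_model_mse - n + 2 * subset_fit.n_params)


def residual_normality(residuals, method: str = "anderson") -> float:
    """P-value of a residual-normality test (Anderson-Darling default)."""
    resid = np.asarray(residuals, dtype=float)
    if resid.size < 8:
        raise ValidationFailure("normality test needs at least 8 residuals")
    if np.ptp(resid) == 0:
        raise DegenerateInputError("constant residuals; normality test undefined")
    if method == "anderson":
        _, p = normal_ad(resid)
    elif method == "shapiro":
        _, p = sps.shapiro(resid)
    else:
        raise ValidationFailure(f"unknown normality method {method!r}")
    return float(p)


@dataclass
class SubsetResult:
    """One candidate subset with its fit and multicollinearity flags."""

    fit: OlsFit
    excluded: bool = False
    vif_warning: bool = False

    @property
    def predictors(self) -> list[str]:
        return self.fit.predictor_names

    @property
    def max_vif(self) -> Optional[float]:
        return max(self.fit.vif.values()) if self.fit.vif else None


def best_subsets(
    candidates,
    response,
    max_size: Optional[int] = None,
    vif_warn: float = VIF_WARN,
    vif_exclude: float = VIF_EXCLUDE,
) -> list[SubsetResult]:
    """Fit every non-empty predictor subset up to ``max_size`` and rank.

    Candidates that are perfectly collinear with the preceding columns are
    dropped from the full reference model so the full-model MSE behind
    Mallows Cp is well defined; enumeration still covers every candidate,
    and only the individual subsets that are themselves rank deficient are
    skipped.
    """
    candidates = _as_design(candidates)
    y = np.asarray(response, dtype=float)
    if candidates.shape[1] > 15:
        raise ValidationFailure("exhaustive enumeration is limited to 15 candidates")
    if max_size is None:
        max_size = candidates.shape[1]
    if max_size < 1:
        raise ValidationFailure("max_size must be at least 1")

    dependent = _dependent_columns(candidates.to_numpy(), candidates.columns)
    usable = [c for c in candidates.columns if c not in dependent]
    if not usable:
        raise CollinearityError(list(candidates.columns))
    full_fit = fit_ols(candidates[usable], y)
    mse_full = full_fit.sse / max(full_fit.nobs - full_fit.n_params, 1)

    results = []
    for size in range(1, min(max_size, candidates.shape[1]) + 1):
        for combo in itertools.combinations(candidates.columns, size):
            try:
                fit = fit_ols(candidates[list(combo)], y)
            except CollinearityError:
                continue
            fit.mallows_cp = mallows_cp(fit, mse_full, fit.nobs)
            max_vif = max(fit.vif.values()) if fit.vif else 1.0
            results.append(
                SubsetResult(
                    fit=fit,
                    excluded=max_vif > vif_exclude,
                    vif_warning=max_vif > vif_warn,
                )
            )

    results.sort(
        key=lambda r: (
            r.excluded,
            r.fit.s,
            abs(r.fit.mallows_cp - r.fit.n_params),
            len(r.predictors),
        )
    )
    return results
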