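"""Adjusted observational models and restricted-cubic-spline nonlinearity.

The exposure-outcome association is modelled with a logistic (binary outcome)
or linear (continuous outcome) regression adjusted for the standard covariate
set. Nonlinearity is assessed with restricted cubic splines: a piecewise-cubic
basis constrained to be linear beyond the boundary knots, knot count chosen by
minimum AIC over a candidate set, and a likelihood-ratio test of the k-2
nonlinear terms against the linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._glm import CollinearityError, fit_logistic, fit_ols

__all__ = [
    "DEFAULT_ADJUSTMENT",
    "FBG_EXTRA_ADJUSTMENT",
    "GlmFitResult",
    "RcsFit",
    "fit_adjusted_glm",
    "rcs_basis",
    "default_knots",
    "select_knots_aic",
    "rcs_nonlinearity_test",
    "rcs_effect_curve",
]

#: Covariates adjusted for in every exposure-outcome model.
DEFAULT_ADJUSTMENT = (
    "age", "sex", "bmi", "diabetes_family_history", "dyslipidemia", "chd",
    "sbp", "dbp",
)
#: Added when the outcome is fasting glucose.
FBG_EXTRA_ADJUSTMENT = ("hypoglycemic_drug_use",)

#: Recommended quantile placements for k knots (Harrell's convention).
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass
class GlmFitResult:
    """Exposure coefficient from an adjusted GLM."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    family: str
    loglik: float
    results: object = field(repr=False, default=None)

    @property
    def odds_ratio(self) -> float | None:
        if self.family != "logistic":
            return None
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float] | None:
        if self.family != "logistic":
            return None
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class RcsFit:
    """Adjusted GLM with a restricted-cubic-spline exposure term."""

    knot_count: int
    knots: np.ndarray
    coefficients: np.ndarray  # [intercept, linear, nonlinear..., covariates...]
    aic: float
    loglik: float
    nonlinearity_p: float
    family: str
    exposure: str
    n: int
    results: object = field(repr=False, default=None)
    covariate_names: list = field(default_factory=list)


def _design(table, columns, exposure_cols=None):
    X = table[list(columns)].to_numpy(dtype=float)
    if exposure_cols is not None:
        X = np.column_stack([exposure_cols, X])
    return np.column_stack([np.ones(len(X)), X])


def _complete_cases(table, columns):
    sub = table[list(columns)]
    return table[sub.notna().all(axis=1)]


def fit_adjusted_glm(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjust=DEFAULT_ADJUSTMENT,
    family: str = "logistic",
) -> GlmFitResult:
    """Fit outcome ~ exposure + covariates on complete cases.

    ``family`` is ``"logistic"`` (maximum likelihood) or ``"linear"`` (least
    squares). Returns the exposure coefficient with its Wald SE, 95% CI and
    p-value; for logistic fits :attr:`GlmFitResult.odds_ratio` exponentiates.
    """
    adjust = [c for c in adjust if c != exposure]
    cols = [outcome, exposure, *adjust]
    data = _complete_cases(table, cols)
    n = len(data)
    n_params = len(adjust) + 2
    if n < 10 * n_params:
        warnings.warn(
            f"only {n} complete cases for {n_params} parameters", stacklevel=2
        )
    y = data[outcome].to_numpy(dtype=float)
    X = _design(data, [exposure, *adjust])
    names = ["intercept", exposure, *adjust]
    if family == "logistic":
        if len(np.unique(y)) < 2:
            raise ValueError(f"outcome {outcome!r} does not vary")
        res = fit_logistic(y, X, names)
    elif family == "linear":
        res = fit_ols(y, X, names)
    else:
        raise ValueError(f"unknown family {family!r}")
    est, se = float(res.params[1]), float(res.bse[1])
    z = est / se
    p = 2 * sps.norm.sf(abs(z))
    return GlmFitResult(
        estimate=est, se=se,
        ci_low=est - 1.959963984540054 * se, ci_high=est + 1.959963984540054 * se,
        p=float(p), n=n, family=family, loglik=float(res.llf), results=res,
    )


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear term + k-2 cubic terms.

    With knots t_1 < ... < t_k, column 0 is x itself and column j (1..k-2) is

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which makes the spline linear for x <= t_1 and x >= t_k and keeps the
    nonlinear coefficients on a scale comparable to the linear one.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    t1, tkm1, tk = knots[0], knots[-2], knots[-1]
    scale = (tk - t1) ** 2

    def cub(t):
        return np.clip(x - t, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cub(tj)
            - cub(tkm1) * (tk - tj) / (tk - tkm1)
            + cub(tk) * (tkm1 - tj) / (tk - tkm1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


def default_knots(x, k: int) -> np.ndarray:
    """Knots at the recommended quantiles for a k-knot spline."""
    if k not in KNOT_QUANTILES:
        raise ValueError(f"knot count must be one of {sorted(KNOT_QUANTILES)}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    knots = np.quantile(x, KNOT_QUANTILES[k])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("data too discrete for distinct knots at this count")
    return knots


def _fit_rcs(data, outcome, exposure, adjust, family, k):
    knots = default_knots(data[exposure].to_numpy(), k)
    B = rcs_basis(data[exposure].to_numpy(dtype=float), knots)
    X = _design(data, adjust, exposure_cols=B)
    names = ["intercept", exposure] + [f"{exposure}_rcs{j}" for j in range(1, k - 1)] + list(adjust)
    y = data[outcome].to_numpy(dtype=float)
    res = fit_logistic(y, X, names) if family == "logistic" else fit_ols(y, X, names)
    return knots, res


def select_knots_aic(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjust=DEFAULT_ADJUSTMENT,
    family: str = "logistic",
    k_candidates=(3, 4, 5),
) -> RcsFit:
    """Fit the RCS model for each candidate knot count; keep the minimum AIC.

    The complete-case sample is fixed across candidates so AICs are
    comparable; AIC = 2*params - 2*loglik; ties go to the smaller k.
    """
    bad = set(k_candidates) - set(KNOT_QUANTILES)
    if bad:
        raise ValueError(f"unsupported knot counts: {sorted(bad)}")
    adjust = [c for c in adjust if c != exposure]
    data = _complete_cases(table, [outcome, exposure, *adjust])
    best = None
    failures = []
    for k in sorted(k_candidates):
        try:
            knots, res = _fit_rcs(data, outcome, exposure, adjust, family, k)
        except Exception as exc:
            warnings.warn(f"RCS fit with k={k} failed: {exc}", stacklevel=2)
            failures.append(k)
            continue
        aic = 2 * len(res.params) - 2 * float(res.llf)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, k, knots, res)
    if best is None:
        raise RuntimeError(f"all candidate knot counts failed: {failures}")
    aic, k, knots, res = best
    reduced = fit_adjusted_glm(data, outcome, exposure, adjust, family)
    p_nonlin = rcs_nonlinearity_p(float(res.llf), reduced.loglik, k - 2)
    return RcsFit(
        knot_count=k, knots=knots, coefficients=np.asarray(res.params),
        aic=float(aic), loglik=float(res.llf), nonlinearity_p=p_nonlin,
        family=family, exposure=exposure, n=len(data), results=res,
        covariate_names=list(adjust),
    )


def rcs_nonlinearity_p(loglik_full: float, loglik_reduced: float, df: int) -> float:
    lr = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    return float(sps.chi2.sf(lr, df=df))


def rcs_nonlinearity_test(fit: RcsFit, reduced: GlmFitResult) -> float:
    """Likelihood-ratio test of the k-2 nonlinear spline terms.

    ``reduced`` must be the same GLM with the linear exposure term only, on
    the same complete-case sample.
    """
    if reduced.family != fit.family:
        raise ValueError("full and reduced models have different families")
    if reduced.n != fit.n:
        raise ValueError(
            f"models are not nested on the same sample (n={fit.n} vs {reduced.n})"
        )
    return rcs_nonlinearity_p(fit.loglik, reduced.loglik, fit.knot_count - 2)


def rcs_effect_curve(
    fit: RcsFit,
    reference_x: float,
    grid,
) -> pd.DataFrame:
    """Spline effect relative to ``reference_x`` on the link scale.

    Returns a DataFrame with columns x/effect/lower/upper (delta-method 95%
    pointwise bands) and attaches the fitted curve's argmin as
    ``df.attrs["argmin_x"]``.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = fit.knots[0], fit.knots[-1]
    span = hi - lo
    if not (lo - 0.5 * span <= reference_x <= hi + 0.5 * span):
        raise ValueError(f"reference {reference_x} is far outside the fitted range")
    B_grid = rcs_basis(grid, fit.knots)
    B_ref = rcs_basis(np.array([reference_x]), fit.knots)
    D = B_grid - B_ref  # intercept and covariates cancel in the contrast
    k = fit.knot_count
    idx = np.arange(1, k)  # spline coefficient positions in the parameter vector
    beta = fit.coefficients[idx]
    eff = D @ beta
    cov = np.asarray(fit.results.cov_params())[np.ix_(idx, idx)]
    var = np.einsum("ij,jk,ik->i", D, cov, D)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = 1.959963984540054
    out = pd.DataFrame({
        "x": grid, "effect": eff, "lower": eff - z * se, "upper": eff + z * se,
    })
    out.attrs["argmin_x"] = float(grid[np.argmin(eff)])
    out.attrs["reference_x"] = float(reference_x)
    return out
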