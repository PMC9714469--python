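"""Stratified nonlinear Mendelian randomization with fractional polynomials.

The exposure distribution is split into strata of the instrument-free
exposure (residual of exposure on the score), so that stratification does not
open a collider path through the instrument. Within each stratum a linear
two-stage MR estimate — the localized average causal effect (LACE) — is
computed with its SE and the stratum mean exposure. A weighted meta-regression
of the LACE values on the *derivative* of fractional-polynomial models of
degrees 1 and 2 (powers from {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, 0 meaning ln x)
reconstructs a flexible causal effect curve. Nonlinearity is judged by a
trend test (slope of LACE on mean exposure) and a fractional-polynomial test
(best FP vs the linear model); pointwise significance of the reconstructed
curve follows the slope-sign rule: a point is flagged only when the slopes of
both confidence-band bounds share the sign of the estimated slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats as sps

from .linear_mr import two_stage_fit
from .observational import DEFAULT_ADJUSTMENT

__all__ = [
    "FP_POWERS",
    "FpModel",
    "NonlinearMrFit",
    "iv_free_exposure",
    "stratify_by_residual",
    "lace_estimates",
    "fp_derivative_basis",
    "fp_antiderivative_basis",
    "fp_meta_regression",
    "select_fp",
    "trend_test",
    "fp_test",
    "curve_with_significance",
    "nonlinear_mr_fit",
]

#: Conventional fractional-polynomial power set; 0 denotes ln x.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_Z95 = 1.959963984540054


@dataclass
class FpModel:
    """Weighted meta-regression of LACE on a fractional-polynomial derivative."""

    degree: int
    powers: tuple
    coefficients: np.ndarray
    cov: np.ndarray
    loglik: float
    mean_exposures: np.ndarray = field(repr=False, default=None)

    def derivative(self, x) -> np.ndarray:
        """Fitted effect-curve slope h'(x)."""
        return fp_derivative_basis(x, self.powers) @ self.coefficients

    def effect(self, x, reference: float) -> np.ndarray:
        """Fitted effect curve h(x) - h(reference)."""
        A = fp_antiderivative_basis(x, self.powers)
        A0 = fp_antiderivative_basis(np.atleast_1d(reference), self.powers)
        return (A - A0) @ self.coefficients


@dataclass
class NonlinearMrFit:
    """Full stratified nonlinear MR result."""

    strata: pd.DataFrame  # columns: stratum, n, mean_exposure, lace, se
    best_fp: FpModel
    linear_fp: FpModel
    trend_p: float
    fp_p: float
    curve: pd.DataFrame  # x, effect, lower, upper, slope, significant


def iv_free_exposure(exposure, grs) -> np.ndarray:
    """Residual of the exposure regressed on the score (intercept included)."""
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(grs, dtype=float)
    if np.std(z) == 0:
        raise ValueError("GRS is constant; cannot compute instrument-free exposure")
    zc = z - z.mean()
    slope = float(zc @ (x - x.mean()) / (zc @ zc))
    resid = x - x.mean() - slope * zc
    return resid


def stratify_by_residual(residuals, n_strata: int = 10) -> np.ndarray:
    """Rank-based partition into ``n_strata`` near-equal groups (0-indexed).

    Ties are broken by stable input order; group sizes differ by at most one,
    ordered smallest-residual-first. Centile stratification is
    ``n_strata=100``.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    if n < 10 * n_strata:
        raise ValueError(f"n={n} too small for {n_strata} strata (need >= {10 * n_strata})")
    if np.nanstd(r) == 0:
        warnings.warn("all residuals identical; stratifying by input order", stacklevel=2)
    order = np.argsort(r, kind="stable")
    assignment = np.empty(n, dtype=int)
    # first (n % n_strata) strata get the extra individual
    base, extra = divmod(n, n_strata)
    sizes = np.full(n_strata, base)
    sizes[:extra] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    for k in range(n_strata):
        assignment[order[edges[k]:edges[k + 1]]] = k
    return assignment


def lace_estimates(
    table: pd.DataFrame,
    grs,
    outcome: str,
    family: str,
    strata,
    adjust=DEFAULT_ADJUSTMENT,
    exposure: str = "ldl_c",
) -> pd.DataFrame:
    """Per-stratum linear two-stage MR estimates (LACE) with SEs.

    Returns a DataFrame (stratum, n, mean_exposure, lace, se), sorted by mean
    exposure. Degenerate strata (constant GRS/outcome, failed fit) are
    dropped with a warning; more than 20% degenerate raises.
    """
    grs = np.asarray(grs, dtype=float)
    strata = np.asarray(strata)
    labels = np.unique(strata)
    rows, dropped = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # stratum-level weak-instrument warnings
        for k in labels:
            mask = strata == k
            sub = table[mask]
            try:
                fit = two_stage_fit(sub, grs[mask], outcome, family, adjust, exposure)
            except Exception as exc:
                dropped.append((int(k), str(exc)))
                continue
            rows.append({
                "stratum": int(k), "n": fit.n,
                "mean_exposure": float(sub[exposure].mean()),
                "lace": fit.estimate, "se": fit.se,
            })
    if dropped:
        warnings.warn(f"dropped degenerate strata: {dropped}", stacklevel=2)
    if len(dropped) > 0.2 * len(labels):
        raise RuntimeError(
            f"{len(dropped)}/{len(labels)} strata degenerate; use fewer strata"
        )
    out = pd.DataFrame(rows).sort_values("mean_exposure", kind="mergesort")
    return out.reset_index(drop=True)


def _as_powers(powers) -> tuple:
    if np.isscalar(powers):
        powers = (powers,)
    return tuple(float(p) for p in powers)


def fp_derivative_basis(x, powers) -> np.ndarray:
    """Derivative terms of the fractional polynomial at x (> 0).

    Power p contributes d/dx x^p = p x^(p-1) (1/x for p = 0, i.e. ln x). A
    repeated power (p, p) contributes the derivative of x^p ln x, namely
    x^(p-1) (p ln x + 1), or 2 ln x / x when p = 0.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("fractional-polynomial exposure values must be positive")
    powers = _as_powers(powers)
    cols = []
    for j, p in enumerate(powers):
        repeated = j > 0 and p == powers[j - 1]
        if repeated:
            if p == 0:
                cols.append(2.0 * np.log(x) / x)
            else:
                cols.append(x ** (p - 1) * (p * np.log(x) + 1.0))
        elif p == 0:
            cols.append(1.0 / x)
        else:
            cols.append(p * x ** (p - 1))
    return np.column_stack(cols)


def fp_antiderivative_basis(x, powers) -> np.ndarray:
    """Antiderivatives matching :func:`fp_derivative_basis` term by term."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("fractional-polynomial exposure values must be positive")
    powers = _as_powers(powers)
    cols = []
    for j, p in enumerate(powers):
        repeated = j > 0 and p == powers[j - 1]
        if repeated:
            cols.append(np.log(x) ** 2 if p == 0 else x**p * np.log(x))
        else:
            cols.append(np.log(x) if p == 0 else x**p)
    return np.column_stack(cols)


def _wls_known_variance(y, X, se):
    w = 1.0 / se**2
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    try:
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular meta-regression basis") from exc
    beta = cov @ (Xw.T @ y)
    resid = y - X @ beta
    loglik = float(-0.5 * np.sum((resid / se) ** 2 + np.log(2 * np.pi * se**2)))
    return beta, cov, loglik


def fp_meta_regression(strata: pd.DataFrame, degree: int) -> FpModel:
    """Best-likelihood FP derivative model of the given degree.

    Fits, for every power combination (8 at degree 1; 36 at degree 2
    including repeats), the weighted least-squares regression of LACE on the
    derivative basis at the stratum mean exposures, weights 1/se^2, no
    intercept (the slope curve is fully parameterized by the FP derivative).
    The likelihood is weighted Gaussian with known variances se^2.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(strata) < degree + 2:
        raise ValueError(f"need at least {degree + 2} strata for degree {degree}")
    y = strata["lace"].to_numpy(dtype=float)
    x = strata["mean_exposure"].to_numpy(dtype=float)
    se = strata["se"].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("all stratum mean exposures equal; basis singular")
    combos = (
        [(p,) for p in FP_POWERS]
        if degree == 1
        else list(combinations_with_replacement(FP_POWERS, 2))
    )
    best = None
    for powers in combos:
        B = fp_derivative_basis(x, powers)
        if np.linalg.matrix_rank(B) < B.shape[1]:
            continue
        try:
            beta, cov, ll = _wls_known_variance(y, B, se)
        except ValueError:
            continue
        if best is None or ll > best.loglik:
            best = FpModel(degree, tuple(powers), beta, cov, ll, x)
    if best is None:
        raise ValueError("no fractional-polynomial model could be fitted")
    return best


def select_fp(strata: pd.DataFrame, degree_max: int = 2, alpha: float = 0.05) -> FpModel:
    """Best FP across degrees: degree 2 only if it beats the best degree-1
    model in a 1-df chi-square likelihood comparison at level ``alpha``."""
    best1 = fp_meta_regression(strata, 1)
    if degree_max == 1 or len(strata) < 4:
        return best1
    best2 = fp_meta_regression(strata, 2)
    stat = 2.0 * (best2.loglik - best1.loglik)
    if sps.chi2.sf(max(stat, 0.0), df=1) < alpha:
        return best2
    return best1


def linear_model(strata: pd.DataFrame) -> FpModel:
    """The linear reference model: degree-1 FP with power 1 (constant slope)."""
    y = strata["lace"].to_numpy(dtype=float)
    x = strata["mean_exposure"].to_numpy(dtype=float)
    se = strata["se"].to_numpy(dtype=float)
    B = fp_derivative_basis(x, (1.0,))
    beta, cov, ll = _wls_known_variance(y, B, se)
    return FpModel(1, (1.0,), beta, cov, ll, x)


def trend_test(strata: pd.DataFrame) -> float:
    """Inverse-variance-weighted meta-regression slope of LACE on mean
    exposure; two-sided normal p-value for the slope."""
    if len(strata) < 3:
        raise ValueError("trend test needs at least 3 strata")
    y = strata["lace"].to_numpy(dtype=float)
    x = strata["mean_exposure"].to_numpy(dtype=float)
    se = strata["se"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(x)), x])
    beta, cov, _ = _wls_known_variance(y, X, se)
    z = beta[1] / np.sqrt(cov[1, 1])
    return float(2 * sps.norm.sf(abs(z)))


def fp_test(best_fp: FpModel, linear_fit: FpModel) -> float:
    """Chi-square comparison of the best FP against the linear model.

    df = 1 for a degree-1 model with a non-unit power, 2 for a degree-2
    model; if the best model *is* the linear model the p-value is 1.
    """
    if best_fp.degree == 1 and best_fp.powers == (1.0,):
        return 1.0
    stat = max(0.0, 2.0 * (best_fp.loglik - linear_fit.loglik))
    df = 1 if best_fp.degree == 1 else 2
    return float(sps.chi2.sf(stat, df=df))


def curve_with_significance(
    best_fp: FpModel,
    grid,
    alpha: float = 0.05,
    reference: float | None = None,
) -> pd.DataFrame:
    """Effect curve h(x) with pointwise bands and slope-sign significance.

    The curve is the antiderivative of the fitted slope model, anchored at
    ``reference`` (default: the central stratum mean). Pointwise CIs come
    from the delta method on the meta-regression coefficients. A grid point
    is flagged significant only when the slopes of both confidence-band
    bounds share the sign of the estimated slope there (numerical slopes on
    the evaluation grid).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid must be positive")
    xm = best_fp.mean_exposures
    if xm is not None:
        lo, hi = xm.min(), xm.max()
        pad = 0.10 * (hi - lo)
        if grid.min() < lo - pad or grid.max() > hi + pad:
            warnings.warn(
                "grid extends beyond the stratum-mean range; curve is an "
                "extrapolation there", stacklevel=2,
            )
    if reference is None:
        reference = float(np.median(xm)) if xm is not None else float(np.median(grid))
    if not (grid.min() <= reference <= grid.max()):
        raise ValueError(f"reference {reference} outside the evaluation grid")

    z = sps.norm.ppf(1 - alpha / 2)
    A = fp_antiderivative_basis(grid, best_fp.powers)
    A0 = fp_antiderivative_basis(np.array([reference]), best_fp.powers)
    D = A - A0
    eff = D @ best_fp.coefficients
    var = np.einsum("ij,jk,ik->i", D, best_fp.cov, D)
    se = np.sqrt(np.clip(var, 0.0, None))
    lower, upper = eff - z * se, eff + z * se

    slope = best_fp.derivative(grid)
    lower_slope = np.gradient(lower, grid)
    upper_slope = np.gradient(upper, grid)
    significant = ((slope > 0) & (lower_slope > 0) & (upper_slope > 0)) | (
        (slope < 0) & (lower_slope < 0) & (upper_slope < 0)
    )
    out = pd.DataFrame({
        "x": grid, "effect": eff, "lower": lower, "upper": upper,
        "slope": slope, "significant": significant,
    })
    out.attrs["reference_x"] = float(reference)
    return out


def nonlinear_mr_fit(
    table: pd.DataFrame,
    grs,
    outcome: str,
    family: str = "logistic",
    adjust=DEFAULT_ADJUSTMENT,
    exposure: str = "ldl_c",
    n_strata: int = 10,
    degree_max: int = 2,
    grid_points: int = 50,
) -> NonlinearMrFit:
    """Run the full stratified nonlinear MR analysis.

    Complete cases on the model columns are stratified on the
    instrument-free exposure; per-stratum LACE values feed the FP
    meta-regression, the trend and FP nonlinearity tests, and the
    reconstructed effect curve with slope-sign significance flags.
    """
    adjust = [c for c in adjust if c != exposure]
    table = table.copy()
    table["_grs"] = np.asarray(grs, dtype=float)
    need = [outcome, exposure, "_grs", *adjust, "sex", "age"]
    need = list(dict.fromkeys(c for c in need if c in table.columns or c == "_grs"))
    data = table[table[need].notna().all(axis=1)].reset_index(drop=True)

    resid = iv_free_exposure(data[exposure].to_numpy(), data["_grs"].to_numpy())
    strata_idx = stratify_by_residual(resid, n_strata)
    strata = lace_estimates(
        data, data["_grs"].to_numpy(), outcome, family, strata_idx, adjust, exposure
    )
    best = select_fp(strata, degree_max=degree_max)
    lin = linear_model(strata)
    xm = strata["mean_exposure"].to_numpy()
    grid = np.linspace(xm.min(), xm.max(), grid_points)
    curve = curve_with_significance(best, grid)
    return NonlinearMrFit(
        strata=strata, best_fp=best, linear_fp=lin,
        trend_p=trend_test(strata), fp_p=fp_test(best, lin), curve=curve,
    )
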