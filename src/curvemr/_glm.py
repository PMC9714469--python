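"""Internal thin wrappers around statsmodels fits.

These helpers work on plain numpy design matrices so that the simulation-heavy
code paths (stratum-level estimates, repeated-seed calibrations) avoid the
overhead of formula handling. All public modules go through these.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CollinearityError",
    "SeparationError",
    "add_intercept",
    "check_full_rank",
    "fit_ols",
    "fit_logistic",
]


class CollinearityError(ValueError):
    """Design matrix is rank-deficient; the message names the offending column."""


class SeparationError(ValueError):
    """Logistic fit failed due to (quasi-)separation or non-convergence."""


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise CollinearityError naming a column whose removal restores full rank."""
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    names = names or [f"column_{j}" for j in range(X.shape[1])]
    # identify a redundant column: dropping it should not reduce the rank
    for j in range(X.shape[1] - 1, -1, -1):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            raise CollinearityError(
                f"design matrix is collinear; column {names[j]!r} is redundant"
            )
    raise CollinearityError("design matrix is collinear")


def fit_ols(y: np.ndarray, X: np.ndarray, names: list[str] | None = None):
    check_full_rank(X, names)
    return sm.OLS(np.asarray(y, float), np.asarray(X, float)).fit()


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str] | None = None):
    y = np.asarray(y, float)
    if y.min() == y.max():
        raise SeparationError("outcome does not vary; cannot fit a logistic model")
    check_full_rank(X, names)
    try:
        res = sm.Logit(y, np.asarray(X, float)).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        raise SeparationError(
            "logistic fit failed (possible separation); consider removing sparse "
            f"covariates or merging strata: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True) or not np.all(
        np.isfinite(res.bse)
    ):
        raise SeparationError(
            "logistic fit did not converge (possible separation); consider "
            "removing sparse covariates or merging strata"
        )
    return res
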