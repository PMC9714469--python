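"""Two-stage linear Mendelian randomization with a genetic risk score.

Stage 1 regresses the exposure on the score plus sex, age and age squared by
least squares; stage 2 regresses the outcome on the stage-1 fitted exposure
(predictor substitution) plus the observational adjustment set, logistic for
binary outcomes and linear for continuous ones. The stage-1 partial
F-statistic for the score must exceed 10 for the instrument to be considered
valid. Stage-2 standard errors are model-based by default; an individual-level
bootstrap is available for uncertainty that accounts for stage-1 estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._glm import fit_logistic, fit_ols
from .cohort import SubgroupSpec, apply_subgroup
from .instruments import instrument_strength
from .observational import DEFAULT_ADJUSTMENT

__all__ = ["TwoStageFit", "two_stage_fit", "wald_ratio", "mr_subgroup_table"]

FIRST_STAGE_ADJUSTMENT = ("sex", "age")  # age^2 added internally


@dataclass
class TwoStageFit:
    """Two-stage MR estimate of the causal effect per unit exposure."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    family: str
    f_statistic: float
    r2: float
    weak_instrument: bool
    fitted_exposure: np.ndarray = field(repr=False, default=None)
    first_stage_params: np.ndarray = field(repr=False, default=None)

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.estimate)) if self.family == "logistic" else None

    @property
    def or_ci(self) -> tuple[float, float] | None:
        if self.family != "logistic":
            return None
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _first_stage_design(data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    # a stratification variable (e.g. sex in a sex-specific subgroup) has no
    # variation and would be collinear with the intercept
    cols = [c for c in FIRST_STAGE_ADJUSTMENT
            if c in data.columns and data[c].nunique(dropna=True) > 1]
    mats, names = [], []
    for c in cols:
        mats.append(data[c].to_numpy(dtype=float))
        names.append(c)
        if c == "age":
            mats.append(data[c].to_numpy(dtype=float) ** 2)
            names.append("age2")
    return (np.column_stack(mats) if mats else None), names


def two_stage_fit(
    table: pd.DataFrame,
    grs,
    outcome: str,
    family: str = "logistic",
    adjust=DEFAULT_ADJUSTMENT,
    exposure: str = "ldl_c",
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> TwoStageFit:
    """Two-stage MR estimate of the exposure's effect on the outcome.

    ``grs`` is the per-individual score aligned with ``table`` rows. With
    ``n_bootstrap > 0`` the SE/CI come from an individual-level bootstrap
    (seeded) instead of the stage-2 model.
    """
    adjust = [c for c in adjust if c not in (exposure,)]
    table = table.copy()
    table["_grs"] = np.asarray(grs, dtype=float)
    need = [outcome, exposure, "_grs", *adjust]
    need += [c for c in FIRST_STAGE_ADJUSTMENT if c in table.columns and c not in need]
    data = table[table[need].notna().all(axis=1)]
    n = len(data)
    z = data["_grs"].to_numpy()
    if np.std(z) == 0:
        raise ValueError("GRS has zero variance in the analysis sample")

    x = data[exposure].to_numpy(dtype=float)
    C1, names1 = _first_stage_design(data)
    f_stat, r2, weak = instrument_strength(x, z, C1, names1)
    if weak:
        warnings.warn(
            f"weak instrument: first-stage F = {f_stat:.2f} <= 10", stacklevel=2
        )

    X1 = np.column_stack([np.ones(n), z]) if C1 is None else np.column_stack(
        [np.ones(n), z, C1]
    )
    stage1 = fit_ols(x, X1, ["intercept", "grs", *names1])
    xhat = np.asarray(stage1.fittedvalues)

    C2 = data[list(adjust)].to_numpy(dtype=float) if adjust else np.empty((n, 0))
    X2 = np.column_stack([np.ones(n), xhat, C2])
    names2 = ["intercept", "fitted_exposure", *adjust]
    y = data[outcome].to_numpy(dtype=float)
    res2 = fit_logistic(y, X2, names2) if family == "logistic" else fit_ols(y, X2, names2)
    est, se = float(res2.params[1]), float(res2.bse[1])

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                s1 = fit_ols(x[idx], X1[idx])
                Xb = np.column_stack([np.ones(n), np.asarray(s1.fittedvalues), C2[idx]])
                yb = y[idx]
                rb = fit_logistic(yb, Xb) if family == "logistic" else fit_ols(yb, Xb)
                reps.append(float(rb.params[1]))
            except Exception:
                continue
        if len(reps) >= max(50, n_bootstrap // 2):
            se = float(np.std(reps, ddof=1))

    zcrit = 1.959963984540054
    p = 2 * sps.norm.sf(abs(est / se))
    return TwoStageFit(
        estimate=est, se=se, ci_low=est - zcrit * se, ci_high=est + zcrit * se,
        p=float(p), n=n, family=family, f_statistic=f_stat, r2=r2,
        weak_instrument=weak, fitted_exposure=xhat,
        first_stage_params=np.asarray(stage1.params),
    )


def wald_ratio(beta_yg: float, beta_xg: float, se_yg: float | None = None,
               se_xg: float | None = None) -> tuple[float, float | None]:
    """Single-instrument ratio estimate beta_yg / beta_xg.

    Returns (estimate, se) with the first-order delta-method SE when both
    input SEs are supplied (treating beta_xg as estimated without error in the
    leading term plus the second-order contribution).
    """
    if beta_xg == 0:
        raise ZeroDivisionError("exposure-on-instrument coefficient is zero")
    est = beta_yg / beta_xg
    se = None
    if se_yg is not None and se_xg is not None:
        se = float(np.sqrt(
            se_yg**2 / beta_xg**2 + beta_yg**2 * se_xg**2 / beta_xg**4
        ))
    return float(est), se


def mr_subgroup_table(
    table: pd.DataFrame,
    grs,
    outcomes: dict[str, str],
    subgroups: dict[str, SubgroupSpec],
    adjust=DEFAULT_ADJUSTMENT,
    exposure: str = "ldl_c",
    min_cases: int = 200,
) -> pd.DataFrame:
    """One two-stage MR row per (outcome, subgroup), forest-plot ready.

    ``outcomes`` maps outcome column to family; ``subgroups`` maps a label to
    its :class:`~curvemr.cohort.SubgroupSpec`. Per-subgroup F and R^2 are
    recomputed. Empty or failing subgroups yield an NA row with the reason.
    """
    grs = np.asarray(grs, dtype=float)
    table = table.copy()
    table["_grs_row"] = grs
    rows = []
    for oname, family in outcomes.items():
        fbg_adjust = list(adjust)
        if oname == "fbg" and "hypoglycemic_drug_use" in table.columns:
            fbg_adjust.append("hypoglycemic_drug_use")
        for sname, spec in subgroups.items():
            sub = apply_subgroup(table, spec)
            base = {"outcome": oname, "subgroup": sname, "n": len(sub)}
            if len(sub) == 0:
                rows.append({**base, "note": "empty subgroup"})
                continue
            if len(sub) < min_cases:
                warnings.warn(
                    f"subgroup {sname!r} has only {len(sub)} rows", stacklevel=2
                )
            # covariates with no variation in the subgroup (e.g. sex after
            # sex-stratification) would make the design collinear
            sub_adjust = [
                c for c in fbg_adjust
                if not (c in sub.columns and sub[c].nunique(dropna=True) <= 1)
            ]
            try:
                fit = two_stage_fit(
                    sub, sub["_grs_row"].to_numpy(), oname, family,
                    sub_adjust, exposure,
                )
            except Exception as exc:
                rows.append({**base, "note": f"fit failed: {exc}"})
                continue
            rows.append({
                **base, "n": fit.n, "F": fit.f_statistic, "R2": fit.r2,
                "estimate": fit.estimate, "se": fit.se,
                "OR": fit.odds_ratio if family == "logistic" else np.nan,
                "CI_low": fit.ci_low, "CI_high": fit.ci_high, "p": fit.p,
                "note": "weak instrument" if fit.weak_instrument else "",
            })
    return pd.DataFrame(rows)
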