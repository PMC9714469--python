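"""One-command orchestration of the full analysis.

Stages run in the analysis order: cleaning -> instrument construction ->
descriptive summary -> observational linear + spline models -> linear MR
(overall and subgroups) -> stratified nonlinear MR -> analytic power, with a
provenance record (config, seeds, library versions, per-stage sample sizes).
A stage failure aborts the run naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    SubgroupSpec, derive_outcomes, drop_sparse_columns, mask_outliers,
    read_cohort, summarize_by_outcome, summary_to_json,
)
from .instruments import (
    compute_grs, harmonize_weights, instrument_strength, read_genotypes,
    read_gwas, select_instruments, variant_qc,
)
from .linear_mr import mr_subgroup_table
from .nonlinear_mr import nonlinear_mr_fit
from .observational import (
    DEFAULT_ADJUSTMENT, FBG_EXTRA_ADJUSTMENT, fit_adjusted_glm,
    rcs_effect_curve, select_knots_aic,
)
from .power import mr_power_binary, mr_power_continuous
from .simulate import preset, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STANDARD_SUBGROUPS"]

OUTLIER_COLUMNS = ("ldl_c", "fbg", "ogtt_2h", "sbp", "dbp", "bmi")

STANDARD_SUBGROUPS = {
    "all": SubgroupSpec(),
    "no lipid-lowering": SubgroupSpec(lipid_lowering_filter="non-users"),
    "female, no lipid-lowering": SubgroupSpec(
        sex_filter="female", lipid_lowering_filter="non-users"
    ),
    "never smokers, no lipid-lowering": SubgroupSpec(
        smoking_filter="never", lipid_lowering_filter="non-users"
    ),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Everything one run needs; either a scenario name or real input paths."""

    out_dir: str
    scenario: str | None = None
    n_individuals: int | None = None
    cohort_path: str | None = None
    dosage_path: str | None = None
    variants_path: str | None = None
    gwas_path: str | None = None
    outcomes: tuple = ("diabetes", "fbg")
    seed: int = 0
    n_strata: int = 10
    degree_max: int = 2
    k_candidates: tuple = (3, 4, 5)
    p_max: float = 5e-8
    r2_tier1: float = 0.001
    window_tier1: int = 1_000_000
    r2_tier2: float = 0.1
    call_rate_min: float = 0.999
    hwe_alpha: float = 1e-4
    sensitivity_fbg: bool = False  # exclude known diabetes / drug use for FBG
    grid_points: int = 60
    max_missing: float = 0.10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("outcomes", "k_candidates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        real = [self.cohort_path, self.dosage_path, self.variants_path, self.gwas_path]
        if self.scenario is not None and any(p is not None for p in real):
            raise PipelineError("config: give either a scenario or input paths, not both")
        if self.scenario is None and any(p is None for p in real):
            missing = [n for n, p in zip(
                ("cohort_path", "dosage_path", "variants_path", "gwas_path"), real
            ) if p is None]
            raise PipelineError(f"config: missing input paths {missing} and no scenario")
        for oc in self.outcomes:
            if oc not in ("diabetes", "fbg"):
                raise PipelineError(f"config: unknown outcome {oc!r}")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("load")
def _load(cfg: RunConfig):
    if cfg.scenario is not None:
        kw = {"seed": cfg.seed}
        if cfg.n_individuals:
            kw["n_individuals"] = cfg.n_individuals
        sim = simulate_cohort(preset(cfg.scenario, **kw))
        return sim.table, sim.genotypes, sim.gwas, sim
    table = read_cohort(cfg.cohort_path)
    genotypes = read_genotypes(cfg.dosage_path, cfg.variants_path)
    gwas = read_gwas(cfg.gwas_path)
    return table, genotypes, gwas, None


@_stage("clean")
def _clean(cfg: RunConfig, table: pd.DataFrame, simulated: bool):
    cols = [c for c in OUTLIER_COLUMNS if c in table.columns]
    table, reports = mask_outliers(table, cols)
    table = drop_sparse_columns(table, cfg.max_missing)
    if not simulated:
        table = derive_outcomes(table)
    return table, reports


@_stage("instruments")
def _instruments(cfg: RunConfig, table, genotypes, gwas):
    genotypes, qc_report = variant_qc(genotypes, cfg.call_rate_min, cfg.hwe_alpha)
    selected = select_instruments(
        gwas, genotypes, cfg.p_max, cfg.r2_tier1, cfg.window_tier1, cfg.r2_tier2
    )
    kept, weights = harmonize_weights(gwas, genotypes, selected)
    grs = compute_grs(genotypes, kept, weights)
    cov = np.column_stack([
        table["sex"].to_numpy(float), table["age"].to_numpy(float),
        table["age"].to_numpy(float) ** 2,
    ])
    f_stat, r2, weak = instrument_strength(
        table["ldl_c"].to_numpy(float), grs, cov, ["sex", "age", "age2"]
    )
    inst = pd.DataFrame({"id": kept, "weight": weights})
    return grs, inst, qc_report, {"F": f_stat, "R2": r2, "weak_instrument": weak}


def _adjust_for(outcome: str, cfg: RunConfig):
    adj = list(DEFAULT_ADJUSTMENT)
    # the drug-use covariate is constant (all zero) in the sensitivity subset
    if outcome == "fbg" and not cfg.sensitivity_fbg:
        adj += list(FBG_EXTRA_ADJUSTMENT)
    return adj


def _analysis_table(cfg: RunConfig, table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    if outcome == "fbg" and cfg.sensitivity_fbg:
        mask = ~((table.get("diabetes") == 1) | (table.get("hypoglycemic_drug_use") == 1))
        logger.info("FBG sensitivity analysis: %d of %d rows kept", mask.sum(), len(table))
        return table[mask]
    return table


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Returns a dict of the principal in-memory results. Written files:
    cohort.tsv, instruments.tsv, grs.tsv, summary.tsv/json,
    observational_<outcome>.json, rcs_curve_<outcome>.tsv, mr_linear.tsv,
    nlmr_strata_<outcome>.tsv, nlmr_tests_<outcome>.json,
    nlmr_curve_<outcome>.tsv, power.json, provenance.json.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": {},
    }
    results: dict = {}

    table, genotypes, gwas, sim = _load(cfg)
    provenance["stages"]["load"] = {"n": len(table), "variants": genotypes.n_variants}

    table, outlier_reports = _clean(cfg, table, simulated=sim is not None)
    table = table.reset_index(drop=True)
    table.to_csv(out / "cohort.tsv", sep="\t", index=False, na_rep="NA")
    provenance["stages"]["clean"] = {
        "n": len(table),
        "outlier_cells": int(sum(len(r.flagged_ids) for r in outlier_reports)),
    }

    grs, inst, qc_report, strength = _instruments(cfg, table, genotypes, gwas)
    inst.to_csv(out / "instruments.tsv", sep="\t", index=False)
    pd.DataFrame({"grs": grs}).to_csv(out / "grs.tsv", sep="\t", index=False)
    results["instrument_strength"] = strength
    provenance["stages"]["instruments"] = {
        "selected": len(inst), "dropped_qc": int(qc_report["dropped"].sum()), **strength,
    }

    summary = summarize_by_outcome(table)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    summary_to_json(summary, out / "summary.json")
    results["summary"] = summary

    families = {"diabetes": "logistic", "fbg": "linear"}
    results["observational"] = {}
    results["nonlinear_mr"] = {}
    for outcome in cfg.outcomes:
        family = families[outcome]
        adj = _adjust_for(outcome, cfg)
        atab = _analysis_table(cfg, table, outcome)
        try:
            lin = fit_adjusted_glm(atab, outcome, "ldl_c", adj, family)
            rcs = select_knots_aic(atab, outcome, "ldl_c", adj, family, cfg.k_candidates)
            xs = atab["ldl_c"].dropna()
            grid = np.linspace(xs.quantile(0.02), xs.quantile(0.98), cfg.grid_points)
            curve = rcs_effect_curve(rcs, float(xs.median()), grid)
        except Exception as exc:
            raise PipelineError(f"stage 'observational:{outcome}' failed: {exc}") from exc
        curve.to_csv(out / f"rcs_curve_{outcome}.tsv", sep="\t", index=False)
        obs = {
            "estimate": lin.estimate, "se": lin.se, "p": lin.p, "n": lin.n,
            "odds_ratio": lin.odds_ratio, "knot_count": rcs.knot_count,
            "aic": rcs.aic, "nonlinearity_p": rcs.nonlinearity_p,
            "curve_argmin_x": curve.attrs["argmin_x"],
        }
        with open(out / f"observational_{outcome}.json", "w") as fh:
            json.dump(obs, fh, indent=1)
        results["observational"][outcome] = obs
        provenance["stages"][f"observational:{outcome}"] = {"n": lin.n, "adjustment": adj}

        try:
            nl = nonlinear_mr_fit(
                atab, np.asarray(grs)[atab.index], outcome, family, adj,
                n_strata=cfg.n_strata, degree_max=cfg.degree_max,
                grid_points=cfg.grid_points,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'nonlinear_mr:{outcome}' failed: {exc}") from exc
        nl.strata.to_csv(out / f"nlmr_strata_{outcome}.tsv", sep="\t", index=False)
        nl.curve.to_csv(out / f"nlmr_curve_{outcome}.tsv", sep="\t", index=False)
        tests = {
            "trend_p": nl.trend_p, "fp_p": nl.fp_p,
            "best_degree": nl.best_fp.degree,
            "best_powers": list(nl.best_fp.powers),
        }
        with open(out / f"nlmr_tests_{outcome}.json", "w") as fh:
            json.dump(tests, fh, indent=1)
        results["nonlinear_mr"][outcome] = nl
        provenance["stages"][f"nonlinear_mr:{outcome}"] = {
            "n": int(nl.strata["n"].sum()), "strata": len(nl.strata), **tests,
        }

    try:
        forest = mr_subgroup_table(
            table, grs, {oc: families[oc] for oc in cfg.outcomes}, STANDARD_SUBGROUPS
        )
    except Exception as exc:
        raise PipelineError(f"stage 'linear_mr' failed: {exc}") from exc
    forest.to_csv(out / "mr_linear.tsv", sep="\t", index=False)
    results["linear_mr"] = forest
    provenance["stages"]["linear_mr"] = {"rows": len(forest)}

    power = {}
    if "diabetes" in cfg.outcomes:
        row = forest[(forest["outcome"] == "diabetes") & (forest["subgroup"] == "all")]
        if len(row) and np.isfinite(row.iloc[0].get("estimate", np.nan)):
            k = float(table["diabetes"].mean())
            or_sd = float(np.exp(row.iloc[0]["estimate"] * table["ldl_c"].std()))
            power["diabetes"] = asdict(mr_power_binary(
                int(row.iloc[0]["n"]), strength["R2"], or_sd, k
            ))
    if "fbg" in cfg.outcomes:
        row = forest[(forest["outcome"] == "fbg") & (forest["subgroup"] == "all")]
        if len(row) and np.isfinite(row.iloc[0].get("estimate", np.nan)):
            beta_std = float(
                row.iloc[0]["estimate"] * table["ldl_c"].std() / table["fbg"].std()
            )
            power["fbg"] = asdict(mr_power_continuous(
                int(row.iloc[0]["n"]), strength["R2"], beta_std
            ))
    with open(out / "power.json", "w") as fh:
        json.dump(power, fh, indent=1)
    results["power"] = power

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)
    results["provenance"] = provenance
    return results


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "curvemr": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
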