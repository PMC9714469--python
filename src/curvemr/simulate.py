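"""Synthetic cohorts with known causal structure.

Every downstream stage is exercised against data whose ground truth is known:
biallelic genotypes in Hardy-Weinberg equilibrium, an exposure driven by a
genetic score (a few percent of variance, calibrated to a target share), a
standard-normal confounder acting on exposure and outcomes, drug-use flags
correlated with both, a logistic disease liability and a Gaussian continuous
outcome, with configurable causal shapes (null / linear / quadratic-U).

The ``nonmonotone`` confounder coupling manufactures a *spurious* U: the
confounder U contributes linearly to the exposure but enters the outcome
liability through (U^2 - 1)/sqrt(2). Conditional on the exposure the expected
value of U^2 is a quadratic function of the exposure, so the observational
exposure-outcome curve is U-shaped even when the causal curve is flat or
linear — while the genotypes stay independent of U, leaving MR unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import derive_hypertension
from .instruments import GenotypeMatrix

__all__ = [
    "SimulationScenario",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "calibrate_weights",
    "preset_scenarios",
    "preset",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of one synthetic cohort.

    Causal coefficients act on the centred exposure: the binary-outcome
    liability is ``outcome_intercept + c1*(X - mean) + c2*(X - mean)^2`` plus
    the confounder term, so ``outcome_intercept`` is the log-odds at the mean
    exposure and ``c1``/``c2`` keep separate interpretations. The continuous
    outcome (fasting glucose) uses its own coefficients on the same pattern.
    """

    name: str = "custom"
    n_individuals: int = 4876
    n_variants: int = 30
    maf_range: tuple = (0.10, 0.45)
    weight_scale: float | None = None  # per-allele effect (mmol/L); None -> calibrated
    grs_variance_share: float = 0.049  # target share of exposure variance
    exposure_mean: float = 3.2  # mmol/L, matching the observed median LDL-C
    exposure_sd: float = 0.8
    causal_shape: str = "null"  # null | linear | quadratic
    outcome_intercept: float = float(logit(0.24))  # log-odds at mean exposure
    c1: float = 0.0  # log-odds per mmol/L
    c2: float = 0.0  # log-odds per (mmol/L)^2, centred at the mean
    confounder_effect_on_exposure: float = 0.0  # mmol/L per SD of U
    confounder_effect_on_outcome: float = 0.0  # log-odds per SD of the coupling term
    confounder_coupling: str = "linear"  # linear | nonmonotone (U^2 form)
    fbg_intercept: float = 5.6  # mmol/L
    fbg_c1: float = 0.0  # mmol/L FBG per mmol/L exposure
    fbg_c2: float = 0.0
    confounder_effect_on_fbg: float = 0.0
    fbg_noise_sd: float = 0.8
    drug_use_model: tuple = (-2.3, 0.25, 0.3)  # logit: intercept, per mmol/L, per SD U
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.causal_shape == "null" and (self.c1 != 0 or self.c2 != 0):
            raise ValueError("null causal shape requires c1 = c2 = 0")
        if self.causal_shape == "linear" and self.c2 != 0:
            raise ValueError("linear causal shape requires c2 = 0")
        if self.causal_shape not in ("null", "linear", "quadratic"):
            raise ValueError(f"unknown causal shape {self.causal_shape!r}")
        if self.confounder_coupling not in ("linear", "nonmonotone"):
            raise ValueError(f"unknown coupling {self.confounder_coupling!r}")
        if not (0 <= self.grs_variance_share < 1):
            raise ValueError("grs_variance_share must lie in [0, 1)")


@dataclass
class SimulatedCohort:
    """Cohort + genotypes + ground truth from one scenario realization."""

    table: pd.DataFrame
    genotypes: GenotypeMatrix
    true_weights: np.ndarray
    grs: np.ndarray  # true-weight score
    gwas: pd.DataFrame  # summary-statistics stand-in carrying the weights
    true_parameters: SimulationScenario
    true_curve: pd.DataFrame  # x, effect (binary log-odds), fbg_effect
    grs_variance_share: float  # realized Var(genetic X)/Var(X)


def simulate_genotypes(n: int, m: int, mafs, seed=None) -> GenotypeMatrix:
    """Independent biallelic dosages, column j ~ Binomial(2, maf_j).

    Variant positions are spaced 2.5 Mb apart (round-robin over chromosomes
    1-22) so that default 1 Mb-window clumping never removes a variant on
    positional grounds alone.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.asarray(mafs, dtype=float)
    if len(mafs) != m:
        raise ValueError(f"expected {m} allele frequencies, got {len(mafs)}")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("allele frequencies must lie in (0, 0.5]")
    dosage = rng.binomial(2, mafs, size=(n, m)).astype(float)
    variants = pd.DataFrame({
        "id": [f"sv{j:04d}" for j in range(m)],
        "chromosome": [(j % 22) + 1 for j in range(m)],
        "position": [1_000_000 + (j // 22) * 2_500_000 for j in range(m)],
        "counted_allele": ["A"] * m,
        "other_allele": ["G"] * m,
    })
    return GenotypeMatrix(dosage, variants)


def calibrate_weights(mafs, raw_weights, target_var: float) -> np.ndarray:
    """Rescale per-allele weights so the score's variance hits ``target_var``.

    Under HWE with independent variants Var(GRS) = sum_j w_j^2 2 maf_j (1-maf_j);
    the raw weight profile is kept, only its overall scale changes.
    """
    mafs = np.asarray(mafs, dtype=float)
    w = np.asarray(raw_weights, dtype=float)
    var_unit = float(np.sum(w**2 * 2 * mafs * (1 - mafs)))
    if var_unit <= 0:
        raise ValueError("raw weights give a zero-variance score")
    return w * np.sqrt(target_var / var_unit)


def simulate_cohort(scenario: SimulationScenario) -> SimulatedCohort:
    """Generate one cohort realization (bit-for-bit reproducible per seed)."""
    s = scenario
    rng = np.random.default_rng(s.seed)
    n, m = s.n_individuals, s.n_variants

    mafs = rng.uniform(*s.maf_range, size=m)
    genotypes = simulate_genotypes(n, m, mafs, rng)

    # per-allele effects: varied profile, rescaled to the target variance share
    raw = np.abs(rng.normal(1.0, 0.3, size=m)) + 0.05
    target_var = s.grs_variance_share * s.exposure_sd**2
    if s.weight_scale is not None:
        weights = np.full(m, s.weight_scale)
        target_var = float(np.sum(weights**2 * 2 * mafs * (1 - mafs)))
    else:
        weights = calibrate_weights(mafs, raw, target_var)

    gamma = s.confounder_effect_on_exposure
    eps_var = s.exposure_sd**2 - target_var - gamma**2
    if eps_var <= 0:
        raise ValueError(
            "requested GRS share plus confounder variance exceeds the total "
            f"exposure variance ({s.exposure_sd**2:.3f})"
        )

    genetic = (genotypes.dosage - 2 * mafs) @ weights
    confounder = rng.normal(0.0, 1.0, size=n)
    eps = rng.normal(0.0, np.sqrt(eps_var), size=n)
    x = s.exposure_mean + genetic + gamma * confounder + eps
    x = np.clip(x, 0.1, None)  # FP powers need a positive exposure
    xc = x - s.exposure_mean

    coupling = (
        confounder
        if s.confounder_coupling == "linear"
        else (confounder**2 - 1.0) / np.sqrt(2.0)
    )
    eta = (
        s.outcome_intercept + s.c1 * xc + s.c2 * xc**2
        + s.confounder_effect_on_outcome * coupling
    )
    diabetes = rng.binomial(1, expit(eta)).astype(float)

    fbg = (
        s.fbg_intercept + s.fbg_c1 * xc + s.fbg_c2 * xc**2
        + s.confounder_effect_on_fbg * coupling
        + rng.normal(0.0, s.fbg_noise_sd, size=n)
    )
    fbg = np.clip(fbg, 0.5, None)

    a0, ax, au = s.drug_use_model
    lipid_drug = rng.binomial(1, expit(a0 + ax * xc + au * confounder)).astype(float)
    hypo_drug = np.where(
        diabetes == 1, rng.binomial(1, 0.5, size=n), rng.binomial(1, 0.02, size=n)
    ).astype(float)
    self_report = np.where(
        diabetes == 1, rng.binomial(1, 0.58, size=n), 0.0
    ).astype(float)

    sex = rng.binomial(1, 0.372, size=n).astype(float)  # 1 = male
    age = np.clip(rng.normal(56.0, 8.0, size=n), 35.0, 90.0)
    zb = rng.normal(size=n)
    bmi = 25.8 + 2.8 * (0.3 * confounder + np.sqrt(1 - 0.09) * zb)
    zs = rng.normal(size=n)
    sbp = 132.0 + 15.0 * (0.2 * confounder + 0.2 * (age - 56) / 8 + 0.94 * zs)
    dbp = 75.0 + 9.0 * (0.5 * zs + np.sqrt(0.75) * rng.normal(size=n))
    smoker_p = np.where(sex == 1, 0.64, 0.033)
    ever_smoker = rng.binomial(1, smoker_p).astype(float)
    family_history = rng.binomial(1, 0.28, size=n).astype(float)
    dyslipidemia = rng.binomial(1, 0.30, size=n).astype(float)
    chd = rng.binomial(1, expit(-2.2 + 0.15 * confounder), size=n).astype(float)
    self_report_htn = rng.binomial(1, 0.15, size=n).astype(float)
    antihtn = rng.binomial(1, 0.12, size=n).astype(float)

    table = pd.DataFrame({
        "individual_id": [f"id{i:06d}" for i in range(n)],
        "sex": sex, "age": age, "bmi": bmi,
        "ldl_c": x, "fbg": fbg, "ogtt_2h": np.clip(1.1 * fbg + rng.normal(0, 1.5, n), 0.5, None),
        "sbp": sbp, "dbp": dbp,
        "self_report_diabetes": self_report,
        "hypoglycemic_drug_use": hypo_drug,
        "lipid_lowering_drug_use": lipid_drug,
        "self_report_hypertension": self_report_htn,
        "antihypertensive_use": antihtn,
        "diabetes_family_history": family_history,
        "chd": chd, "dyslipidemia": dyslipidemia,
        "ever_smoker": ever_smoker,
        "diabetes": diabetes,
        "confounder": confounder,  # latent; kept for diagnostics, not adjustment
    })
    table["hypertension"] = derive_hypertension(table)

    grid = np.linspace(
        max(0.2, s.exposure_mean - 2.5 * s.exposure_sd),
        s.exposure_mean + 2.5 * s.exposure_sd, 101,
    )
    gc = grid - s.exposure_mean
    true_curve = pd.DataFrame({
        "x": grid,
        "effect": s.c1 * gc + s.c2 * gc**2,  # log-odds relative to the mean
        "fbg_effect": s.fbg_c1 * gc + s.fbg_c2 * gc**2,
    })

    gwas = pd.DataFrame({
        "SNP": genotypes.variants["id"],
        "CHR": genotypes.variants["chromosome"],
        "BP": genotypes.variants["position"],
        "EA": genotypes.variants["counted_allele"],
        "NEA": genotypes.variants["other_allele"],
        "BETA": weights,
        "SE": np.maximum(np.abs(weights) / 8.0, 1e-4),
        "P": np.full(m, 1e-30),
    })

    realized = float(np.var(genetic) / np.var(x)) if np.var(x) > 0 else 0.0
    return SimulatedCohort(
        table=table, genotypes=genotypes, true_weights=weights,
        grs=genotypes.dosage @ weights, gwas=gwas, true_parameters=s,
        true_curve=true_curve, grs_variance_share=realized,
    )


_PRESETS: dict[str, SimulationScenario] = {
    # no causal effect, no confounding: every analysis should be null
    "NULL": SimulationScenario(name="NULL", causal_shape="null"),
    # constant protective log-odds ln(0.44) per mmol/L, matching the female
    # MR regime; continuous outcome slope -0.14 mmol/L FBG per mmol/L
    "LINEAR_PROTECTIVE": SimulationScenario(
        name="LINEAR_PROTECTIVE", causal_shape="linear",
        c1=float(np.log(0.44)), fbg_c1=-0.14,
    ),
    # genuinely U-shaped causal liability, vertex at the mean exposure
    "CAUSAL_U": SimulationScenario(
        name="CAUSAL_U", causal_shape="quadratic", c2=0.8, fbg_c2=0.25,
    ),
    # flat causal curve + nonmonotone confounding -> observational U only
    "SPURIOUS_U": SimulationScenario(
        name="SPURIOUS_U", causal_shape="null",
        confounder_effect_on_exposure=0.6,
        confounder_effect_on_outcome=1.2,
        confounder_effect_on_fbg=0.5,
        confounder_coupling="nonmonotone",
    ),
}


def preset_scenarios() -> dict[str, SimulationScenario]:
    """The four named study conditions (copies; safe to replace fields)."""
    return dict(_PRESETS)


def preset(name: str, **overrides) -> SimulationScenario:
    """A preset scenario with field overrides, e.g. ``preset("NULL", seed=7)``."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    return dc_replace(_PRESETS[name], **overrides)
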