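"""Genetic instrument construction: variant QC, LD clumping, GRS and strength.

The genetic risk score is the weighted allele-dosage sum
``GRS_i = sum_j beta_j * G_ij`` with weights taken from external GWAS summary
statistics for the exposure. Candidate variants must pass genome-wide
significance (p < 5e-8, strict); approximate independence is enforced by
two-tier greedy clumping (r^2 < 0.001 within a 1 Mb window, then r^2 < 0.1
within the chromosome), with LD measured as the squared Pearson correlation
of dosages in a reference genotype sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._glm import fit_ols

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "InstrumentResult",
    "read_gwas",
    "read_genotypes",
    "write_genotypes",
    "variant_qc",
    "hwe_test",
    "ld_r2",
    "select_instruments",
    "harmonize_weights",
    "compute_grs",
    "instrument_strength",
]

GWAS_COLUMNS = ["SNP", "CHR", "BP", "EA", "NEA", "BETA", "SE", "P"]
VARIANT_COLUMNS = ["id", "chromosome", "position", "counted_allele", "other_allele"]

AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants) with aligned variant metadata.

    ``dosage`` holds ALT/counted-allele dosages in [0, 2]; missing genotypes
    are NaN. ``variants`` is a DataFrame with columns
    id/chromosome/position/counted_allele/other_allele, one row per column of
    ``dosage`` in the same order.
    """

    dosage: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x variants)")
        if len(self.variants) != self.dosage.shape[1]:
            raise ValueError("variant metadata rows must match dosage columns")
        self.variants = self.variants.reset_index(drop=True)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0) < 0 or np.nanmax(self.dosage, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return self.dosage[:, idx[0]]

    def subset(self, variant_ids) -> "GenotypeMatrix":
        pos = {v: i for i, v in enumerate(self.variants["id"])}
        cols = [pos[v] for v in variant_ids]
        return GenotypeMatrix(self.dosage[:, cols], self.variants.iloc[cols])


@dataclass
class InstrumentResult:
    """Selected instrument set with the per-individual score and diagnostics."""

    selected_ids: list[str]
    weights: np.ndarray
    grs: np.ndarray
    first_stage_f: float
    first_stage_r2: float
    weak_instrument: bool


def read_gwas(path) -> pd.DataFrame:
    """Read tab-delimited GWAS summary statistics (SNP CHR BP EA NEA BETA SE P)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (df["SE"] <= 0).any():
        raise ValueError("standard errors must be positive")
    dup = df.duplicated(subset=["CHR", "BP"])
    if dup.any():
        raise ValueError(f"duplicate (CHR, BP) positions for ids {df.loc[dup, 'SNP'].tolist()}")
    return df


def read_genotypes(dosage_path, variants_path) -> GenotypeMatrix:
    """Read a TSV dosage matrix (individuals x variants) plus variant TSV."""
    dosage = pd.read_csv(dosage_path, sep="\t")
    variants = pd.read_csv(variants_path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if list(dosage.columns) != list(variants["id"]):
        raise ValueError("dosage columns must match variant ids in order")
    return GenotypeMatrix(dosage.to_numpy(dtype=float), variants)


def write_genotypes(g: GenotypeMatrix, dosage_path, variants_path) -> None:
    pd.DataFrame(g.dosage, columns=g.variants["id"]).to_csv(
        dosage_path, sep="\t", index=False, na_rep="NA"
    )
    g.variants.to_csv(variants_path, sep="\t", index=False)


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = col[~np.isnan(col)]
    rounded = np.rint(ok).astype(int)
    return int((rounded == 0).sum()), int((rounded == 1).sum()), int((rounded == 2).sum())


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    Uses the 1-df chi-square of observed vs HWE-expected counts; falls back to
    the exact conditional (mid-p) test when any expected count is below 5.
    Monomorphic variants return p = 1.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    if exp.min() >= 5:
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(sps.chi2.sf(chi2, df=1))
    return _hwe_exact_midp(n_aa, n_ab, n_bb)


def _hwe_exact_midp(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test (conditional on allele counts), mid-p variant."""
    n = n_aa + n_ab + n_bb
    n_a = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)  # minor allele count
    hets = range(n_a % 2, n_a + 1, 2)
    # unnormalized conditional probabilities via log-factorials
    from scipy.special import gammaln

    def logp(h):
        aa = (n_a - h) // 2  # minor-homozygote count
        bb = n - aa - h
        return (h * np.log(2) - gammaln(aa + 1) - gammaln(h + 1) - gammaln(bb + 1))

    obs_h = n_ab  # heterozygote count is invariant to allele labelling
    lp = np.array([logp(h) for h in hets])
    pr = np.exp(lp - lp.max())
    pr /= pr.sum()
    p_obs = pr[list(hets).index(obs_h)]
    tail = pr[pr <= p_obs + 1e-12].sum()
    return float(min(1.0, tail - 0.5 * p_obs))


def variant_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.999,
    hwe_alpha: float = 1e-4,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants with low call rate or Hardy-Weinberg deviation.

    Returns the filtered matrix and a report DataFrame (id, call_rate, hwe_p,
    dropped, reason).
    """
    call = g.call_rate
    rows = []
    keep = []
    for j, vid in enumerate(g.variants["id"]):
        counts = _genotype_counts(g.dosage[:, j])
        hwe_p = hwe_test(*counts)
        if sum(counts) and max(counts) == sum(counts):
            logger.info("variant %s is monomorphic; HWE p set to 1, kept", vid)
        reason = None
        if call[j] < call_rate_min:
            reason = f"call rate {call[j]:.4f} < {call_rate_min}"
        elif hwe_p < hwe_alpha:
            reason = f"HWE p {hwe_p:.3g} < {hwe_alpha}"
        rows.append({
            "id": vid, "call_rate": call[j], "hwe_p": hwe_p,
            "dropped": reason is not None, "reason": reason or "",
        })
        if reason is None:
            keep.append(j)
    report = pd.DataFrame(rows)
    filtered = GenotypeMatrix(g.dosage[:, keep], g.variants.iloc[keep])
    return filtered, report


def ld_r2(g: GenotypeMatrix, i, j) -> float:
    """Squared Pearson correlation between two dosage columns.

    Genotype-correlation approximation to composite LD; invariant to allele
    re-coding (G -> 2-G). ``i``/``j`` may be column indices or variant ids.
    """
    def col(v):
        return g.column(v) if isinstance(v, str) else g.dosage[:, v]

    a, b = col(i), col(j)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    for name, x in ((i, a), (j, b)):
        if np.std(x) == 0:
            raise ValueError(f"variant {name!r} has zero dosage variance in the reference")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def select_instruments(
    stats: pd.DataFrame,
    reference: GenotypeMatrix,
    p_max: float = 5e-8,
    r2_tier1: float = 0.001,
    window_tier1: int = 1_000_000,
    r2_tier2: float = 0.1,
) -> list[str]:
    """Two-tier greedy LD clumping of genome-wide-significant variants.

    Only variants present in both the summary statistics and the reference are
    considered. Variants with p < ``p_max`` (strict) are processed in
    ascending (p, chromosome, position) order; an accepted variant removes all
    later variants with r^2 >= ``r2_tier1`` within ``window_tier1`` base pairs
    total (i.e. +/- half-window), and, in a second pass over the survivors,
    all later variants with r^2 >= ``r2_tier2`` on the same chromosome. The
    returned ids keep ascending-p order.
    """
    avail = set(reference.variants["id"])
    cand = stats[stats["SNP"].isin(avail) & (stats["P"] < p_max)].copy()
    if len(cand) == 0:
        raise ValueError("no genome-wide-significant instruments among available variants")
    cand = cand.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)

    half_window = window_tier1 // 2

    def greedy(frame: pd.DataFrame, same_chrom_only: bool, r2_max: float, window: int | None):
        alive = np.ones(len(frame), dtype=bool)
        for a in range(len(frame)):
            if not alive[a]:
                continue
            for b in range(a + 1, len(frame)):
                if not alive[b]:
                    continue
                if frame.loc[a, "CHR"] != frame.loc[b, "CHR"]:
                    continue
                if window is not None and abs(frame.loc[a, "BP"] - frame.loc[b, "BP"]) > window:
                    continue
                if ld_r2(reference, frame.loc[a, "SNP"], frame.loc[b, "SNP"]) >= r2_max:
                    alive[b] = False
        return frame[alive].reset_index(drop=True)

    tier1 = greedy(cand, False, r2_tier1, half_window)
    tier2 = greedy(tier1, True, r2_tier2, None)
    return tier2["SNP"].tolist()


def harmonize_weights(
    stats: pd.DataFrame,
    g: GenotypeMatrix,
    selected_ids,
    drop_ambiguous: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Align GWAS effect alleles with the matrix's counted alleles.

    Effect allele equal to the counted allele keeps beta; equal to the other
    allele flips its sign; any other allele pair drops the variant with a
    warning. Strand-ambiguous (A/T, C/G) variants are kept unless
    ``drop_ambiguous``.
    """
    meta = g.variants.set_index("id")
    srow = stats.set_index("SNP")
    kept, weights = [], []
    for vid in selected_ids:
        ea, nea = srow.loc[vid, "EA"], srow.loc[vid, "NEA"]
        beta = float(srow.loc[vid, "BETA"])
        counted = meta.loc[vid, "counted_allele"]
        other = meta.loc[vid, "other_allele"]
        if drop_ambiguous and frozenset({ea, nea}) in AMBIGUOUS_PAIRS:
            logger.warning("dropping strand-ambiguous variant %s (%s/%s)", vid, ea, nea)
            continue
        if ea == counted and nea == other:
            kept.append(vid); weights.append(beta)
        elif ea == other and nea == counted:
            kept.append(vid); weights.append(-beta)
        else:
            logger.warning(
                "dropping variant %s: alleles %s/%s do not match matrix %s/%s",
                vid, ea, nea, counted, other,
            )
    return kept, np.asarray(weights, dtype=float)


def compute_grs(g: GenotypeMatrix, selected_ids, weights) -> np.ndarray:
    """Weighted dosage sum per individual (missing dosages mean-imputed)."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(selected_ids):
        raise ValueError(
            f"{len(selected_ids)} variants but {len(weights)} weights; must align"
        )
    sub = g.subset(selected_ids)
    dosage = sub.dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(dosage), np.nan, dosage), axis=0)
    nan_rows, nan_cols = np.where(np.isnan(dosage))
    dosage[nan_rows, nan_cols] = col_mean[nan_cols]
    return dosage @ weights


def instrument_strength(exposure, grs, covariates=None, names=None):
    """Partial F and incremental R^2 for the score in the first-stage model.

    Fits ``exposure ~ grs + covariates`` by least squares and returns
    ``(F, R2, weak)`` where F is the 1-df partial F for the score, R2 the
    incremental variance explained by the score over the covariates, and
    ``weak`` flags F <= 10 (the conventional weak-instrument bar, strict >10
    to pass).
    """
    y = np.asarray(exposure, dtype=float)
    z = np.asarray(grs, dtype=float)
    n = len(y)
    if covariates is None:
        C = np.ones((n, 1))
        cov_names = ["intercept"]
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        cov_names = ["intercept"] + (
            list(names) if names is not None
            else [f"covariate_{j}" for j in range(C.shape[1] - 1)]
        )
    ok = np.isfinite(y) & np.isfinite(z) & np.all(np.isfinite(C), axis=1)
    y, z, C = y[ok], z[ok], C[ok]
    if len(y) <= C.shape[1] + 2:
        raise ValueError("too few complete cases for the first-stage model")

    full = fit_ols(y, np.column_stack([C, z]), cov_names + ["grs"])
    reduced = fit_ols(y, C, cov_names)
    rss_full = float(full.ssr)
    rss_red = float(reduced.ssr)
    df_resid = len(y) - C.shape[1] - 1
    if rss_full <= 0:
        f_stat = np.inf
    else:
        f_stat = (rss_red - rss_full) / (rss_full / df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = (rss_red - rss_full) / tss if tss > 0 else 0.0
    return float(f_stat), float(r2), bool(f_stat <= 10.0)
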