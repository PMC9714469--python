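"""Cohort table input/output, cleaning rules and descriptive summaries.

A cohort is held as a plain :class:`pandas.DataFrame` with canonical column
names (see :data:`COHORT_COLUMNS`). Missing values are ``NaN`` per cell; rows
are never dropped by the cleaning rules, only cells are blanked.

The derived outcome is diabetes — positive if any of: self-reported history,
hypoglycemic drug use, fasting glucose >= 7.0 mmol/L, or 2-hour post-load
glucose >= 11.1 mmol/L. Hypertension is the analogous composite of
self-report, SBP >= 140 mmHg, DBP >= 90 mmHg or antihypertensive use. Both
cut-offs are inclusive. A row whose evaluable criteria are all negative but
which is missing any criterion gets a missing derived value rather than 0.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COHORT_COLUMNS",
    "SchemaError",
    "OutlierReport",
    "SubgroupSpec",
    "read_cohort",
    "write_cohort",
    "flag_outliers",
    "mask_outliers",
    "drop_sparse_columns",
    "median_impute",
    "derive_diabetes",
    "derive_hypertension",
    "apply_subgroup",
    "summarize_by_outcome",
    "summary_to_json",
]

#: Canonical column names and whether each is required by :func:`read_cohort`.
COHORT_COLUMNS: dict[str, bool] = {
    "individual_id": True,
    "sex": True,  # 0 = female, 1 = male
    "age": True,
    "bmi": False,
    "ldl_c": True,
    "fbg": True,
    "ogtt_2h": False,
    "sbp": False,
    "dbp": False,
    "self_report_diabetes": False,
    "hypoglycemic_drug_use": False,
    "lipid_lowering_drug_use": False,
    "self_report_hypertension": False,
    "antihypertensive_use": False,
    "diabetes_family_history": False,
    "chd": False,
    "dyslipidemia": False,
    "ever_smoker": False,
}

#: Columns that must be non-negative when present (concentrations/pressures).
NONNEGATIVE_COLUMNS = ("ldl_c", "fbg", "ogtt_2h", "sbp", "dbp", "bmi", "age")

MISSING_TOKENS = ("", "NA", "NaN", "nan", ".")


class SchemaError(ValueError):
    """A mapped column is absent or a cell cannot be parsed."""


@dataclass(frozen=True)
class OutlierReport:
    """Tukey-fence report for one numeric column.

    The keep-interval is [Q1 - 1.5*IQR, Q3 + 1.5*IQR]; values strictly outside
    are flagged. Quartiles use linear interpolation between order statistics
    (numpy's default, "type 7").
    """

    column: str
    q1: float
    q3: float
    iqr: float
    lower_bound: float
    upper_bound: float
    flagged_ids: tuple = ()

    def __post_init__(self):
        assert self.lower_bound <= self.upper_bound


@dataclass(frozen=True)
class SubgroupSpec:
    """Conjunctive row filters; ``None`` means no restriction on that axis."""

    sex_filter: str | None = None  # "female" | "male"
    lipid_lowering_filter: str | None = None  # "users" | "non-users"
    smoking_filter: str | None = None  # "never" | "ever"
    chd_filter: str | None = None  # "with" | "without"

    def label(self) -> str:
        parts = []
        if self.sex_filter:
            parts.append(self.sex_filter)
        if self.lipid_lowering_filter:
            parts.append(f"lipid-lowering {self.lipid_lowering_filter}")
        if self.smoking_filter:
            parts.append(f"{self.smoking_filter} smokers")
        if self.chd_filter:
            parts.append(f"{self.chd_filter} CHD")
        return ", ".join(parts) if parts else "all"


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_cohort(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited cohort table into canonical columns.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file with a header row. Missing cells may be empty or any
        of ``NA``, ``NaN``, ``.``.
    schema : dict, optional
        Mapping from canonical column name to the column name used in the
        file. Unmapped canonical names are assumed to match literally.

    Raises
    ------
    SchemaError
        If a required column is absent, or a numeric cell fails to parse (the
        error names the row and column).
    """
    schema = dict(schema or {})
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    out = pd.DataFrame(index=raw.index)
    for canon, required in COHORT_COLUMNS.items():
        src = schema.get(canon, canon)
        if src not in raw.columns:
            if required or canon in schema:
                raise SchemaError(f"required column {canon!r} (file column {src!r}) not found")
            continue
        col = raw[src].str.strip().replace(list(MISSING_TOKENS), np.nan)
        if canon == "individual_id":
            out[canon] = col
            continue
        try:
            out[canon] = pd.to_numeric(col)
        except (ValueError, TypeError):
            bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
            row = bad.index[0]
            raise SchemaError(
                f"unparseable numeric value {bad.iloc[0]!r} in column {canon!r}, row {row}"
            ) from None

    for canon in NONNEGATIVE_COLUMNS:
        if canon in out.columns and (out[canon].dropna() < 0).any():
            raise SchemaError(f"negative values in non-negative column {canon!r}")
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def flag_outliers(values, column: str = "value", ids=None) -> OutlierReport:
    """Tukey's fences: flag values strictly outside [Q1-1.5 IQR, Q3+1.5 IQR].

    ``values`` may be a pandas Series (its index labels the flags) or any
    numeric sequence. Requires at least 4 non-missing values.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if ids is not None:
        s.index = pd.Index(ids)
    elif isinstance(values, pd.Series):
        s.index = values.index
    ok = s.dropna()
    if len(ok) == 0:
        raise ValueError(f"column {column!r}: all values missing")
    if len(ok) < 4:
        raise ValueError(f"column {column!r}: need >=4 non-missing values, got {len(ok)}")
    q1, q3 = np.quantile(ok.to_numpy(), [0.25, 0.75])  # linear interpolation ("type 7")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = ok[(ok < lo) | (ok > hi)]
    return OutlierReport(
        column=column, q1=float(q1), q3=float(q3), iqr=float(iqr),
        lower_bound=float(lo), upper_bound=float(hi),
        flagged_ids=tuple(flagged.index),
    )


def mask_outliers(table: pd.DataFrame, columns) -> tuple[pd.DataFrame, list[OutlierReport]]:
    """Blank (set to NaN) extreme-outlier cells in the given columns.

    Rows are kept; only the offending cells become missing.
    """
    table = table.copy()
    reports = []
    for col in columns:
        rep = flag_outliers(table[col], column=col)
        reports.append(rep)
        if rep.flagged_ids:
            table.loc[list(rep.flagged_ids), col] = np.nan
            logger.info("masked %d outlier cells in %r", len(rep.flagged_ids), col)
    return table, reports


def drop_sparse_columns(table: pd.DataFrame, max_missing: float = 0.10) -> pd.DataFrame:
    """Drop columns whose missing fraction exceeds ``max_missing`` (default 10%)."""
    keep, dropped = [], []
    for col in table.columns:
        frac = table[col].isna().mean()
        (dropped if frac > max_missing else keep).append(col)
    if dropped:
        logger.warning("dropping columns with >%d%% missing: %s", int(max_missing * 100), dropped)
    return table[keep]


def median_impute(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Fill missing numeric cells with the column median.

    A crude stand-in for model-based multiple imputation; estimates from
    imputed data understate uncertainty and are not equivalent to it.
    """
    table = table.copy()
    for col in columns:
        table[col] = table[col].fillna(table[col].median())
    return table


def _crit(table: pd.DataFrame, col: str, threshold: float | None = None) -> pd.Series:
    """One criterion as 1/0/NaN: missing source cell stays missing."""
    if col not in table.columns:
        return pd.Series(np.nan, index=table.index, dtype=float)
    src = table[col]
    cond = (src == 1) if threshold is None else (src >= threshold)
    out = cond.astype(float)
    out[src.isna()] = np.nan
    return out


def _composite_flag(criteria: list[pd.Series]) -> pd.Series:
    """1 if any criterion is 1; 0 if all evaluable and 0; NaN otherwise."""
    pos = pd.Series(False, index=criteria[0].index)
    any_missing = pd.Series(False, index=criteria[0].index)
    for c in criteria:
        pos |= c == 1
        any_missing |= c.isna()
    out = pd.Series(np.nan, index=pos.index, dtype=float)
    out[pos] = 1.0
    out[~pos & ~any_missing] = 0.0
    return out


def derive_diabetes(table: pd.DataFrame) -> pd.Series:
    """Composite diabetes status (1/0/NaN) from its four criteria."""
    return _composite_flag([
        _crit(table, "self_report_diabetes"),
        _crit(table, "hypoglycemic_drug_use"),
        _crit(table, "fbg", 7.0),
        _crit(table, "ogtt_2h", 11.1),
    ])


def derive_hypertension(table: pd.DataFrame) -> pd.Series:
    """Composite hypertension status (1/0/NaN)."""
    return _composite_flag([
        _crit(table, "self_report_hypertension"),
        _crit(table, "sbp", 140.0),
        _crit(table, "dbp", 90.0),
        _crit(table, "antihypertensive_use"),
    ])


def derive_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Attach/refresh derived ``diabetes`` and ``hypertension`` columns."""
    table = table.copy()
    table["diabetes"] = derive_diabetes(table)
    table["hypertension"] = derive_hypertension(table)
    return table


_NA_CMP = {
    "sex_filter": ("sex", {"female": 0, "male": 1}),
    "lipid_lowering_filter": ("lipid_lowering_drug_use", {"non-users": 0, "users": 1}),
    "smoking_filter": ("ever_smoker", {"never": 0, "ever": 1}),
    "chd_filter": ("chd", {"without": 0, "with": 1}),
}


def apply_subgroup(table: pd.DataFrame, spec: SubgroupSpec) -> pd.DataFrame:
    """Select the rows matching every active filter, preserving row order."""
    mask = pd.Series(True, index=table.index)
    for f in dc_fields(spec):
        val = getattr(spec, f.name)
        if val is None:
            continue
        col, mapping = _NA_CMP[f.name]
        if val not in mapping:
            raise ValueError(f"{f.name}={val!r}: expected one of {sorted(mapping)}")
        if col not in table.columns:
            raise KeyError(f"subgroup filter column {col!r} not in table")
        mask &= table[col] == mapping[val]
    out = table[mask]
    if len(out) == 0:
        warnings.warn(f"subgroup {spec.label()!r} selected no rows", stacklevel=2)
    return out


DEFAULT_CATEGORICAL = (
    "sex", "ever_smoker", "diabetes_family_history", "chd", "hypertension",
    "lipid_lowering_drug_use", "hypoglycemic_drug_use", "self_report_diabetes",
)
DEFAULT_CONTINUOUS = ("age", "bmi", "ldl_c", "fbg", "ogtt_2h", "sbp", "dbp")


def summarize_by_outcome(
    table: pd.DataFrame,
    categorical=None,
    continuous=None,
    outcome: str = "diabetes",
) -> pd.DataFrame:
    """Baseline-characteristics table by outcome group.

    For each of the overall sample, controls and cases: ``n (pct)`` per level
    of categorical columns (percentages among the group's non-missing rows)
    and ``median [Q1, Q3]`` for continuous columns. Returns a long-format
    DataFrame with numeric ``count``/``percent``/``median``/``q1``/``q3``
    columns alongside a formatted ``display`` string.
    """
    if outcome not in table.columns:
        raise KeyError(f"derived outcome column {outcome!r} missing; derive it first")
    categorical = [c for c in (categorical or DEFAULT_CATEGORICAL) if c in table.columns]
    continuous = [c for c in (continuous or DEFAULT_CONTINUOUS) if c in table.columns]

    groups = {
        "overall": table,
        "control": table[table[outcome] == 0],
        "case": table[table[outcome] == 1],
    }
    rows = []
    for gname, g in groups.items():
        rows.append({"group": gname, "variable": "n", "level": "", "count": len(g)})
        for col in categorical:
            vals = g[col].dropna()
            total = len(vals)
            for level, cnt in vals.value_counts().sort_index().items():
                pct = 100.0 * cnt / total if total else np.nan
                rows.append({
                    "group": gname, "variable": col, "level": level,
                    "count": int(cnt), "percent": pct,
                    "display": f"{int(cnt)} ({pct:.1f})" if total else "NA",
                })
            if total == 0:
                rows.append({"group": gname, "variable": col, "level": "", "display": "NA"})
        for col in continuous:
            vals = g[col].dropna().to_numpy()
            if len(vals) == 0:
                rows.append({"group": gname, "variable": col, "level": "", "display": "NA"})
                continue
            med, q1, q3 = np.quantile(vals, [0.5, 0.25, 0.75])
            rows.append({
                "group": gname, "variable": col, "level": "",
                "median": med, "q1": q1, "q3": q3,
                "display": f"{med:.2f} [{q1:.2f}, {q3:.2f}]",
            })
    return pd.DataFrame(rows)


def summary_to_json(summary: pd.DataFrame, path=None) -> str:
    """Serialize the summary table to JSON records (optionally to ``path``)."""
    txt = json.dumps(
        json.loads(summary.to_json(orient="records")), indent=1, sort_keys=True
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(txt)
    return txt
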