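"""Group statistics for annualized cortical thinning.

Two-sample t-tests (pooled by default, Welch optional), one-sample tests of
regional change against zero, Pearson chi-squared tests on 2x2 demographic
tables (uncorrected, df = 1), Pearson correlations with clinical variables,
Benjamini-Hochberg FDR correction, and Engel-outcome binarization.  The
full battery over a cohort is :func:`run_group_analysis`.

Sign convention: annualized change is signed, negative = thinning.  FDR
families: regionwise tests are corrected separately within the ipsilateral
and contralateral sets (configurable to a single family).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclasses.dataclass
class StatResult:
    """One hypothesis test: statistic, degrees of freedom, p, summaries."""

    name: str
    statistic: float
    df: float
    p_value: float
    n: int
    group_summaries: Dict[str, Tuple[float, float, int]] = dataclasses.field(
        default_factory=dict
    )
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def _summary(x: np.ndarray) -> Tuple[float, float, int]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0, len(x)


def _check_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < min_n:
        raise ValueError(f"sample {name} needs n >= {min_n}, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError(f"sample {name} contains non-finite values")
    return x


def two_sample_t(x, y, variant: str = "pooled", name: str = "two_sample_t") -> StatResult:
    """Two-sided two-sample t-test; pooled (equal-variance) by default."""
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant samples: no evidence of a difference
            return StatResult(name, 0.0, len(x) + len(y) - 2, 1.0,
                              len(x) + len(y),
                              {"x": _summary(x), "y": _summary(y)})
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    df = float(res.df)
    direction = "x>y" if res.statistic > 0 else ("x<y" if res.statistic < 0 else None)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        n=len(x) + len(y),
        group_summaries={"x": _summary(x), "y": _summary(y)},
        direction=direction,
    )


def one_sample_t(x, popmean: float = 0.0, name: str = "one_sample_t") -> StatResult:
    """Two-sided one-sample t-test of mean != popmean."""
    x = _check_sample(x, "x")
    if np.var(x, ddof=1) == 0:
        raise ValueError("zero variance sample: one-sample t is degenerate")
    res = sps.ttest_1samp(x, popmean)
    direction = "above" if res.statistic > 0 else ("below" if res.statistic < 0 else None)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=float(len(x) - 1),
        p_value=float(res.pvalue),
        n=len(x),
        group_summaries={"x": _summary(x)},
        direction=direction,
    )


def chi_square(table, name: str = "chi_square") -> StatResult:
    """Uncorrected Pearson chi-squared on a 2x2 count table (df = 1)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValueError("counts must be nonnegative integers")
        table = np.round(table).astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(res.pvalue),
        n=int(table.sum()),
    )


def pearson_r(x, y, name: str = "pearson_r") -> StatResult:
    """Pearson correlation with two-sided p via the t transform."""
    x = _check_sample(x, "x", min_n=3)
    y = _check_sample(y, "y", min_n=3)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=float(x.size - 2),
        p_value=float(res.pvalue),
        n=x.size,
        direction="positive" if res.statistic > 0 else "negative",
    )


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def engel_binarize(engel) -> Optional[str]:
    """Engel I -> 'favorable'; II-IV -> 'less_favorable'; missing -> None."""
    if engel is None or (isinstance(engel, float) and np.isnan(engel)) or engel == "":
        logger.info("missing Engel class: subject excluded from outcome analysis")
        return None
    value = str(engel).strip().upper()
    if value == "I":
        return "favorable"
    if value in ("II", "III", "IV"):
        return "less_favorable"
    raise ValueError(f"unknown Engel class: {engel!r}")


@dataclasses.dataclass
class GroupAnalysisResult:
    """Output of the full cohort statistical battery."""

    global_test: Optional[StatResult]
    region_table: pd.DataFrame  # ATL-vs-SAH per region, FDR within laterality
    change_vs_zero_table: pd.DataFrame  # per-region change vs 0, all subjects
    correlations: Dict[str, StatResult]
    engel_test: Optional[StatResult]
    skipped: List[str]


def _fdr_by_family(df: pd.DataFrame, family_col: Optional[str]) -> pd.DataFrame:
    df = df.copy()
    df["q"] = np.nan
    if df.empty:
        return df
    if family_col is None:
        mask = df["p"].notna()
        df.loc[mask, "q"] = fdr_correct(df.loc[mask, "p"].to_numpy())
    else:
        for _, idx in df.groupby(family_col).groups.items():
            mask = df.loc[idx, "p"].notna()
            take = df.loc[idx][mask]
            if len(take):
                df.loc[take.index, "q"] = fdr_correct(take["p"].to_numpy())
    df["significant"] = df["q"] < ALPHA
    return df


def run_group_analysis(
    regional: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = ALPHA,
    variant: str = "pooled",
    fdr_families: str = "by_laterality",
) -> GroupAnalysisResult:
    """The full statistical battery over a cohort.

    ``regional`` has one row per subject x region with columns ``subject``,
    ``region``, ``laterality``, ``thickness_pre``, ``annualized_change``
    (exclusions already applied); ``cohort`` has one row per subject with
    ``procedure`` and the clinical variables.  Analyses with missing
    metadata are skipped with a log entry, never silently.
    """
    skipped: List[str] = []
    cohort = cohort.set_index("subject") if "subject" in cohort.columns else cohort
    per_subject = (
        regional.groupby("subject")
        .agg(
            global_change=("annualized_change", "mean"),
            global_pre_thickness=("thickness_pre", "mean"),
        )
        .join(cohort, how="inner")
    )

    groups = {
        proc: per_subject.loc[per_subject["procedure"] == proc, "global_change"]
        for proc in ("ATL", "SAH")
    }
    global_test = None
    if all(len(g) >= 2 for g in groups.values()):
        global_test = two_sample_t(
            groups["ATL"], groups["SAH"], variant=variant, name="global_ATL_vs_SAH"
        )
        global_test.group_summaries = {
            "ATL": _summary(groups["ATL"].to_numpy()),
            "SAH": _summary(groups["SAH"].to_numpy()),
        }
    else:
        skipped.append("global ATL-vs-SAH test (a group has < 2 subjects)")
        logger.warning("skipping global test: a group has < 2 subjects")

    regional = regional.merge(
        cohort[["procedure"]], left_on="subject", right_index=True, how="left"
    )
    family_col = "laterality" if fdr_families == "by_laterality" else None

    rows = []
    for (region, lat), sub in regional.groupby(["region", "laterality"]):
        a = sub.loc[sub["procedure"] == "ATL", "annualized_change"].to_numpy()
        s = sub.loc[sub["procedure"] == "SAH", "annualized_change"].to_numpy()
        a, s = a[np.isfinite(a)], s[np.isfinite(s)]
        row = {"region": region, "laterality": lat, "t": np.nan, "p": np.nan,
               "mean_ATL": np.nan, "mean_SAH": np.nan}
        if len(a) >= 2 and len(s) >= 2:
            try:
                res = two_sample_t(a, s, variant=variant)
                row.update(t=res.statistic, p=res.p_value,
                           mean_ATL=float(a.mean()), mean_SAH=float(s.mean()))
            except ValueError:
                pass
        rows.append(row)
    region_table = _fdr_by_family(pd.DataFrame(rows), family_col)

    rows = []
    for (region, lat), sub in regional.groupby(["region", "laterality"]):
        x = sub["annualized_change"].to_numpy()
        x = x[np.isfinite(x)]
        row = {"region": region, "laterality": lat, "t": np.nan, "p": np.nan,
               "mean_change": np.nan}
        if len(x) >= 2 and np.var(x, ddof=1) > 0:
            res = one_sample_t(x)
            row.update(t=res.statistic, p=res.p_value, mean_change=float(x.mean()))
        rows.append(row)
    change_table = _fdr_by_family(pd.DataFrame(rows), family_col)

    correlations: Dict[str, StatResult] = {}
    corr_vars = {
        "age_at_surgery": "age_at_surgery",
        "duration": "duration_years",
        "preop_thickness": None,  # computed from the regional table
    }
    for label, col in corr_vars.items():
        if label == "preop_thickness":
            sub = per_subject[["global_change", "global_pre_thickness"]].dropna()
            x, y = sub["global_pre_thickness"], sub["global_change"]
        else:
            if col not in per_subject.columns:
                skipped.append(f"correlation with {label} (column missing)")
                logger.warning("skipping correlation with %s: column missing", label)
                continue
            sub = per_subject[["global_change", col]].dropna()
            x, y = sub[col], sub["global_change"]
        if len(sub) < 3 or np.var(x) == 0 or np.var(y) == 0:
            skipped.append(f"correlation with {label} (insufficient data)")
            logger.warning("skipping correlation with %s: insufficient data", label)
            continue
        correlations[label] = pearson_r(x, y, name=f"corr_{label}")

    engel_test = None
    if "engel" in per_subject.columns:
        outcome = per_subject["engel"].map(engel_binarize)
        fav = per_subject.loc[outcome == "favorable", "global_change"]
        unf = per_subject.loc[outcome == "less_favorable", "global_change"]
        if len(fav) >= 2 and len(unf) >= 2:
            engel_test = two_sample_t(
                fav, unf, variant=variant, name="engel_favorable_vs_less"
            )
        else:
            skipped.append("Engel outcome comparison (a group has < 2 subjects)")
            logger.warning("skipping Engel comparison: a group has < 2 subjects")
    else:
        skipped.append("Engel outcome comparison (no engel column)")
        logger.warning("skipping Engel comparison: no engel column")

    return GroupAnalysisResult(
        global_test=global_test,
        region_table=region_table,
        change_vs_zero_table=change_table,
        correlations=correlations,
        engel_test=engel_test,
        skipped=skipped,
    )
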