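"""Group comparison statistics for cohort metric tables.

The battery mirrors standard clinical-imaging practice: Shapiro-Wilk
(alpha = 0.05 per group) decides between mean +/- SD with one-way ANOVA
and median (IQR) with Kruskal-Wallis; categorical variables use the
chi-squared test; pairwise post-hoc tests reuse the omnibus family with a
Bonferroni multiplier equal to the number of pairs; ANCOVA fits
metric ~ group + covariates by OLS and reports the type-II F-test on the
group factor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io_formats import GROUPS

log = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


class StatisticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def is_normal(values: np.ndarray, alpha: float = SHAPIRO_ALPHA) -> bool:
    """Shapiro-Wilk normality gate (True = compatible with normality)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.ptp(values) == 0:
        return True  # too few points / constant: treat as normal
    return bool(stats.shapiro(values).pvalue >= alpha)


def describe(values: np.ndarray, normal: bool | None = None) -> dict:
    """Mean +/- SD when normal, median (IQR) otherwise."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise StatisticsError("empty group")
    if normal is None:
        normal = is_normal(values)
    if normal:
        return {"normal": True, "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"normal": False, "median": float(med), "iqr": (float(q1), float(q3))}


def format_summary(summary: dict, fmt: str = "{:.3f}") -> str:
    if summary["normal"]:
        return f"{fmt.format(summary['mean'])} ± {fmt.format(summary['sd'])}"
    q1, q3 = summary["iqr"]
    return f"{fmt.format(summary['median'])} ({fmt.format(q1)}, {fmt.format(q3)})"


# ---------------------------------------------------------------------------
# omnibus and post-hoc tests
# ---------------------------------------------------------------------------

def omnibus_test(groups: list[np.ndarray], family: str) -> tuple[float, float]:
    """Three (or more) group omnibus test.

    family: "anova", "kruskal_wallis" (tie-corrected) or "chi_squared"
    (groups are count vectors of a contingency table).
    """
    if len(groups) < 2:
        raise StatisticsError("need at least two groups")
    if family == "anova":
        res = stats.f_oneway(*groups)
    elif family == "kruskal_wallis":
        res = stats.kruskal(*groups)
    elif family == "chi_squared":
        table = np.asarray(groups)
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise StatisticsError("chi-squared requires non-negative counts")
        chi2 = stats.chi2_contingency(table)
        return float(chi2.statistic), float(chi2.pvalue)
    else:
        raise StatisticsError(f"unknown test family {family!r}")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    return min(1.0, p_raw * n_comparisons)


def posthoc_pairwise(groups: dict[str, np.ndarray], family: str) -> dict:
    """All pairwise tests of the omnibus family with Bonferroni adjustment.

    The non-parametric pairwise test is the 2-group Kruskal-Wallis (rank
    test equivalent to Mann-Whitney up to tie handling).
    """
    if len(groups) < 2:
        raise StatisticsError("need at least two groups for post-hoc tests")
    pairs = list(itertools.combinations(sorted(groups), 2))
    out = {}
    for a, b in pairs:
        if family == "anova":
            res = stats.ttest_ind(groups[a], groups[b])
        elif family == "kruskal_wallis":
            res = stats.kruskal(groups[a], groups[b])
        else:
            raise StatisticsError(f"no pairwise test for family {family!r}")
        out[(a, b)] = {"p_raw": float(res.pvalue),
                       "p_adjusted": bonferroni(float(res.pvalue), len(pairs))}
    return out


def ancova(df: pd.DataFrame, metric: str, group_col: str = "group",
           covariates: tuple[str, ...] = ("bmi",)) -> dict:
    """OLS metric ~ group + covariates; type-II F-test on the group factor."""
    cols = [metric, group_col, *covariates]
    data = df[cols].dropna()
    if data[list(covariates)].isna().any().any():
        raise StatisticsError("covariates contain missing values")
    for cov in covariates:
        if np.ptp(data[cov].to_numpy(dtype=float)) == 0:
            # constant covariate: the model reduces to one-way ANOVA, but a
            # singular design confuses the type-II table; drop it explicitly
            covariates = tuple(c for c in covariates if c != cov)
    rhs = " + ".join([f"C({group_col})", *covariates]) or f"C({group_col})"
    model = smf.ols(f"{metric} ~ {rhs}", data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise StatisticsError("collinear design matrix in ANCOVA")
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[f"C({group_col})"]
    return {"F": float(row["F"]), "p": float(row["PR(>F)"]),
            "covariates": tuple(covariates)}


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    metric: str
    family: str
    summaries: dict
    statistic: float
    p: float
    pairwise: dict = field(default_factory=dict)
    ancova_p: float | None = None

    def as_row(self) -> dict:
        row = {"metric": self.metric, "family": self.family,
               "statistic": self.statistic, "p": self.p,
               "ancova_p": self.ancova_p}
        for g, s in self.summaries.items():
            row[g] = format_summary(s)
        for (a, b), r in self.pairwise.items():
            row[f"p_{a}_vs_{b}"] = r["p_adjusted"]
        return row


def compare_metric(df: pd.DataFrame, metric: str, group_col: str = "group",
                   covariates: tuple[str, ...] = ("bmi",),
                   force_family: str | None = None) -> GroupComparison:
    """Full comparison of one continuous metric across the study groups."""
    groups = {g: df.loc[df[group_col] == g, metric].dropna().to_numpy(dtype=float)
              for g in sorted(df[group_col].unique())}
    for g, v in groups.items():
        if len(v) < 2:
            raise StatisticsError(f"group {g!r} has fewer than 2 observations")
    all_normal = all(is_normal(v) for v in groups.values())
    family = force_family or ("anova" if all_normal else "kruskal_wallis")
    stat, p = omnibus_test(list(groups.values()), family)
    pairwise = posthoc_pairwise(groups, family)
    anc = None
    if covariates and all(c in df.columns for c in covariates):
        anc = ancova(df, metric, group_col=group_col, covariates=covariates)["p"]
    summaries = {g: describe(v, normal=all_normal) for g, v in groups.items()}
    return GroupComparison(metric=metric, family=family, summaries=summaries,
                           statistic=stat, p=p, pairwise=pairwise, ancova_p=anc)


def compare_table(df: pd.DataFrame, metrics: list[str],
                  covariates: tuple[str, ...] = ("bmi",)) -> pd.DataFrame:
    """One comparison row per metric (the shape of the study's result tables)."""
    missing = set(df["group"].unique()) ^ set(GROUPS)
    if set(GROUPS) - set(df["group"].unique()):
        raise StatisticsError(f"missing study groups: {sorted(missing)}")
    rows = [compare_metric(df, m, covariates=covariates).as_row() for m in metrics]
    return pd.DataFrame(rows)
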