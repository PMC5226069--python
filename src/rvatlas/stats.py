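"""Cohort statistics: group comparisons, ANOVA with Bonferroni, ICC.

Mirrors the statistical workflow of a two-group (surgical shunt type),
two-stage CMR cohort study: Shapiro-Wilk normality screening, unpaired
equal-variance t-tests for continuous variables, Pearson chi-square
(without continuity correction) for categorical ones, one-way ANOVA
with Bonferroni-adjusted post hoc t-tests for the atlas mode scores,
and two-way random absolute-agreement intraclass correlation ICC(A,1)
for inter-observer reproducibility.  Significance is declared at
p < 0.05 throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way random, absolute agreement, single rater (A,1)"


def compare_groups(a, b, kind: str = "continuous", equal_var: bool = True,
                   label_a: str = "A", label_b: str = "B") -> dict:
    """Two-group comparison row.

    Continuous: per-group Shapiro-Wilk then an unpaired two-sided
    t-test (equal-variance Student by default, switchable to Welch).
    Categorical: ``a`` must be a 2 x C contingency table; Pearson
    chi-square without continuity correction.
    """
    if kind == "categorical":
        table = np.asarray(a, dtype=float)
        if table.ndim != 2:
            raise ValueError("categorical comparison expects a 2D contingency table")
        expected = sps.contingency.expected_freq(table)
        if (expected < 1).any():
            warnings.warn("chi-square expected cell count < 1; test may be unreliable")
        chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
        return {"test": "chi2", "statistic": float(chi2), "p": float(p), "dof": int(dof)}

    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    row = {
        "test": "t" if equal_var else "welch_t",
        f"mean_{label_a}": float(x.mean()), f"sd_{label_a}": float(x.std(ddof=1)),
        f"mean_{label_b}": float(y.mean()), f"sd_{label_b}": float(y.std(ddof=1)),
    }
    for lab, v in ((label_a, x), (label_b, y)):
        if np.ptp(v) > 0 and v.size >= 3:
            row[f"shapiro_p_{lab}"] = float(sps.shapiro(v).pvalue)
        else:
            row[f"shapiro_p_{lab}"] = np.nan
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # zero variance in both groups: identical means are a perfect null
        row.update(statistic=0.0 if x.mean() == y.mean() else np.inf,
                   p=1.0 if x.mean() == y.mean() else 0.0,
                   dof=x.size + y.size - 2)
        return row
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    row.update(statistic=float(t), p=float(p), dof=int(x.size + y.size - 2))
    return row


def anova_bonferroni(values, labels, m_comparisons: int = 1) -> dict:
    """One-way ANOVA with Bonferroni adjustment over ``m_comparisons``.

    Returns F, raw p, adjusted p = min(1, p x m), and Bonferroni-adjusted
    post hoc pairwise t-tests (over the number of pairs).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("ANOVA requires at least two groups")
    per_group = [values[labels == g] for g in groups]
    if any(g.size < 2 for g in per_group):
        raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*per_group)
    pairs = list(itertools.combinations(range(groups.size), 2))
    posthoc = {}
    for i, j in pairs:
        t, pp = sps.ttest_ind(per_group[i], per_group[j], equal_var=True)
        posthoc[f"{groups[i]}_vs_{groups[j]}"] = {
            "t": float(t), "p": float(pp),
            "p_bonferroni": float(min(1.0, pp * len(pairs)))}
    return {"F": float(f), "p": float(p),
            "p_bonferroni": float(min(1.0, p * m_comparisons)),
            "posthoc": posthoc}


def icc_two_way_random(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete (subjects x raters) matrix.  Point
    estimate and F-based confidence interval follow the standard
    mean-squares decomposition (McGraw & Wong).
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    if np.isnan(Y).any():
        raise ValueError("ratings matrix contains missing entries")
    n, k = Y.shape
    if n < 5 or k < 2:
        raise ValueError("ICC needs >= 5 subjects and >= 2 raters")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)  # subjects
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)  # raters
    sse = ((Y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 1.0

    # F-based CI (McGraw & Wong 1996, case A-1)
    if 1.0 - icc < 1e-12:
        lo = hi = 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(icc=float(np.clip(icc, -1, 1)),
                     ci_low=float(min(lo, icc)), ci_high=float(max(hi, icc)))


# -- report tables ----------------------------------------------------------

_STRATA = ("Total", "I", "II")
_VOLUME_METRICS = ("iEDV", "iESV", "iSV", "EF")


def _mean_sd(v) -> str:
    v = np.asarray(v, dtype=float)
    return f"{v.mean():.1f} ± {v.std(ddof=1):.1f}" if v.size > 1 else "-"


def _stratify(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    return df if stratum == "Total" else df[df["stage"] == stratum]


def _two_group_rows(df: pd.DataFrame, variables: dict, groups: tuple) -> list[dict]:
    rows = []
    for stratum in _STRATA:
        sub = _stratify(df, stratum)
        if sub.empty:
            warnings.warn(f"stratum {stratum!r} empty; block omitted")
            continue
        for var, col in variables.items():
            row = {"stratum": stratum, "variable": var}
            vals = {g: sub.loc[sub["group"] == g, col].dropna().to_numpy()
                    for g in groups}
            for g in groups:
                row[f"{g} (mean ± SD)"] = _mean_sd(vals[g]) if vals[g].size else "-"
            if all(v.size >= 2 for v in vals.values()):
                cmp = compare_groups(vals[groups[0]], vals[groups[1]])
                row["p"] = round(cmp["p"], 4)
                row["significant"] = cmp["p"] < 0.05
            rows.append(row)
    return rows


def build_report_tables(cohort: pd.DataFrame, geometry: pd.DataFrame | None = None,
                        mode_comparison: pd.DataFrame | None = None,
                        strain_peaks: pd.DataFrame | None = None) -> dict:
    """Assemble the four study-style report tables.

    table1: demographics (BSA by stage); table2: indexed volumes and EF,
    Total / stage I / stage II blocks; table3: 2D geometric indices;
    table4: strain and strain-rate peaks by direction and level.  Tables
    for which inputs are missing are omitted from the result.
    """
    groups = tuple(pd.unique(cohort["group"]))
    single_group = len(groups) < 2
    out: dict[str, pd.DataFrame] = {}

    rows = []
    for stage in ("I", "II"):
        sub = cohort[cohort["stage"] == stage]
        row = {"variable": f"BSA m2 (stage {stage})"}
        for g in groups:
            row[f"{g} (mean ± SD)"] = _mean_sd(sub.loc[sub["group"] == g, "bsa_m2"])
            row[f"n_{g}"] = int((sub["group"] == g).sum())
        if not single_group:
            a = sub.loc[sub["group"] == groups[0], "bsa_m2"].to_numpy()
            b = sub.loc[sub["group"] == groups[1], "bsa_m2"].to_numpy()
            if a.size >= 2 and b.size >= 2:
                row["p"] = round(compare_groups(a, b)["p"], 4)
        rows.append(row)
    out["table1"] = pd.DataFrame(rows)

    if geometry is not None:
        merged = geometry.merge(cohort, on="subject_id")
        if not single_group:
            vol_vars = {"iEDV ml/BSA^1.3": "iedv", "iESV ml/BSA^1.3": "iesv",
                        "iSV ml/BSA^1.3": "isv", "EF %": "ef_pct"}
            out["table2"] = pd.DataFrame(_two_group_rows(merged, vol_vars, groups))
            geo_vars = {"Myocardial mass (indexed)": "imass",
                        "Length mm/sqrt(m2)": "ilength",
                        "Max cavity diameter mm/sqrt(m2)": "icavity_diam",
                        "Max epicardial diameter mm/sqrt(m2)": "iepi_diam",
                        "Sphericity ratio": "sphericity_ratio",
                        "Max wall thickness mm/sqrt(m2)": "imax_wall",
                        "SD septal wall thickness mm/sqrt(m2)": "isd_septal_wall"}
            geo_vars = {k: v for k, v in geo_vars.items() if v in merged.columns}
            out["table3"] = pd.DataFrame(_two_group_rows(merged, geo_vars, groups))
        else:
            desc = merged.describe().T[["mean", "std"]]
            out["table2"] = desc.reset_index().rename(columns={"index": "variable"})

    if mode_comparison is not None:
        out["mode_comparison"] = mode_comparison

    if strain_peaks is not None and not single_group:
        merged = strain_peaks.merge(cohort, on="subject_id")
        rows = []
        for (level, direction), sub in merged.groupby(["level", "direction"]):
            for metric in ("systolic_strain_pct", "systolic_rate_per_s",
                           "diastolic_rate_per_s"):
                row = {"level": level, "direction": direction, "metric": metric}
                vals = {g: sub.loc[sub["group"] == g, metric].dropna().to_numpy()
                        for g in groups}
                for g in groups:
                    row[f"{g} (mean ± SD)"] = (
                        f"{vals[g].mean():.2f} ± {vals[g].std(ddof=1):.2f}"
                        if vals[g].size > 1 else "-")
                if all(v.size >= 2 for v in vals.values()):
                    cmp = compare_groups(vals[groups[0]], vals[groups[1]])
                    row["p"] = round(cmp["p"], 4)
                    row["significant"] = cmp["p"] < 0.05
                rows.append(row)
        out["table4"] = pd.DataFrame(rows)
    return out
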