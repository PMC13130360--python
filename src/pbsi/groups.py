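"""Group-level statistics: matching, outlier exclusion, adjusted regression,
ANOVA with Tukey-Kramer post-hoc tests, and the demographics table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .atlas import MEASURE_CLASSES
from .core import Z_COLUMNS
from .errors import AnalysisError

ALPHA = 0.05

PBSI_MEASURES = list(Z_COLUMNS)


# -- outlier exclusion -------------------------------------------------------

def iqr_keep_mask(values: np.ndarray) -> np.ndarray:
    """True for values inside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics.  NaNs are
    kept (they carry no evidence of being outlying).
    """
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size < 4:
        raise AnalysisError(f"need >= 4 values for quartiles, got {finite.size}")
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    with np.errstate(invalid="ignore"):
        keep = (values >= lo) & (values <= hi)
    return keep | np.isnan(values)


def exclude_outliers(scores: pd.DataFrame, measures: list[str] | None = None,
                     policy: str = "per-measure") -> pd.DataFrame:
    """Per-group IQR flagging of raw PBSI scores.

    Returns a boolean keep-mask frame (subjects x measures).  Under the
    default ``per-measure`` policy a subject flagged on one measure still
    contributes to the others; ``listwise`` drops flagged subjects from every
    measure.
    """
    if policy not in ("per-measure", "listwise"):
        raise ValueError(f"unknown outlier policy {policy!r}")
    measures = measures or [f"raw_{m}" for m in MEASURE_CLASSES]
    keep = pd.DataFrame(True, index=scores.index, columns=measures)
    for _, part in scores.groupby("group", sort=False):
        for measure in measures:
            keep.loc[part.index, measure] = iqr_keep_mask(part[measure].to_numpy())
    if policy == "listwise":
        rows = keep.all(axis=1)
        keep.loc[:, :] = rows.to_numpy()[:, None]
    return keep


# -- age/sex matching --------------------------------------------------------

def match_groups(meta: pd.DataFrame, treated_groups: list[str],
                 control_group: str = "HC", ratio: int = 1,
                 seed: int = 0) -> pd.Index:
    """Greedy nearest-neighbour age matching within exact sex strata.

    Every treated subject is retained; for each (in seeded random order) up
    to ``ratio`` controls with the closest age and the same sex are selected
    without replacement.  Returns the retained subject index.
    """
    rng = np.random.default_rng(seed)
    treated = meta.index[meta["group"].isin(treated_groups)]
    controls = meta.index[meta["group"] == control_group]
    if len(treated) == 0 or len(controls) == 0:
        raise AnalysisError("both treated and control pools must be non-empty")

    selected: list = []
    for sex in sorted(meta["sex"].unique()):
        t_ids = [s for s in treated if meta.at[s, "sex"] == sex]
        pool = [s for s in controls if meta.at[s, "sex"] == sex]
        if not t_ids:
            continue
        if not pool:
            warnings.warn(f"no controls in sex stratum {sex}; stratum skipped",
                          stacklevel=2)
            continue
        order = rng.permutation(len(t_ids))
        pool_ages = {s: meta.at[s, "age"] for s in pool}
        available = set(pool)
        for k in order:
            t_age = meta.at[t_ids[k], "age"]
            for _ in range(ratio):
                if not available:
                    break
                # seeded jitter breaks exact distance ties deterministically
                best = min(available,
                           key=lambda s: (abs(pool_ages[s] - t_age), rng.random()))
                available.remove(best)
                selected.append(best)
    retained = list(treated) + selected
    return meta.index[meta.index.isin(retained)]


# -- group comparison --------------------------------------------------------

@dataclass
class MeasureComparison:
    """Statistics for one PBSI measure."""

    measure: str
    regression: pd.DataFrame      # term, coef, se, t, p  (age/sex adjusted)
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    tukey: pd.DataFrame           # group1, group2, diff, se, q, p_adj
    n_per_group: dict[str, int]


@dataclass
class GroupComparisonResult:
    measures: dict[str, MeasureComparison] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary mirroring a group-differences table."""
        rows = []
        for m, comp in self.measures.items():
            for _, row in comp.tukey.iterrows():
                rows.append({
                    "measure": m, "contrast": f"{row.group1} - {row.group2}",
                    "diff": row["diff"], "se": row.se, "q": row.q,
                    "p_adj": row.p_adj,
                    "anova_F": comp.anova_f, "anova_p": comp.anova_p,
                })
        columns = ["measure", "contrast", "diff", "se", "q", "p_adj",
                   "anova_F", "anova_p"]
        return pd.DataFrame(rows, columns=columns)


def tukey_kramer(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """All-pairs Tukey HSD with the Kramer correction for unequal n.

    The adjusted p-value comes from the studentized-range distribution with
    ``k`` groups and the pooled within-group degrees of freedom; at
    ``k = 2`` this reduces exactly to the two-sample pooled t-test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    levels = list(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise AnalysisError("need >= 2 groups for pairwise comparison")
    ns = {g: int((groups == g).sum()) for g in levels}
    if min(ns.values()) < 2:
        raise AnalysisError("every group needs >= 2 observations")
    means = {g: values[groups == g].mean() for g in levels}
    df_within = len(values) - k
    ss_within = sum(((values[groups == g] - means[g]) ** 2).sum() for g in levels)
    msw = ss_within / df_within

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = levels[i], levels[j]
            diff = means[g1] - means[g2]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_within))
            rows.append({"group1": g1, "group2": g2, "diff": diff,
                         "se": se, "q": q, "p_adj": min(p, 1.0)})
    return pd.DataFrame(rows)


def compare_groups(scores: pd.DataFrame, meta: pd.DataFrame,
                   measures: list[str] | None = None,
                   control_group: str = "HC") -> GroupComparisonResult:
    """Age/sex-adjusted OLS plus one-way ANOVA and Tukey-Kramer post-hocs.

    ``scores`` must contain ``group`` and the requested measure columns
    (NaN where a subject was excluded for that measure).
    """
    measures = measures or PBSI_MEASURES
    groups = scores["group"].astype(str)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise AnalysisError("need >= 2 groups represented")
    indicator_levels = sorted(set(levels) - {control_group})

    result = GroupComparisonResult()
    meta = meta.loc[scores.index]
    for measure in measures:
        y = scores[measure]
        keep = y.notna()
        if keep.sum() < len(indicator_levels) + 3:
            raise AnalysisError(f"too few observations for {measure}")
        yk = y[keep].to_numpy(dtype=float)
        gk = groups[keep]

        design = pd.DataFrame({"const": 1.0}, index=y.index[keep])
        for g in indicator_levels:
            design[f"group[{g}]"] = (gk == g).astype(float)
        design["age"] = meta.loc[keep[keep].index, "age"].astype(float)
        design["sex"] = meta.loc[keep[keep].index, "sex"].astype(float)
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise AnalysisError(f"rank-deficient design for {measure}")
        fit = sm.OLS(yk, design.to_numpy()).fit()
        regression = pd.DataFrame({
            "term": design.columns, "coef": fit.params, "se": fit.bse,
            "t": fit.tvalues, "p": fit.pvalues,
        })

        present = [g for g in levels if (gk == g).any()]
        samples = [yk[(gk == g).to_numpy()] for g in present]
        f_stat, p_anova = stats.f_oneway(*samples)
        tukey = tukey_kramer(yk, gk.to_numpy())

        result.measures[measure] = MeasureComparison(
            measure=measure, regression=regression,
            anova_f=float(f_stat),
            anova_df=(len(present) - 1, int(keep.sum()) - len(present)),
            anova_p=float(p_anova), tukey=tukey,
            n_per_group={g: int((gk == g).sum()) for g in present},
        )
    return result


# -- demographics ------------------------------------------------------------

def chi_square(counts: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    stat, p, dof, _ = stats.chi2_contingency(np.asarray(counts), correction=False)
    return float(stat), float(p), int(dof)


def demographics_table(meta: pd.DataFrame, clinical: pd.DataFrame | None = None,
                       control_group: str = "HC") -> pd.DataFrame:
    """Per-group mean +/- SD summaries with the matching significance tests.

    Three-group continuous variables get one-way ANOVA, patient-only
    variables (dose, duration, GAF) a two-sample t-test, and sex a
    chi-square test.
    """
    groups = list(pd.unique(meta["group"].astype(str)))
    patient_groups = [g for g in groups if g != control_group]
    rows = []

    def summarise(series: pd.Series, by: pd.Series, label: str, test: str) -> None:
        data = pd.DataFrame({"value": series, "group": by}).dropna()
        row: dict = {"variable": label, "test": test}
        present = [g for g in groups if (data["group"] == g).any()]
        for g in groups:
            sub = data.loc[data["group"] == g, "value"]
            row[f"{g}_mean"] = sub.mean() if len(sub) else np.nan
            row[f"{g}_sd"] = sub.std(ddof=1) if len(sub) > 1 else np.nan
            row[f"{g}_n"] = len(sub)
        samples = [data.loc[data["group"] == g, "value"].to_numpy() for g in present]
        if test == "anova" and len(present) >= 3:
            stat, p = stats.f_oneway(*samples)
        elif len(present) >= 2:
            stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        else:
            stat, p = np.nan, np.nan
        row["statistic"], row["p"] = float(stat), float(p)
        rows.append(row)

    summarise(meta["age"], meta["group"], "age", "anova")

    sex_counts = pd.crosstab(meta["group"], meta["sex"]).reindex(groups).to_numpy()
    stat, p, _ = chi_square(sex_counts)
    sex_row: dict = {"variable": "sex", "test": "chi2",
                     "statistic": stat, "p": p}
    for g in groups:
        sub = meta.loc[meta["group"] == g, "sex"]
        sex_row[f"{g}_mean"] = sub.mean()  # proportion female
        sex_row[f"{g}_sd"] = np.nan
        sex_row[f"{g}_n"] = len(sub)
    rows.append(sex_row)

    if clinical is not None:
        joined = clinical.loc[clinical.index.intersection(meta.index)]
        by = meta.loc[joined.index, "group"]
        for var in ("fsiq", "mq"):
            if var in joined:
                summarise(joined[var], by, var, "anova")
        patient_by = by[by.isin(patient_groups)]
        for var in ("gaf", "panss_total", "illness_duration", "antipsychotic_dose"):
            if var in joined:
                summarise(joined.loc[patient_by.index, var], patient_by, var, "ttest")

    order = ["variable", "test", "statistic", "p"]
    extra = [c for c in rows[0] if c not in order]
    return pd.DataFrame(rows)[order + extra]


def duration_split(duration_years: pd.Series, threshold: float = 5.0) -> pd.Series:
    """Recent-onset (<= threshold years) vs chronic (> threshold) labels."""
    out = pd.Series(pd.NA, index=duration_years.index, dtype=object)
    out[duration_years <= threshold] = "recent"
    out[duration_years > threshold] = "chronic"
    return out
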