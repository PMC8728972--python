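"""Group comparisons: chi-square, t-tests, and two-way mixed ANOVA.

These reproduce the descriptive layer of a two-group repeated-measures
cohort study: categorical characteristics compared by Pearson chi-square
(no continuity correction by default), continuous ones by the
independent-samples t-test (pooled-variance Student by default, Welch via
flag), and each repeated biomarker by a two-way mixed-design ANOVA with
group as the between factor and visit (time) as the within factor.  With
only two within levels sphericity holds trivially, so no correction is
applied.

The mixed ANOVA is implemented from its sums-of-squares decomposition
rather than delegated, so the statistic is fully specified: with t = 2 the
design is equivalent to a one-way ANOVA on per-subject means (group
effect) and on per-subject visit differences (time and interaction
effects), which is the decomposition used here; it remains valid for
unbalanced group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BIOMARKERS, GDM, NON_GDM, CohortTable

_GROUPS = (NON_GDM, GDM)


class DegenerateTableError(ValueError):
    """A contingency table has a zero marginal."""


class InsufficientDataError(ValueError):
    """Fewer than two subjects in a group."""


class TTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


class MixedAnovaResult(NamedTuple):
    f_interaction: float
    p_interaction: float
    f_group: float
    p_group: float
    f_time: float
    p_time: float


def t_test_summary(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Two-sided independent-samples t-test from summary statistics.

    ``variant="pooled"`` is the classical Student test (df = n1 + n2 - 2);
    ``variant="welch"`` uses the Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if not (s1 > 0 and s2 > 0):
        raise ValueError("SDs must be > 0")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def chi_square(table, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    No Yates continuity correction by default; df = (r-1)(c-1).
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return ChiSquareResult(float(chi2), int(df), float(p))


def _mixed_anova_arrays(
    y1: np.ndarray, y2: np.ndarray, groups: np.ndarray
) -> MixedAnovaResult:
    """Mixed ANOVA from per-subject visit-1/visit-2 values and group labels.

    Between part: one-way ANOVA on subject means.  Within part: the time
    effect tests the mean of d = y2 - y1 against 0 and the interaction is a
    one-way ANOVA on d, both against the within-subject error.  Exact for
    t = 2 within levels.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise InsufficientDataError("need at least two groups")
    ng = np.array([np.sum(groups == g) for g in levels])
    if (ng < 2).any():
        raise InsufficientDataError("each group needs >= 2 subjects")
    n = y1.size
    a = levels.size
    subj_mean = 0.5 * (y1 + y2)
    d = y2 - y1

    # between-subjects stratum (x2: each subject contributes b=2 obs)
    grand = subj_mean.mean()
    gmeans = np.array([subj_mean[groups == g].mean() for g in levels])
    ss_group = 2.0 * np.sum(ng * (gmeans - grand) ** 2)
    ss_subj = 2.0 * sum(
        ((subj_mean[groups == g] - gm) ** 2).sum()
        for g, gm in zip(levels, gmeans)
    )
    df_group, df_subj = a - 1, n - a
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    p_group = float(stats.f.sf(f_group, df_group, df_subj))

    # within-subject stratum (in terms of d = y2 - y1: Var contributions /2)
    dmeans = np.array([d[groups == g].mean() for g in levels])
    dbar = d.mean()
    ss_time = 0.5 * n * dbar**2
    ss_inter = 0.5 * np.sum(ng * (dmeans - dbar) ** 2)
    ss_err = 0.5 * np.sum(
        [((d[groups == g] - dm) ** 2).sum() for g, dm in zip(levels, dmeans)]
    )
    df_time, df_inter, df_err = 1, a - 1, n - a
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        # ms_err = 0 only for exactly-degenerate data; F becomes inf/nan
        f_time = (ss_time / df_time) / ms_err
        f_inter = (ss_inter / df_inter) / ms_err
    return MixedAnovaResult(
        f_interaction=float(f_inter),
        p_interaction=float(stats.f.sf(f_inter, df_inter, df_err)),
        f_group=float(f_group),
        p_group=p_group,
        f_time=float(f_time),
        p_time=float(stats.f.sf(f_time, df_time, df_err)),
    )


def mixed_anova(table: CohortTable, marker: str) -> MixedAnovaResult:
    """Two-way mixed-design ANOVA for one biomarker (group x visit)."""
    if marker not in BIOMARKERS:
        raise ValueError(f"unknown biomarker {marker!r}")
    df = table.data.sort_values(["subject_id", "visit"], kind="mergesort")
    vals = df[marker].to_numpy(float).reshape(-1, 2)
    groups = df["group"].to_numpy(int)[::2]
    return _mixed_anova_arrays(vals[:, 0], vals[:, 1], groups)


@dataclass
class GroupSummary:
    """Cohort descriptives by group with the appropriate test per variable.

    ``characteristics``: one row per continuous covariate or categorical
    level (mean +/- SD or count (%)) with the t-test / chi-square p-value.
    ``marker_trends``: one row per biomarker x visit with group means/SDs
    and the mixed-ANOVA group, time and interaction p-values.
    """

    characteristics: pd.DataFrame
    marker_trends: pd.DataFrame
    group_sizes: dict


def describe_by_group(table: CohortTable, t_variant: str = "pooled") -> GroupSummary:
    """Tabulate the cohort the way two-group screening studies report it.

    For a single-group table all test columns are NaN (not applicable).
    Output row order and labels are deterministic.
    """
    df = table.data
    groups_per_subject = table.subject_groups()
    sizes = {g: int((groups_per_subject == g).sum()) for g in _GROUPS}
    two_groups = sizes[NON_GDM] >= 2 and sizes[GDM] >= 2

    char_rows = []
    # continuous covariates: age (visit-stationary), bmi/sbp/dbp per visit
    cont_vars = [("age", None)] + [
        (v, visit) for v in ("bmi", "dbp", "sbp") for visit in (1, 2)
    ]
    for var, visit in cont_vars:
        sub = df if visit is None else df[df["visit"] == visit]
        if visit is None:
            sub = sub[sub["visit"] == 1]  # one row per subject
        cells = {}
        stats_parts = {}
        for g in _GROUPS:
            vals = sub.loc[sub["group"] == g, var].to_numpy(float)
            if vals.size:
                cells[g] = f"{vals.mean():.2f} +/- {vals.std(ddof=1):.2f}"
                stats_parts[g] = (vals.mean(), vals.std(ddof=1), vals.size)
            else:
                cells[g] = "-"
        if two_groups:
            m1, s1, n1 = stats_parts[NON_GDM]
            m2, s2, n2 = stats_parts[GDM]
            tt = t_test_summary(m1, s1, n1, m2, s2, n2, variant=t_variant)
            stat, pval = tt.statistic, tt.pvalue
        else:
            stat, pval = np.nan, np.nan
        label = var if visit is None else f"{var} (visit {visit})"
        char_rows.append(
            {
                "variable": label,
                "level": "-",
                "non_gdm": cells[NON_GDM],
                "gdm": cells[GDM],
                "test": "t" if two_groups else "n/a",
                "statistic": stat,
                "p": pval,
            }
        )
    # categoricals
    first = df[df["visit"] == 1]
    for var, levels in (
        ("parity", [0, 1, 2, 3]),
        ("education", ["non-academic", "academic"]),
    ):
        counts = np.zeros((len(levels), 2))
        for j, g in enumerate(_GROUPS):
            sub = first.loc[first["group"] == g, var]
            for i, lev in enumerate(levels):
                counts[i, j] = int((sub == lev).sum())
        present = counts.sum(axis=1) > 0
        if two_groups and present.sum() >= 2:
            cs = chi_square(counts[present].T)
            stat, pval = cs.statistic, cs.pvalue
            test = "chi2"
        else:
            stat, pval, test = np.nan, np.nan, "n/a"
        for i, lev in enumerate(levels):
            n1, n2 = counts[i]
            tot1 = max(counts[:, 0].sum(), 1)
            tot2 = max(counts[:, 1].sum(), 1)
            char_rows.append(
                {
                    "variable": var,
                    "level": str(lev),
                    "non_gdm": f"{int(n1)} ({100 * n1 / tot1:.1f}%)",
                    "gdm": f"{int(n2)} ({100 * n2 / tot2:.1f}%)",
                    "test": test if i == 0 else "",
                    "statistic": stat if i == 0 else np.nan,
                    "p": pval if i == 0 else np.nan,
                }
            )

    marker_rows = []
    for marker in BIOMARKERS:
        if two_groups:
            an = mixed_anova(table, marker)
        else:
            an = None
        for visit in (1, 2):
            sub = df[df["visit"] == visit]
            cells = {}
            for g in _GROUPS:
                vals = sub.loc[sub["group"] == g, marker].to_numpy(float)
                cells[g] = (
                    f"{vals.mean():.2f} +/- {vals.std(ddof=1):.2f}"
                    if vals.size
                    else "-"
                )
            marker_rows.append(
                {
                    "marker": marker,
                    "visit": visit,
                    "non_gdm": cells[NON_GDM],
                    "gdm": cells[GDM],
                    "p_group": an.p_group if an else np.nan,
                    "p_time": an.p_time if an else np.nan,
                    "p_interaction": an.p_interaction if an else np.nan,
                }
            )
    return GroupSummary(
        characteristics=pd.DataFrame(char_rows),
        marker_trends=pd.DataFrame(marker_rows),
        group_sizes=sizes,
    )
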