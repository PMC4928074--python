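"""Group-comparison statistics and tabular reporting.

The study's conventions: sample averages as mean +/- SEM (SD on
restitution curves), two-tailed Welch t-tests for two-group comparisons,
and one-way ANOVA with post-hoc Tukey HSD for multiple groups — applied
independently at each pacing cycle length when comparing restitution
curves.  The experimental unit is the slice: feed one summary value per
slice per condition; pixel-level samples within a slice are not
independent and per-pixel testing should be treated as exploratory.
"""

from __future__ import annotations

import itertools
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "welch_t",
    "welch_t_from_summary",
    "anova_tukey",
    "tukey_from_summary",
    "compare_restitution",
    "report",
]


@dataclass
class GroupSummary:
    """n, mean, SD (n-1 denominator) and SEM of one group."""

    label: str
    n: int
    mean: float
    sd: float
    sem: float


@dataclass
class ComparisonResult:
    """Outcome of a Welch t-test or ANOVA + Tukey HSD.

    For ``welch_t``: ``statistic`` is t, ``df`` the Welch-Satterthwaite
    degrees of freedom, ``p_value`` two-tailed.  For ``anova_tukey``:
    ``statistic`` is F, ``df`` = (between, within), ``p_value`` the omnibus
    p, and ``pairwise`` a symmetric label-indexed table of Tukey-adjusted
    p-values.
    """

    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    alpha: float = 0.05
    pairwise: pd.DataFrame | None = None
    labels: list[str] = field(default_factory=list)


def summarize(values, label: str = "") -> GroupSummary:
    """Mean, SD and SEM of one group (n >= 2)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to summarize a group")
    sd = float(x.std(ddof=1))
    return GroupSummary(label=label, n=int(x.size), mean=float(x.mean()),
                        sd=sd, sem=sd / np.sqrt(x.size))


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------


def welch_t(a, b, alpha: float = 0.05) -> ComparisonResult:
    """Two-tailed t-test assuming unequal variances (Welch)."""
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return ComparisonResult("welch_t", 0.0, float(x.size + y.size - 2), 1.0,
                                    alpha)
        raise ValueError(
            "both groups have zero variance but different means; "
            "a t-test is undefined (p would be 0)"
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return ComparisonResult("welch_t", float(res.statistic), float(res.df),
                            float(res.pvalue), alpha)


def welch_t_from_summary(n1: int, mean1: float, sd1: float,
                         n2: int, mean2: float, sd2: float,
                         alpha: float = 0.05) -> ComparisonResult:
    """Welch t-test from printed summary statistics (n, mean, SD)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return ComparisonResult("welch_t", 0.0, float(n1 + n2 - 2), 1.0, alpha)
        raise ValueError("zero variance with unequal means")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult("welch_t", float(t), float(df), float(p), alpha)


# ---------------------------------------------------------------------------
# One-way ANOVA with Tukey HSD
# ---------------------------------------------------------------------------


def anova_tukey(groups, labels=None, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA with post-hoc Tukey honestly-significant-difference test.

    The omnibus F compares between- to within-group variance; pairwise
    p-values come from the studentized range distribution with the pooled
    within-group variance.  For two groups the Tukey p equals the pooled
    two-sided t-test p (q = t * sqrt(2)).
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels length must match groups")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")

    if all(g.std() == 0 for g in gs) and len({g.mean() for g in gs}) == 1:
        f_stat, p_omni = 0.0, 1.0
        pairwise = pd.DataFrame(np.ones((len(gs), len(gs))), index=labels,
                                columns=labels)
    else:
        f_stat, p_omni = stats.f_oneway(*gs)
        tk = stats.tukey_hsd(*gs)
        pairwise = pd.DataFrame(np.asarray(tk.pvalue), index=labels, columns=labels)
    df_between = len(gs) - 1
    df_within = sum(g.size for g in gs) - len(gs)
    return ComparisonResult(
        test="anova_tukey",
        statistic=float(f_stat),
        df=(float(df_between), float(df_within)),
        p_value=float(p_omni),
        alpha=alpha,
        pairwise=pairwise,
        labels=labels,
    )


def tukey_from_summary(summaries: list[GroupSummary], alpha: float = 0.05
                       ) -> ComparisonResult:
    """ANOVA + Tukey HSD from per-group (n, mean, SD) summary statistics.

    Lets printed tables be re-analyzed when raw values are unavailable.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.n < 2 for s in summaries):
        raise ValueError("every group needs n >= 2")
    labels = [s.label or f"group{i}" for i, s in enumerate(summaries)]
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_tot = ns.sum()
    k = len(summaries)
    grand = (ns * means).sum() / n_tot
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds ** 2).sum()
    df_between, df_within = k - 1, n_tot - k
    if ss_within == 0:
        raise ValueError("zero pooled within-group variance")
    ms_within = ss_within / df_within
    f_stat = (ss_between / df_between) / ms_within
    p_omni = float(stats.f.sf(f_stat, df_between, df_within))
    pv = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(means[i] - means[j]) / se
        p = float(stats.studentized_range.sf(q, k, df_within))
        pv[i, j] = pv[j, i] = p
    pairwise = pd.DataFrame(pv, index=labels, columns=labels)
    return ComparisonResult("anova_tukey", float(f_stat),
                            (float(df_between), float(df_within)), p_omni,
                            alpha, pairwise, labels)


# ---------------------------------------------------------------------------
# Restitution comparisons
# ---------------------------------------------------------------------------


def compare_restitution(samples_by_condition: dict, alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Independent ANOVA + Tukey HSD at each pacing cycle length.

    ``samples_by_condition`` maps condition label -> {pcl_ms -> list of
    per-slice durations}.  Cycle lengths not shared by all conditions are
    dropped with a warning.  Returns a long table with one row per
    (pcl_ms, condition pair): Tukey-adjusted p and a significance flag.
    """
    conditions = list(samples_by_condition)
    if len(conditions) < 2:
        return pd.DataFrame(columns=["pcl_ms", "group_a", "group_b",
                                     "p_value", "significant"])
    pcl_sets = [set(samples_by_condition[c]) for c in conditions]
    shared = sorted(set.intersection(*pcl_sets), reverse=True)
    dropped = set.union(*pcl_sets) - set(shared)
    if dropped:
        warnings.warn(
            f"cycle lengths {sorted(dropped)} not present in every condition; "
            "restricted to the shared set", stacklevel=2)
    if not shared:
        raise ValueError("conditions share no pacing cycle length")
    rows = []
    for pcl in shared:
        groups = [samples_by_condition[c][pcl] for c in conditions]
        res = anova_tukey(groups, labels=conditions, alpha=alpha)
        for a, b in itertools.combinations(conditions, 2):
            p = float(res.pairwise.loc[a, b])
            rows.append({"pcl_ms": pcl, "group_a": a, "group_b": b,
                         "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(summaries: list[GroupSummary], comparisons=None, out_dir=".",
           per_pcl_flags: pd.DataFrame | None = None,
           config: dict | None = None, seed: int | None = None) -> dict[str, Path]:
    """Write CSV tables (summaries, pairwise p-values, per-PCL flags) and a
    plain-text run log with library versions, the seed and a config echo."""
    labels = [s.label for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in summaries")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    df = pd.DataFrame([{"label": s.label, "n": s.n, "mean": s.mean,
                        "sd": s.sd, "sem": s.sem} for s in summaries])
    paths["summaries"] = out / "group_summaries.csv"
    df.to_csv(paths["summaries"], index=False)

    rows = []
    for comp in (comparisons or []):
        if comp.pairwise is not None:
            for a, b in itertools.combinations(comp.labels, 2):
                rows.append({"test": comp.test, "group_a": a, "group_b": b,
                             "p_value": float(comp.pairwise.loc[a, b])})
        else:
            rows.append({"test": comp.test, "group_a": "", "group_b": "",
                         "p_value": comp.p_value})
    if rows:
        paths["pairwise"] = out / "pairwise_pvalues.csv"
        pd.DataFrame(rows).to_csv(paths["pairwise"], index=False)

    if per_pcl_flags is not None:
        paths["flags"] = out / "per_pcl_flags.csv"
        per_pcl_flags.to_csv(paths["flags"], index=False)

    log = [
        "slicemap run log",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}, scipy {scipy.__version__}, pandas {pd.__version__}",
        f"seed: {seed}",
        f"config: {config}",
        f"groups: {labels}",
    ]
    paths["log"] = out / "run_log.txt"
    paths["log"].write_text("\n".join(log) + "\n")
    return paths
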