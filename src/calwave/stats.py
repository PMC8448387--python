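"""Two-group statistics: normality-gated tests, mean +/- SEM, percent change.

The comparison workflow mirrors standard slice-physiology reporting: each
metric is summarised per group as mean +/- SEM, normality of each group is
assessed with Shapiro-Wilk, and the two groups are compared with a
two-sided t test when both groups pass the normality gate (p > alpha) or a
two-sided Mann-Whitney U test otherwise.  Effect sizes are printed as
integer percent change of the treated group relative to control.  Western
blot densitometry is normalised to a loading-control band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparison:
    metric: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    shapiro_p_a: float
    shapiro_p_b: float
    test_used: str                        # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    percent_change: int | None            # round(100*(b-a)/a), ties away from 0
    significant: bool
    stars: str


@dataclass
class DensitometryRecord:
    target: float
    control: float
    ratio: float


def mean_sem(values) -> tuple[float, float]:
    """Sample mean and SEM (SD with n-1 denominator over sqrt(n)).

    SEM is nan for a single value.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("mean_sem requires at least one value")
    if v.size < 2:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def percent_change_exact(ctl_mean: float, vpa_mean: float) -> float:
    """Unrounded 100*(vpa - ctl)/ctl."""
    if ctl_mean == 0:
        raise ValueError("percent change undefined for a zero control mean")
    return 100.0 * (vpa_mean - ctl_mean) / ctl_mean


def percent_change(ctl_mean: float, vpa_mean: float) -> int:
    """Integer percent change, rounded half away from zero (+29%, +82% style)."""
    x = percent_change_exact(ctl_mean, vpa_mean)
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _stars(p: float, alpha: float) -> str:
    if not (p < alpha):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "*"


def normality_gated_test(group_a, group_b, alpha: float = 0.05,
                         equal_var: bool = False,
                         metric: str = "") -> GroupComparison:
    """Shapiro-Wilk-gated two-sample comparison.

    Both groups normal at ``alpha`` -> two-sided t test (Welch by default,
    Student's pooled form with ``equal_var=True``); otherwise two-sided
    Mann-Whitney U (exact when both samples are small and tie-free, the
    tie-corrected normal approximation otherwise).  Significance is strict
    (p < alpha); p == alpha is flagged not significant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("A", a), ("B", b)):
        if g.size < 3:
            raise ValueError(f"group {name} has n={g.size} < 3: "
                             "Shapiro-Wilk requires n >= 3")
    pa = float(sps.shapiro(a).pvalue) if a.std() > 0 else 0.0
    pb = float(sps.shapiro(b).pvalue) if b.std() > 0 else 0.0
    if pa > alpha and pb > alpha:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test_used = "t_test"
    else:
        ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (not ties and a.size <= 20 and b.size <= 20) \
            else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test_used = "mann_whitney"
    ma, sa = mean_sem(a)
    mb, sb = mean_sem(b)
    pc = percent_change(ma, mb) if ma != 0 else None
    p = float(res.pvalue)
    return GroupComparison(metric=metric, mean_a=ma, mean_b=mb,
                           sem_a=sa, sem_b=sb, n_a=a.size, n_b=b.size,
                           shapiro_p_a=pa, shapiro_p_b=pb,
                           test_used=test_used, statistic=float(res.statistic),
                           p_value=p, percent_change=pc,
                           significant=bool(p < alpha), stars=_stars(p, alpha))


def normalize_densitometry(target: float, control: float) -> DensitometryRecord:
    """Optical density of a band normalised to its loading-control band."""
    if control <= 0:
        raise ValueError("loading-control optical density must be > 0")
    return DensitometryRecord(target=target, control=control,
                              ratio=target / control)


def densitometry_fold_change(ctl_ratios, vpa_ratios) -> tuple[float, float]:
    """Group mean ratios rescaled so the control group mean is 1.0."""
    c = float(np.mean(ctl_ratios))
    v = float(np.mean(vpa_ratios))
    if c <= 0:
        raise ValueError("control group mean ratio must be > 0")
    return 1.0, v / c


def build_report(slice_metrics: pd.DataFrame, group_col: str = "group",
                 groups: tuple[str, str] = ("CTL", "VPA"),
                 alpha: float = 0.05, equal_var: bool = False,
                 fdr: bool = False) -> pd.DataFrame:
    """One GroupComparison row per metric column of a per-slice table.

    ``slice_metrics`` has one row per slice (or per cell for morphometry)
    with a group column and one numeric column per metric.  Rows with nan
    in a metric are dropped for that metric.  ``fdr=True`` adds
    Benjamini-Hochberg adjusted p-values (off by default).
    """
    ga, gb = groups
    present = set(slice_metrics[group_col].unique())
    for g in groups:
        if g not in present:
            raise ValueError(f"group {g!r} missing from the metrics table")
    rows = []
    metrics = [c for c in slice_metrics.columns if c != group_col]
    for m in metrics:
        a = slice_metrics.loc[slice_metrics[group_col] == ga, m].dropna()
        b = slice_metrics.loc[slice_metrics[group_col] == gb, m].dropna()
        if len(a) < 3 or len(b) < 3:
            continue
        cmp_ = normality_gated_test(a, b, alpha=alpha, equal_var=equal_var,
                                    metric=m)
        rows.append(cmp_.__dict__)
    report = pd.DataFrame(rows)
    if fdr and len(report):
        from statsmodels.stats.multitest import multipletests
        report["p_adj_bh"] = multipletests(report["p_value"],
                                           method="fdr_bh")[1]
    return report
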