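"""Stage (DIV) temporal profiles, growth rates and group comparisons.

Per-view or per-cell metrics are aggregated into mean +/- SEM per
developmental stage; growth rates are first derivatives of the stage-mean
curves on the irregular DIV grid; functional and morphological profiles
are related by ordinary least squares; group comparisons use the two-tailed
unpaired Student's t-test (two groups) or one-way ANOVA with Bonferroni
post hoc pairwise tests (three or more), with the conventional star coding
(* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StageProfile",
    "GroupComparison",
    "stage_profiles",
    "growth_rates",
    "profile_correlation",
    "group_compare",
    "significance_stars",
]


@dataclass
class StageProfile:
    """Per-stage mean, SEM and sample size of one metric."""

    stage_days: np.ndarray      # DIV, strictly increasing
    mean: np.ndarray
    sem: np.ndarray             # SD/sqrt(n); NaN where n == 1
    n: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        if not (
            len(self.stage_days) == len(self.mean) == len(self.sem) == len(self.n)
        ):
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(self.stage_days) <= 0):
            raise ValueError("stage_days must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "div": self.stage_days,
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
                "metric": self.metric_name,
            }
        )


@dataclass
class GroupComparison:
    """Result of a two-group t-test or a multi-group ANOVA + Bonferroni."""

    test: str                   # "t_test_two_tailed_unpaired" | "anova_bonferroni"
    statistic: float            # t or F
    p_value: float
    stars: str
    pairwise: pd.DataFrame | None = None   # per-pair t, raw p, adjusted p, stars


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def stage_profiles(
    records: pd.DataFrame,
    value_col: str,
    stage_col: str = "div",
) -> StageProfile:
    """Aggregate a metric table with DIV labels into a stage profile.

    Stages with no finite values are dropped with a warning; single-value
    stages get NaN SEM (flagged rather than zero).
    """
    df = records[[stage_col, value_col]].dropna()
    if df.empty:
        raise ValueError("no records to aggregate")
    grouped = df.groupby(stage_col)[value_col]
    days = np.array(sorted(grouped.groups))
    dropped = set(records[stage_col].unique()) - set(days)
    if dropped:
        warnings.warn(
            f"stages with no values dropped: {sorted(dropped)}",
            RuntimeWarning,
            stacklevel=2,
        )
    mean = grouped.mean().loc[days].to_numpy()
    n = grouped.count().loc[days].to_numpy()
    sd = grouped.std(ddof=1).loc[days].to_numpy()
    sem = np.where(n > 1, sd / np.sqrt(n), np.nan)
    return StageProfile(
        stage_days=days, mean=mean, sem=sem, n=n, metric_name=value_col
    )


def growth_rates(profile: StageProfile) -> tuple[np.ndarray, np.ndarray]:
    """First derivative of the stage-mean curve (units/day).

    Returns ``(midpoint_days, rates)`` where
    ``rates[i] = (mean[i+1] - mean[i]) / (day[i+1] - day[i])`` is assigned
    to the midpoint of each stage interval.
    """
    days = np.asarray(profile.stage_days, dtype=float)
    if days.size < 2:
        raise ValueError("need at least two stages")
    dd = np.diff(days)
    if np.any(dd == 0):
        raise ValueError("duplicate stage days")
    rates = np.diff(profile.mean) / dd
    midpoints = (days[:-1] + days[1:]) / 2.0
    return midpoints, rates


def profile_correlation(
    x: StageProfile, y: StageProfile
) -> tuple[float, float, float]:
    """OLS fit of y stage means on x stage means: (slope, intercept, R^2).

    Degenerate y (zero variance) yields R^2 = 0 with a warning; degenerate
    x raises, as the fit is undefined.
    """
    if not np.array_equal(x.stage_days, y.stage_days):
        raise ValueError("profiles must share the same stage grid")
    if x.stage_days.size < 3:
        raise ValueError("need at least three stages")
    xv, yv = x.mean, y.mean
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in x profile")
    if np.ptp(yv) == 0:
        warnings.warn(
            "y profile has zero variance; R^2 reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, float(yv[0]), 0.0
    res = stats.linregress(xv, yv)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def group_compare(
    groups: dict[str, np.ndarray],
    test: str = "auto",
) -> GroupComparison:
    """Compare labelled samples by t-test (2 groups) or ANOVA + Bonferroni.

    ``test`` may be "auto", "t_test_two_tailed_unpaired" or
    "anova_bonferroni".  The Bonferroni correction multiplies each raw
    pairwise p by m = g*(g-1)/2, capped at 1.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least two values")
    if test == "auto":
        test = "t_test_two_tailed_unpaired" if len(samples) == 2 else "anova_bonferroni"

    if test == "t_test_two_tailed_unpaired":
        if len(samples) != 2:
            raise ValueError("t-test requires exactly two groups")
        t, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        if np.isnan(p):  # both groups constant and identical
            t, p = 0.0, 1.0
        return GroupComparison(
            test=test, statistic=float(t), p_value=float(p), stars=significance_stars(p)
        )

    if test != "anova_bonferroni":
        raise ValueError(f"unknown test {test!r}")
    F, p = stats.f_oneway(*samples)
    if np.isnan(p):
        F, p = 0.0, 1.0
    m = len(samples) * (len(samples) - 1) // 2
    rows = []
    for (i, a), (j, b) in combinations(enumerate(labels), 2):
        t_ij, p_ij = stats.ttest_ind(samples[i], samples[j], equal_var=True)
        if np.isnan(p_ij):
            t_ij, p_ij = 0.0, 1.0
        p_adj = min(1.0, float(p_ij) * m)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t_ij),
                "p_raw": float(p_ij),
                "p_bonferroni": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return GroupComparison(
        test=test,
        statistic=float(F),
        p_value=float(p),
        stars=significance_stars(p),
        pairwise=pd.DataFrame(rows),
    )
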