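"""Cohort-level summaries and hypothesis tests.

The analysis conventions are: values reported as mean ± sample SD (n − 1
denominator); follow-up imaging measurements expressed as percent change from
baseline; normality checked with Shapiro–Wilk; one-way ANOVA for multi-group
comparisons with Bonferroni-corrected pairwise follow-ups; unpaired pooled-
variance t tests for two-group comparisons; Pearson's r for correlations; and
p < 0.05 considered significant.

A packaged fixture (``table1.csv``) holds the 18-patient melanoma cohort:
body weight and BMI at three timepoints, last-measurement percent changes of
VAT, SCAT and LTW, therapy and response group.  Checkpoint-inhibitor-only
(CIT) analyses filter therapy to PD-1/CTLA-4 antibodies (n = 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALPHA",
    "CIT_THERAPIES",
    "RESPONSE_GROUPS",
    "StatsResult",
    "load_table1",
    "group_summary",
    "one_way_anova",
    "pairwise_bonferroni",
    "unpaired_t",
    "pearson_r",
    "shapiro_wilk",
]

#: Significance threshold used throughout.
ALPHA = 0.05

#: Checkpoint-inhibitor therapies (the CIT subgroup filter, n = 16 in the fixture).
CIT_THERAPIES = frozenset({"PD-1-mAb", "CTLA-4-mAb"})

RESPONSE_GROUPS = ("PD", "MIXED", "RTT")


@dataclass
class StatsResult:
    """Container for a test outcome: statistic, p value and per-group summaries."""

    test: str
    statistic: float
    p_value: float
    df: tuple[float, ...] | None = None
    group_means: dict[str, float] | None = None
    group_sds: dict[str, float] | None = None
    pairwise: pd.DataFrame | None = None
    adjustment: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def load_table1() -> pd.DataFrame:
    """Load the packaged 18-patient cohort table."""
    with resources.files("adipoquant.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    bad = set(df["Response"]) - set(RESPONSE_GROUPS)
    if bad:
        raise ValueError(f"unknown response labels in fixture: {bad}")
    return df


def _variable_column(df: pd.DataFrame, variable: str) -> str:
    if variable in df.columns:
        return variable
    guess = f"{variable} change from baseline (%)"
    if guess in df.columns:
        return guess
    raise KeyError(f"variable {variable!r} not found in table")


def group_summary(
    table: pd.DataFrame,
    variable: str,
    by: str = "Response",
    therapy_filter: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Mean ± sample SD (n − 1) per group, to full precision.

    A group of size 1 reports SD as NaN (not 0).  ``therapy_filter`` keeps
    only rows whose Therapy is in the given set (e.g. :data:`CIT_THERAPIES`).
    """
    df = table
    if therapy_filter is not None:
        df = df[df["Therapy"].isin(therapy_filter)]
    col = _variable_column(df, variable)
    if df.empty:
        raise ValueError("no subjects remain after filtering")
    out = []
    for name, grp in df.groupby(by, sort=True):
        vals = grp[col].to_numpy(dtype=float)
        out.append(
            {
                by: name,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(out).set_index(by)


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("at least two groups are required")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    return arrs


def one_way_anova(groups: list[np.ndarray]) -> StatsResult:
    """Classical one-way ANOVA: between/within F with (k−1, N−k) df."""
    arrs = _check_groups(groups)
    k = len(arrs)
    n_total = sum(len(a) for a in arrs)
    within_ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    flags = []
    if within_ss == 0 and len({a.mean() for a in arrs}) > 1:
        flags.append("zero within-group variance with unequal means: F is infinite")
        return StatsResult("one-way ANOVA", np.inf, 0.0, (k - 1, n_total - k), flags=flags)
    stat, p = stats.f_oneway(*arrs)
    if np.isnan(stat):  # all values identical in every group
        stat, p = 0.0, 1.0
    return StatsResult("one-way ANOVA", float(stat), float(p), (k - 1, n_total - k))


def unpaired_t(x: np.ndarray, y: np.ndarray) -> StatsResult:
    """Two-sided unpaired Student's t test (pooled variance)."""
    x, y = _check_groups([x, y])
    if np.ptp(x) == 0 and np.ptp(y) == 0:  # degenerate: no pooled variance
        if np.isclose(x.mean(), y.mean()):
            return StatsResult("unpaired t", 0.0, 1.0, (len(x) + len(y) - 2,))
        return StatsResult(
            "unpaired t", np.inf, 0.0, (len(x) + len(y) - 2,),
            flags=["zero pooled variance with unequal means"],
        )
    res = stats.ttest_ind(x, y, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        if np.isclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf, 0.0
    return StatsResult("unpaired t", t, p, (len(x) + len(y) - 2,))


def pairwise_bonferroni(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> StatsResult:
    """All pairwise mean differences with Bonferroni-adjusted p and 95 % CIs.

    Raw two-sided pooled-variance p values are multiplied by the number of
    comparisons (capped at 1); the CI on each difference uses the pair-pooled
    standard error at the unadjusted 95 % level.
    """
    arrs = _check_groups(groups)
    labels = labels or [f"group{i}" for i in range(len(arrs))]
    n_comp = len(arrs) * (len(arrs) - 1) // 2
    rows = []
    for (i, a), (j, b) in combinations(enumerate(arrs), 2):
        na, nb = len(a), len(b)
        df = na + nb - 2
        sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        diff = float(a.mean() - b.mean())
        if se == 0:
            t = 0.0 if diff == 0 else np.inf
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p_raw = 2.0 * stats.t.sf(abs(t), df)
        crit = stats.t.ppf(0.975, df)
        rows.append(
            {
                "pair": f"{labels[i]} vs {labels[j]}",
                "diff": diff,
                "ci_low": diff - crit * se,
                "ci_high": diff + crit * se,
                "t": float(t),
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * n_comp)),
            }
        )
    table = pd.DataFrame(rows).set_index("pair")
    best = table.loc[table["p_adj"].idxmin()]
    return StatsResult(
        "pairwise t (Bonferroni)",
        float(best["t"]),
        float(best["p_adj"]),
        pairwise=table,
        adjustment="bonferroni",
        group_means={lab: float(a.mean()) for lab, a in zip(labels, arrs)},
        group_sds={lab: float(np.std(a, ddof=1)) for lab, a in zip(labels, arrs)},
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> StatsResult:
    """Pearson product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r is undefined for a zero-variance sample")
    r, p = stats.pearsonr(x, y)
    return StatsResult("Pearson r", float(r), float(p), (len(x) - 2,))


def shapiro_wilk(x: np.ndarray) -> StatsResult:
    """Shapiro–Wilk normality test (3 ≤ n ≤ 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = stats.shapiro(x)
    return StatsResult("Shapiro-Wilk", float(w), float(p))
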