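"""Nonparametric group comparisons: Kruskal-Wallis rank sum with tie
correction, Mann-Whitney U pairwise post hocs, Bonferroni adjustment.

Used for consumption volumes, spontaneous-walking measures and
gene-expression-style tables.  Heavy mixed-model machinery (GLMMs, beta
regression, Kenward-Roger post hocs) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "mann_whitney_u",
    "bonferroni",
    "pairwise_mann_whitney",
    "compare_groups",
]

#: Above this product of sample sizes the Mann-Whitney p switches from exact
#: enumeration to the tie-corrected normal approximation.
EXACT_MWU_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: int | None = None
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def kruskal_wallis(*samples) -> TestResult:
    """Kruskal-Wallis H on midranks with tie correction; p from chi-square
    with (groups - 1) df.  All-identical values give H = 0, p = 1."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("kruskal_wallis requires total n >= 3")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal-wallis", 0.0, 1.0, df=df)
    stat, p = sps.kruskal(*samples)
    return TestResult("kruskal-wallis", float(stat), float(p), df=df)


def mann_whitney_u(a, b, alternative: str = "two-sided", method: str = "auto") -> TestResult:
    """Mann-Whitney U with midranks.

    ``method='auto'`` uses exact enumeration when the samples are tie-free
    and ``len(a) * len(b) <= 400``, otherwise the normal approximation with
    tie-corrected variance and continuity correction.  ``'exact'`` and
    ``'asymptotic'`` force the respective path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if tie_free and len(a) * len(b) <= EXACT_MWU_LIMIT else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return TestResult(f"mann-whitney-{method}", float(res.statistic), float(res.pvalue))


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p multiplied by the family size m
    (default: the number of p-values) and capped at 1."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than number of tests {len(p_values)}")
    return [min(1.0, m * float(p)) for p in p_values]


def pairwise_mann_whitney(
    df: pd.DataFrame, group_col: str = "group", value_col: str = "value", alternative: str = "two-sided"
) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons with Bonferroni adjustment over
    the comparisons actually performed.  Returns a tidy table."""
    groups = list(df[group_col].unique())
    rows = []
    for g1, g2 in combinations(groups, 2):
        res = mann_whitney_u(
            df.loc[df[group_col] == g1, value_col],
            df.loc[df[group_col] == g2, value_col],
            alternative=alternative,
        )
        rows.append({"group_a": g1, "group_b": g2, "method": res.method, "U": res.statistic, "p": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p"], m=len(out))
    return out


def compare_groups(df: pd.DataFrame, group_col: str = "group", value_col: str = "value") -> dict:
    """Omnibus Kruskal-Wallis followed by Bonferroni-adjusted pairwise
    Mann-Whitney post hocs on a long-format table."""
    samples = [sub[value_col].to_numpy() for _, sub in df.groupby(group_col, observed=True)]
    omnibus = kruskal_wallis(*samples)
    posthoc = pairwise_mann_whitney(df, group_col, value_col)
    return {"kruskal_wallis": omnibus, "pairwise": posthoc}
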