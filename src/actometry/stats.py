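"""Group comparisons: omnibus tests with Bonferroni-adjusted pairwise tests.

The default path is rank-based — a Kruskal-Wallis omnibus test followed by
all-pairs Mann-Whitney U tests — because the tremor metrics are skewed,
heavy-tailed scalars for which normality is doubtful at the study's group
sizes.  A parametric path (one-way ANOVA omnibus, Welch t pairwise) is
available by flag.  Pairwise p values are Bonferroni-adjusted by the
number of pairs, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairwiseResult", "GroupComparisonResult", "compare_groups"]


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    raw_p: float
    adjusted_p: float
    mean_a: float
    mean_b: float

    def __post_init__(self) -> None:
        if self.adjusted_p < self.raw_p - 1e-12 or self.adjusted_p > 1.0 + 1e-12:
            raise ValueError("adjusted p must lie in [raw p, 1]")


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    groups: tuple[str, ...]
    method: str  # "kruskal" or "anova" (after any degenerate fallback)
    omnibus_stat: float
    omnibus_p: float
    pairwise: tuple[PairwiseResult, ...]
    group_summary: pd.DataFrame  # index: group; columns n, mean, sd

    def significant_pairs(self, alpha: float = 0.05) -> list[PairwiseResult]:
        return [p for p in self.pairwise if p.adjusted_p < alpha]


def _omnibus(samples: list[np.ndarray], method: str) -> tuple[float, float, str]:
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        # every observation identical: no evidence of any difference
        return 0.0, 1.0, "kruskal"
    if method == "anova":
        if any(np.ptp(s) == 0 for s in samples):
            method = "kruskal"  # zero-variance group breaks the F statistic
        else:
            stat, p = sps.f_oneway(*samples)
            return float(stat), float(p), "anova"
    try:
        stat, p = sps.kruskal(*samples)
    except ValueError:  # all numbers identical
        return 0.0, 1.0, "kruskal"
    return float(stat), float(p), "kruskal"


def _pairwise_p(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    if method == "anova":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_groups(
    metrics: pd.DataFrame,
    variable: str,
    method: str = "kruskal",
    group_col: str = "group",
) -> GroupComparisonResult:
    """Compare one metric across groups.

    Requires at least two groups with at least two animals each.  Returns
    the omnibus result plus every pairwise comparison with its raw and
    Bonferroni-adjusted p value.
    """
    if method not in ("kruskal", "anova"):
        raise ValueError("method must be 'kruskal' or 'anova'")
    if variable not in metrics.columns:
        raise KeyError(f"variable {variable!r} not in metrics table")
    clean = metrics[[group_col, variable]].dropna()
    groups = tuple(pd.unique(clean[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    samples = [clean.loc[clean[group_col] == g, variable].to_numpy(float) for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two animals")

    stat, p, used = _omnibus(samples, method)

    pairs = list(combinations(range(len(groups)), 2))
    n_pairs = len(pairs)
    pairwise = []
    for i, j in pairs:
        raw = _pairwise_p(samples[i], samples[j], used)
        pairwise.append(
            PairwiseResult(
                group_a=groups[i],
                group_b=groups[j],
                raw_p=raw,
                adjusted_p=min(1.0, raw * n_pairs),
                mean_a=float(np.mean(samples[i])),
                mean_b=float(np.mean(samples[j])),
            )
        )
    summary = pd.DataFrame(
        {
            "n": [len(s) for s in samples],
            "mean": [float(np.mean(s)) for s in samples],
            "sd": [float(np.std(s, ddof=1)) for s in samples],
        },
        index=list(groups),
    )
    return GroupComparisonResult(
        variable=variable,
        groups=groups,
        method=used,
        omnibus_stat=stat,
        omnibus_p=p,
        pairwise=tuple(pairwise),
        group_summary=summary,
    )
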