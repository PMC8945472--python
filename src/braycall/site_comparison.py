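"""Normality-gated comparison of acoustic parameters between sites.

Each continuous parameter is first tested for normality per group with the
Shapiro–Wilk test. If every group looks normal (p ≥ alpha, default 0.05) a
Welch's t-test is used for two groups; otherwise the two-sided Mann–Whitney U
test. Three or more groups are compared with the Kruskal–Wallis test. All
tests are two-sided and no multiple-testing correction is applied.

The Mann–Whitney p-value is exact for small samples (both n ≤ 20, no ties)
and uses the tie-corrected normal approximation otherwise; the method used is
recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "compare_two", "compare_k", "compare_table"]

_EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one parameter comparison."""

    parameter: str
    groups: tuple[str, ...]
    normality_p: tuple[float, ...]
    test_used: str                      # welch_t | mann_whitney | kruskal_wallis
    statistic: float
    p_value: float
    group_summaries: tuple[dict, ...]   # {"n", "mean", "sd"} per group
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _summaries(groups: Sequence[np.ndarray]) -> tuple[dict, ...]:
    return tuple(
        {"n": int(g.size), "mean": float(g.mean()),
         "sd": float(g.std(ddof=1)) if g.size > 1 else 0.0}
        for g in groups
    )


def _shapiro_p(sample: np.ndarray) -> float:
    # Shapiro-Wilk is degenerate on constant samples; a constant sample is
    # trivially non-Gaussian for gating purposes.
    if np.ptp(sample) == 0:
        return 0.0
    return float(stats.shapiro(sample).pvalue)


def compare_two(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha_normality: float = 0.05,
    parameter: str = "",
    group_names: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-group comparison with a Shapiro–Wilk normality gate.

    Welch's t-test if both groups pass the gate (p ≥ ``alpha_normality``),
    two-sided Mann–Whitney U otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    p_norm = (_shapiro_p(a), _shapiro_p(b))
    metadata: dict = {"alpha_normality": alpha_normality}
    if all(p >= alpha_normality for p in p_norm):
        res = stats.ttest_ind(a, b, equal_var=False)
        test_used, statistic, p_value = "welch_t", res.statistic, res.pvalue
        metadata["df"] = float(res.df)
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        exact = (a.size <= _EXACT_MW_MAX_N and b.size <= _EXACT_MW_MAX_N
                 and not has_ties)
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test_used, statistic, p_value = "mann_whitney", res.statistic, res.pvalue
        metadata["mann_whitney_method"] = method
    return ComparisonResult(
        parameter=parameter,
        groups=tuple(group_names),
        normality_p=p_norm,
        test_used=test_used,
        statistic=float(statistic),
        p_value=float(min(p_value, 1.0)),
        group_summaries=_summaries([a, b]),
        metadata=metadata,
    )


def compare_k(
    groups: Sequence[Sequence[float]],
    parameter: str = "",
    group_names: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Kruskal–Wallis comparison of three or more groups."""
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use compare_two for 2)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    names = tuple(group_names) if group_names else tuple(
        f"group{i + 1}" for i in range(len(arrays))
    )
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all observations identical: no rank separation at all
        h, p = 0.0, 1.0
    else:
        res = stats.kruskal(*arrays)
        h, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        parameter=parameter,
        groups=names,
        normality_p=tuple(_shapiro_p(g) for g in arrays),
        test_used="kruskal_wallis",
        statistic=h,
        p_value=min(p, 1.0),
        group_summaries=_summaries(arrays),
    )


def compare_table(
    df: pd.DataFrame,
    group_col: str = "site",
    parameter_col: str = "parameter",
    value_col: str = "value",
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Run the gated protocol on a long-format table, one row per parameter."""
    rows = []
    for param, sub in df.groupby(parameter_col, sort=True):
        names = tuple(sorted(sub[group_col].unique()))
        samples = [
            sub.loc[sub[group_col] == g, value_col].to_numpy(dtype=float)
            for g in names
        ]
        if len(samples) == 2:
            res = compare_two(samples[0], samples[1],
                              alpha_normality=alpha_normality,
                              parameter=str(param), group_names=names)
        else:
            res = compare_k(samples, parameter=str(param), group_names=names)
        row = {
            "parameter": res.parameter,
            "test_used": res.test_used,
            "statistic": res.statistic,
            "p_value": res.p_value,
        }
        for name, p_sw, summ in zip(res.groups, res.normality_p,
                                    res.group_summaries):
            row[f"shapiro_p_{name}"] = p_sw
            row[f"n_{name}"] = summ["n"]
            row[f"mean_{name}"] = summ["mean"]
            row[f"sd_{name}"] = summ["sd"]
        rows.append(row)
    return pd.DataFrame(rows)
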