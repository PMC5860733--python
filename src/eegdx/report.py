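"""Group-comparison statistics and box-plot summaries for feature tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "compare_groups", "compare_feature_table", "feature_boxplot_data"]


@dataclass
class GroupComparison:
    feature: str
    median_a: float
    median_b: float
    statistic: float  # Mann-Whitney U for the first sample
    p_value: float
    method: str  # "exact" or "asymptotic"


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, feature: str = ""
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of two feature samples.

    Uses the exact null distribution when both groups have at most 20
    observations and there are no ties, and the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:  # all observations identical: no evidence at all
        return GroupComparison(feature, float(np.median(a)), float(np.median(b)),
                               statistic=a.size * b.size / 2.0, p_value=1.0,
                               method="degenerate")
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        feature=feature,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


def compare_feature_table(
    features: pd.DataFrame, groups: pd.Series, group_a: str, group_b: str
) -> pd.DataFrame:
    """Mann-Whitney comparison of every feature column between two groups."""
    rows = []
    a_idx = groups[groups == group_a].index
    b_idx = groups[groups == group_b].index
    for col in features.columns:
        cmp = compare_groups(features.loc[a_idx, col], features.loc[b_idx, col], feature=col)
        rows.append(
            {"feature": col, f"median_{group_a}": cmp.median_a,
             f"median_{group_b}": cmp.median_b, "U": cmp.statistic,
             "p_value": cmp.p_value, "method": cmp.method}
        )
    return pd.DataFrame(rows).set_index("feature")


def feature_boxplot_data(values: np.ndarray) -> dict:
    """Tukey box-plot summary: median, quartiles, 1.5*IQR whiskers, outliers.

    Plotting is left to the caller; this returns only the numbers a box plot
    needs, so figures can be reproduced from the JSON export.
    """
    x = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(v) for v in x[(x < lo_fence) | (x > hi_fence)]],
        "n": int(x.size),
    }
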