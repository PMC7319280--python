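"""Feature-distribution comparisons: Wilcoxon rank-sum tests with
step-down Holm correction across the tested feature family."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["holm_adjust", "wilcoxon_ranksum", "compare_features", "significance_stars"]


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, output aligned with the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution for small samples without ties and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "asymptotic" if (has_ties or min(a.size, b.size) > 10) else "exact"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_features(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    features: Iterable[str] | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per (feature, peak index) Wilcoxon rank-sum with Holm correction.

    ``group_a``/``group_b`` are tidy feature tables (``cell_id, feature,
    peak_index, value``).  The Holm family is the full set of performed
    tests.  Returns a frame with the test statistic, raw and adjusted p,
    the median shift direction and significance stars.
    """
    for name, g in zip(labels, (group_a, group_b)):
        if g.empty:
            raise ValueError(f"feature table for group {name} is empty")
    if features is not None:
        features = list(features)
        group_a = group_a[group_a["feature"].isin(features)]
        group_b = group_b[group_b["feature"].isin(features)]
    keys = sorted(
        set(map(tuple, group_a[["feature", "peak_index"]].drop_duplicates().values))
        & set(map(tuple, group_b[["feature", "peak_index"]].drop_duplicates().values))
    )
    rows = []
    for feature, idx in keys:
        a = group_a.query("feature == @feature and peak_index == @idx")["value"].to_numpy()
        b = group_b.query("feature == @feature and peak_index == @idx")["value"].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        stat, p = wilcoxon_ranksum(a, b)
        rows.append({
            "feature": feature,
            "peak_index": idx,
            "n_a": a.size,
            "n_b": b.size,
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "statistic": stat,
            "p_raw": p,
        })
    if not rows:
        raise ValueError("no feature/peak combination had >= 2 observations in both groups")
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    table["direction"] = np.sign(table["median_b"] - table["median_a"]).astype(int)
    table["stars"] = table["p_holm"].map(significance_stars)
    return table
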