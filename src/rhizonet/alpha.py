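"""Alpha diversity indices and nonparametric group comparisons.

Indices follow the Mothur conventions: Shannon in natural-log units,
Pielou evenness H/ln(S), Good's coverage 1 - F1/N with F1 the number of
singleton OTUs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .otu import OtuTable

logger = logging.getLogger("rhizonet")


# ---------------------------------------------------------------------------
# per-sample indices
# ---------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over nonzero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon undefined for all-zero counts")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Observed OTU count (number of nonzero entries)."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValueError("richness undefined for empty sample")
    return int((counts > 0).sum())


def evenness(counts) -> float:
    """Pielou evenness H / ln(S); defined as 1.0 for a single taxon."""
    s = richness(counts)
    if s == 1:
        return 1.0
    return shannon(counts) / np.log(s)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N, with F1 the number of singletons."""
    counts = np.asarray(counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("coverage undefined for empty sample")
    singletons = int((counts == 1).sum())
    return 1.0 - singletons / total


def diversity_profile(table: OtuTable) -> pd.DataFrame:
    """Per-sample table of shannon, richness, evenness and coverage."""
    rows = {}
    for sample in table.sample_ids:
        c = table.counts.loc[sample].to_numpy()
        rows[sample] = {
            "shannon": shannon(c),
            "richness": richness(c),
            "evenness": evenness(c),
            "coverage": goods_coverage(c),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    test_name: str
    statistic: float
    p_value: float
    group_labels: list
    group_medians: list


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode='exact'`` enumerates the null distribution (refused under ties);
    ``'normal_approx'`` uses the normal approximation with tie-corrected
    variance and continuity correction; ``'auto'`` picks exact when both
    groups have n <= 10 and the pooled data has no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.warning("constant pooled data in rank-sum test; p = 1")
        return GroupTestResult(
            "wilcoxon_rank_sum", 0.0, 1.0, ["x", "y"],
            [float(np.median(x)), float(np.median(y))],
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "normal_approx"
    if mode == "exact" and has_ties:
        logger.warning("ties present; falling back to normal approximation")
        mode = "normal_approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupTestResult(
        "wilcoxon_rank_sum",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        ["x", "y"],
        [float(np.median(x)), float(np.median(y))],
    )


def kruskal_wallis(groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use wilcoxon_rank_sum for two")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        logger.warning("constant pooled data in Kruskal-Wallis test; p = 1")
        return GroupTestResult(
            "kruskal_wallis", 0.0, 1.0,
            [f"g{i}" for i in range(len(groups))],
            [float(np.median(g)) for g in groups],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.kruskal(*groups)
    return GroupTestResult(
        "kruskal_wallis",
        float(stat),
        float(p),
        [f"g{i}" for i in range(len(groups))],
        [float(np.median(g)) for g in groups],
    )


def compare_groups(values: pd.Series, labels: pd.Series) -> GroupTestResult:
    """Dispatch to Wilcoxon (2 groups) or Kruskal-Wallis (>2 groups)."""
    labels = labels.loc[values.index]
    groups = [values[labels == lab].to_numpy() for lab in sorted(labels.unique())]
    if len(groups) == 2:
        res = wilcoxon_rank_sum(groups[0], groups[1])
    else:
        res = kruskal_wallis(groups)
    res.group_labels = sorted(labels.unique())
    res.group_medians = [float(np.median(g)) for g in groups]
    return res
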