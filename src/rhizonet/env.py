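"""OTU-environment bipartite networks and diversity-environment regression.

The environment table carries per-sample soil chemistry (pH, SWC, TOC, TN,
TP, AP, AK). The bipartite network connects abundant OTUs to factors whose
correlation passes the same |rho| / adjusted-p thresholds used for the
co-occurrence networks; the regression is ordinary least squares of Shannon
diversity on one factor at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .otu import OtuTable

logger = logging.getLogger("rhizonet")

ENV_FACTORS = ("pH", "SWC", "TOC", "TN", "TP", "AP", "AK")


def read_env_table(path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if not np.isfinite(env.to_numpy(dtype=float)).all():
        raise ValueError("environment table contains non-finite values")
    return env


@dataclass
class EnvAssociation:
    """Bipartite OTU-factor edge set with per-node degrees."""

    edges: pd.DataFrame  # otu, factor, rho, p_adj, sign
    factor_degree: pd.Series
    otu_degree: pd.Series

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def top_factor(self) -> str | None:
        if self.factor_degree.empty or self.factor_degree.max() == 0:
            return None
        return str(self.factor_degree.idxmax())


def bipartite_network(
    table: OtuTable,
    env: pd.DataFrame,
    corr_method: str = "spearman",
    min_abs_corr: float = 0.6,
    alpha: float = 0.05,
    p_adjust: str = "bh",
) -> EnvAssociation:
    """Correlate each OTU's relative abundance with each environmental factor.

    Thresholding matches the co-occurrence network contract: keep an edge iff
    |rho| >= ``min_abs_corr`` and adjusted p < ``alpha`` (BH across all
    OTU x factor tests). Constant factor columns are excluded with a warning.
    """
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples")
    env = env.loc[table.sample_ids]
    constant = [c for c in env.columns if env[c].nunique() <= 1]
    if constant:
        logger.warning("excluding constant factors: %s", constant)
        env = env.drop(columns=constant)
    rel = table.relative_abundance()

    rows = []
    for factor in env.columns:
        y = env[factor].to_numpy(dtype=float)
        for otu in rel.columns:
            x = rel[otu].to_numpy()
            if np.ptp(x) == 0:
                continue
            if corr_method == "spearman":
                rho, p = stats.spearmanr(x, y)
            else:
                rho, p = stats.pearsonr(x, y)
            rows.append((otu, factor, float(rho), float(p)))
    raw = pd.DataFrame(rows, columns=["otu", "factor", "rho", "p"])
    if p_adjust == "bh":
        raw["p_adj"] = multipletests(raw["p"], method="fdr_bh")[1]
    elif p_adjust == "bonferroni":
        raw["p_adj"] = np.minimum(raw["p"] * len(raw), 1.0)
    else:
        raw["p_adj"] = raw["p"]
    keep = (raw["rho"].abs() >= min_abs_corr) & (raw["p_adj"] < alpha)
    edges = raw.loc[keep, ["otu", "factor", "rho", "p_adj"]].reset_index(drop=True)
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    factor_degree = (
        edges["factor"].value_counts().reindex(env.columns, fill_value=0)
    )
    otu_degree = edges["otu"].value_counts()
    return EnvAssociation(edges, factor_degree, otu_degree)


@dataclass
class RegressionSummary:
    factor: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def diversity_regression(
    diversity: pd.Series, env: pd.DataFrame, factor: str
) -> RegressionSummary:
    """OLS of a diversity index (typically Shannon) on one factor.

    Two-sided slope p-value from the t distribution on n-2 df; for simple
    regression R^2 equals the squared Pearson correlation of x and y.
    """
    x = env.loc[diversity.index, factor].to_numpy(dtype=float)
    y = diversity.to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 samples for regression")
    if np.ptp(x) == 0:
        raise ValueError(f"zero-variance factor {factor!r}")
    res = stats.linregress(x, y)
    return RegressionSummary(
        factor=factor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n=len(x),
    )
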