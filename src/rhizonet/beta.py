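"""Bray-Curtis dissimilarity, principal coordinates analysis and PERMANOVA.

PCoA is the classical (Gower) eigendecomposition of -1/2 J D^2 J; negative
eigenvalues are reported but excluded from the coordinates, and axis
percentages are fractions of the positive-eigenvalue sum. PERMANOVA is the
single-factor distance-based pseudo-F with a label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .otu import OtuTable


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with a zero diagonal."""

    data: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(u, v) = sum|u-v| / sum(u+v) on counts."""
    counts = table.counts.to_numpy(dtype=float)
    zero = table.counts.sum(axis=1) == 0
    if zero.any():
        raise ValueError(f"all-zero sample: {list(table.counts.index[zero])}")
    d = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(d, table.sample_ids)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per positive axis, of positive sum


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical metric MDS of a distance matrix."""
    n = d.n
    sq = d.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ sq @ j
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    prop = eigvals[pos] / eigvals[pos].sum()
    return PcoaResult(
        pd.DataFrame(coords, index=d.sample_ids, columns=axes), eigvals, prop
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    grouping_name: str


def _sum_squares(sq: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = sq.shape[0]
    ss_total = sq[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    grouping_name: str = "group",
) -> PermanovaResult:
    """Single-factor PERMANOVA (Adonis) with label permutation.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations);
    R^2 = SS_between / SS_total.
    """
    labels = pd.Categorical(np.asarray(grouping)).codes
    if len(labels) != d.n:
        raise ValueError("grouping length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs n >= 2")
    n, k = d.n, len(uniq)
    sq = d.data ** 2

    def pseudo_f(lab):
        ss_total, ss_within = _sum_squares(sq, lab)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf, ss_between / ss_total if ss_total > 0 else 0.0
        return (
            (ss_between / (k - 1)) / (ss_within / (n - k)),
            ss_between / ss_total,
        )

    f_obs, r2 = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        f_perm, _ = pseudo_f(rng.permutation(labels))
        if f_perm >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, grouping_name)
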