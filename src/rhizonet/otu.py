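"""OTU table data model, TSV I/O, rarefaction, abundance filtering and core-OTU sets.

The central container is :class:`OtuTable`: an integer count matrix
(samples x OTUs) with per-sample metadata (compartment, species, replicate)
and a per-OTU seven-rank taxonomy table parsed from QIIME-style lineage
strings (``k__Fungi;p__Ascomycota;...``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rhizonet")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(zip(RANKS, ("k", "p", "c", "o", "f", "g", "s")))
METADATA_COLUMNS = ("compartment", "species", "replicate")


# ---------------------------------------------------------------------------
# taxonomy lineages
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-joined lineage string into the seven canonical ranks.

    Unresolved ranks are filled with ``unclassified_<prefix>__<parent>`` where
    ``<parent>`` is the deepest resolved label above them, so that e.g. an OTU
    resolved only to family Melanommataceae gets genus and species
    ``unclassified_f__Melanommataceae``.
    """
    resolved: dict[str, str] = {}
    for token in str(lineage).split(";"):
        token = token.strip()
        if not token:
            continue
        for rank, prefix in RANK_PREFIXES.items():
            if token.startswith(prefix + "__"):
                name = token[len(prefix) + 2 :].strip()
                if name and not name.lower().startswith("unclassified"):
                    resolved[rank] = name
                break
    out: dict[str, str] = {}
    parent_prefix, parent_name = "k", "Fungi"
    for rank in RANKS:
        prefix = RANK_PREFIXES[rank]
        if rank in resolved:
            out[rank] = resolved[rank]
            parent_prefix, parent_name = prefix, resolved[rank]
        else:
            out[rank] = f"unclassified_{parent_prefix}__{parent_name}"
    return out


def format_lineage(ranks: dict[str, str]) -> str:
    """Inverse of :func:`parse_lineage` for resolved ranks (round-trips)."""
    parts = []
    for rank in RANKS:
        label = ranks[rank]
        if label.startswith("unclassified_"):
            break
        parts.append(f"{RANK_PREFIXES[rank]}__{label}")
    return ";".join(parts)


def all_unclassified_lineage() -> dict[str, str]:
    # kingdom is taken as known (ITS surveys target Fungi); everything below
    # is unresolved
    out = {rank: "unclassified_k__Fungi" for rank in RANKS}
    out["kingdom"] = "Fungi"
    return out


# ---------------------------------------------------------------------------
# OtuTable
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Integer OTU count matrix with sample metadata and OTU taxonomy.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = sample ids,
        columns = OTU ids.
    metadata
        DataFrame indexed by sample id with columns
        ``compartment`` (e.g. G/T), ``species`` (e.g. PZ/CZ/OZ/ZJ)
        and ``replicate``.
    taxonomy
        DataFrame indexed by OTU id with one column per rank in
        :data:`RANKS`.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate OTU id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts contain non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(
                f"non-integer count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {list(missing)}")
        self.metadata = self.metadata.loc[self.counts.index]
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                [all_unclassified_lineage()] * self.n_otus, index=self.counts.columns
            )
        else:
            absent = self.counts.columns.difference(self.taxonomy.index)
            if len(absent):
                logger.warning(
                    "%d OTUs missing taxonomy, assigned all-unclassified", len(absent)
                )
                filler = pd.DataFrame(
                    [all_unclassified_lineage()] * len(absent), index=absent
                )
                self.taxonomy = pd.concat([self.taxonomy, filler])
            self.taxonomy = self.taxonomy.loc[self.counts.columns, list(RANKS)]
        # canonical axis names so write/read round-trips compare equal
        self.counts.index.name = "sample_id"
        self.counts.columns.name = None
        self.metadata.index.name = "sample_id"
        self.taxonomy.index.name = "otu"

    # -- basic views -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValueError(f"sample {bad!r} has zero total count")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        return OtuTable(
            self.counts.loc[sample_ids].copy(),
            self.metadata.loc[sample_ids].copy(),
            self.taxonomy.copy(),
        )

    def subset_otus(self, otu_ids) -> "OtuTable":
        otu_ids = list(otu_ids)
        return OtuTable(
            self.counts[otu_ids].copy(),
            self.metadata.copy(),
            self.taxonomy.loc[otu_ids].copy(),
        )


# ---------------------------------------------------------------------------
# I/O (tab-delimited, "#" comment lines skipped, "#OTU_ID" header kept)
# ---------------------------------------------------------------------------

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [
            ln
            for ln in fh
            if not (ln.startswith("#") and not ln.startswith("#OTU_ID"))
        ]
    from io import StringIO

    return pd.read_csv(StringIO("".join(lines)), sep="\t", **kwargs)


def read_otu_table(table_path, taxonomy_path=None, metadata_path=None) -> OtuTable:
    """Load an OtuTable from TSV files.

    ``otu_table.tsv`` has OTUs as rows (first column ``#OTU_ID``) and samples
    as columns; it is transposed into the samples x OTUs orientation.
    Taxonomy rows for unknown OTUs are ignored with a warning; OTUs without a
    taxonomy row get an all-unclassified lineage.
    """
    raw = _read_tsv(table_path, index_col=0)
    counts = raw.T  # rows -> samples
    counts.index.name = "sample_id"

    if metadata_path is not None:
        metadata = _read_tsv(metadata_path, index_col=0)
    else:
        metadata = pd.DataFrame(
            {c: ["NA"] * counts.shape[0] for c in METADATA_COLUMNS},
            index=counts.index,
        )

    taxonomy = None
    if taxonomy_path is not None:
        tax_raw = _read_tsv(taxonomy_path, index_col=0, header=None, names=["otu", "lineage"])
        unknown = tax_raw.index.difference(counts.columns)
        if len(unknown):
            logger.warning("ignoring taxonomy for %d unknown OTUs", len(unknown))
            tax_raw = tax_raw.drop(index=unknown)
        taxonomy = pd.DataFrame(
            [parse_lineage(s) for s in tax_raw["lineage"]], index=tax_raw.index
        )
    return OtuTable(counts, metadata, taxonomy)


def write_otu_table(table: OtuTable, directory, prefix="") -> dict[str, str]:
    """Write otu_table.tsv / taxonomy.tsv / metadata.tsv; returns the paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {}
    otu_path = os.path.join(directory, prefix + "otu_table.tsv")
    out = table.counts.T.rename_axis("#OTU_ID")
    out.to_csv(otu_path, sep="\t")
    paths["otu_table"] = otu_path

    tax_path = os.path.join(directory, prefix + "taxonomy.tsv")
    with open(tax_path, "wt", encoding="utf-8") as fh:
        for otu in table.otu_ids:
            ranks = table.taxonomy.loc[otu].to_dict()
            fh.write(f"{otu}\t{format_lineage(ranks) or 'k__Fungi'}\n")
    paths["taxonomy"] = tax_path

    meta_path = os.path.join(directory, prefix + "metadata.tsv")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")
    paths["metadata"] = meta_path
    return paths


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth="min", seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    ``depth="min"`` resolves to the minimum sample total (the usual
    homogenisation to the shallowest library). Sampling is multivariate
    hypergeometric, so the per-OTU marginal expectation is
    ``depth / total * count``. OTUs that drop to zero everywhere are kept as
    zero columns so OTU ids stay aligned across subsets.
    """
    totals = table.sample_sums()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    short = totals.index[totals < depth]
    if len(short):
        raise ValueError(
            f"samples shallower than depth {depth}: {list(short)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, sample in enumerate(table.sample_ids):
        row = table.counts.loc[sample].to_numpy()
        out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(counts, table.metadata.copy(), table.taxonomy.copy())


# ---------------------------------------------------------------------------
# rank aggregation and abundance filtering
# ---------------------------------------------------------------------------

def aggregate_rank(table: OtuTable, rank: str, relative: bool = False) -> pd.DataFrame:
    """Sum OTU columns by taxonomy label at ``rank``.

    Returns a samples x taxa DataFrame; with ``relative=True`` each row is
    normalised to sum to 1.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = table.taxonomy[rank]
    agg = table.counts.T.groupby(labels).sum().T
    if relative:
        agg = agg.div(agg.sum(axis=1), axis=0)
    return agg


def filter_abundant(table: OtuTable, proportion_threshold: float = 5e-5) -> OtuTable:
    """Keep OTUs whose total reads are strictly above ``proportion_threshold``
    of the grand total (default 0.005%), preserving column order."""
    grand = table.counts.to_numpy().sum()
    if grand == 0:
        raise ValueError("empty table")
    totals = table.counts.sum(axis=0)
    keep = totals[totals / grand > proportion_threshold].index
    return table.subset_otus(keep)


# ---------------------------------------------------------------------------
# core OTU sets (Venn-style)
# ---------------------------------------------------------------------------

@dataclass
class CoreOtuSets:
    """Per-group OTU presence sets plus their intersections.

    Presence in a group means a nonzero count in at least one sample of the
    group. ``core`` is the intersection across all groups; ``exclusive`` maps
    each group to OTUs found in no other group.
    """

    per_group: dict[str, set]
    core: set
    pairwise: dict[tuple[str, str], set]
    exclusive: dict[str, set]

    @property
    def union(self) -> set:
        out: set = set()
        for s in self.per_group.values():
            out |= s
        return out


def core_otu_sets(table: OtuTable, grouping: str = "species") -> CoreOtuSets:
    """Compute presence sets per metadata group and all their intersections."""
    groups = table.metadata[grouping]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for core-OTU analysis")
    per_group = {}
    for label in labels:
        samples = groups.index[groups == label]
        present = table.counts.loc[samples].sum(axis=0) > 0
        per_group[label] = set(present.index[present])
    core = set.intersection(*per_group.values())
    pairwise = {
        (a, b): per_group[a] & per_group[b]
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    exclusive = {
        a: per_group[a].difference(*(per_group[b] for b in labels if b != a))
        for a in labels
    }
    return CoreOtuSets(per_group, core, pairwise, exclusive)
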