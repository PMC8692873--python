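"""FUNGuild-style trophic-mode and guild annotation.

A user-supplied reference table maps taxon names (at a stated taxonomic
level) to a trophic mode (pathotroph / symbiotroph / saprotroph, possibly
compound like "Pathotroph-Saprotroph"), a guild string (possibly
"|"-delimited for multi-guild records) and a confidence ranking. Each OTU is
matched at the most specific rank with a record; OTUs whose matched record
lists two or more guilds are excluded from guild abundances (single-guild
rule), and OTUs without any match are tracked as unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .alpha import GroupTestResult, compare_groups
from .otu import RANKS, OtuTable

logger = logging.getLogger("rhizonet")

TROPHIC_MODES = ("pathotroph", "symbiotroph", "saprotroph")
CONFIDENCE_LEVELS = ("possible", "probable", "highly probable")

# match from most to least specific rank
_MATCH_ORDER = tuple(reversed(RANKS))


@dataclass
class GuildReference:
    """Reference records: taxon, taxonomic level, trophic_mode, guild, confidence."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"taxon", "level", "trophic_mode", "guild", "confidence"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"guild reference missing columns: {sorted(missing)}")
        if self.records.empty:
            raise ValueError("empty guild reference")
        for mode in self.records["trophic_mode"]:
            for token in str(mode).split("-"):
                if token.lower() not in TROPHIC_MODES:
                    raise ValueError(f"unknown trophic mode token {token!r} in {mode!r}")
        # case-insensitive lookup keyed by (level, name)
        self._lookup = {
            (str(r.level).lower(), str(r.taxon).lower()): r
            for r in self.records.itertuples()
        }

    def match(self, lineage: pd.Series):
        """Return (record, matched_rank) at the most specific rank, or None."""
        for rank in _MATCH_ORDER:
            name = str(lineage[rank])
            if name.startswith("unclassified_"):
                continue
            rec = self._lookup.get((rank, name.lower()))
            if rec is not None:
                return rec, rank
        return None


def read_guild_reference(path) -> GuildReference:
    return GuildReference(pd.read_csv(path, sep="\t", comment="#"))


def write_guild_reference(ref: GuildReference, path) -> None:
    ref.records.to_csv(path, sep="\t", index=False)


@dataclass
class GuildProfile:
    """Per-OTU assignments plus per-sample guild / trophic-mode abundances.

    ``assignments`` has one row per OTU with columns status
    (included / excluded_multiguild / unassigned), trophic_mode, guild,
    confidence and matched_rank. ``guild_abundance`` and ``mode_abundance``
    are samples x label relative-abundance tables over included OTUs;
    ``unassigned_fraction`` tracks the per-sample mass that was not included.
    """

    assignments: pd.DataFrame
    guild_abundance: pd.DataFrame
    mode_abundance: pd.DataFrame
    unassigned_fraction: pd.Series


def assign_guilds(
    table: OtuTable, ref: GuildReference, min_confidence: str | None = None
) -> GuildProfile:
    """Annotate every OTU and aggregate included OTUs per sample.

    ``min_confidence`` optionally drops matches below a confidence rank
    (e.g. "probable"); the default applies no confidence filter.
    """
    conf_rank = {c: i for i, c in enumerate(CONFIDENCE_LEVELS)}
    min_rank = conf_rank[min_confidence.lower()] if min_confidence else -1

    rows = []
    for otu in table.otu_ids:
        hit = ref.match(table.taxonomy.loc[otu])
        if hit is None:
            rows.append((otu, "unassigned", "", "", "", ""))
            continue
        rec, rank = hit
        if conf_rank.get(str(rec.confidence).lower(), 0) < min_rank:
            rows.append((otu, "unassigned", "", "", "", ""))
            continue
        guilds = [g.strip() for g in str(rec.guild).split("|") if g.strip()]
        status = "included" if len(guilds) == 1 else "excluded_multiguild"
        rows.append(
            (otu, status, str(rec.trophic_mode), str(rec.guild),
             str(rec.confidence), rank)
        )
    assignments = pd.DataFrame(
        rows,
        columns=["otu", "status", "trophic_mode", "guild", "confidence", "matched_rank"],
    ).set_index("otu")

    rel = table.relative_abundance()
    included = assignments.index[assignments["status"] == "included"]
    guild_abundance = rel[included].T.groupby(assignments.loc[included, "guild"]).sum().T
    mode_abundance = (
        rel[included].T.groupby(assignments.loc[included, "trophic_mode"]).sum().T
    )
    unassigned = 1.0 - rel[included].sum(axis=1)
    return GuildProfile(assignments, guild_abundance, mode_abundance, unassigned)


def compare_guilds(
    profile: GuildProfile, grouping: pd.Series, on: str = "mode"
) -> dict[str, GroupTestResult]:
    """Per-guild (or per-trophic-mode) group comparison.

    Uses the Wilcoxon rank-sum test for two groups and Kruskal-Wallis for
    more, via the alpha-diversity module. Labels absent from every sample
    are skipped with a log entry.
    """
    tableau = profile.mode_abundance if on == "mode" else profile.guild_abundance
    results: dict[str, GroupTestResult] = {}
    for label in tableau.columns:
        values = tableau[label]
        if (values == 0).all():
            logger.info("guild %r absent from all samples; skipped", label)
            continue
        results[label] = compare_groups(values, grouping)
    return results
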