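"""End-to-end orchestration: rarefaction through networks to environment fits.

``run_pipeline`` executes the full downstream analysis in the order the
stages depend on each other: rarefy, alpha diversity + group tests,
rank-level profiles + per-taxon tests, PCoA + PERMANOVA, guild annotation +
tests, abundance filtering, per-compartment co-occurrence networks with
modules, Zi-Pi roles and shared keystones, bipartite OTU-environment
networks and Shannon ~ factor regressions. All stage outputs are written as
TSV/GraphML plus a JSON summary; runs are deterministic given the seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import alpha, beta, env as env_mod, guilds, network, otu

logger = logging.getLogger("rhizonet")


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the defaults the pipeline documents.

    Paths may be left None when the corresponding stage is skipped (e.g. no
    guild reference). ``rarefy_networks`` controls whether networks are
    built from the rarefied table (default) or the raw counts.
    """

    otu_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    env_table: str | None = None
    guild_reference: str | None = None
    output_dir: str = "rhizonet_out"

    rarefaction_depth: int | str = "min"
    rarefaction_seed: int = 0
    rarefy_networks: bool = True
    abundance_threshold: float = 5e-5

    corr_method: str = "spearman"
    min_abs_corr: float = 0.6
    corr_alpha: float = 0.05
    p_adjust: str = "bh"
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62

    n_permutations: int = 999
    permutation_seed: int = 0
    compartment_column: str = "compartment"
    species_column: str = "species"
    top_taxa: int = 15

    def validate(self) -> None:
        if self.abundance_threshold < 0:
            raise ValueError("abundance_threshold must be >= 0")
        if self.zi_threshold <= 0 or not (0 < self.pi_threshold < 1):
            raise ValueError("role thresholds out of range")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def per_taxon_tests(
    table: otu.OtuTable, rank: str, grouping: pd.Series, top_n: int = 15
) -> pd.DataFrame:
    """Group tests on the ``top_n`` most abundant taxa at one rank.

    Taxa are ranked by mean relative abundance across all samples; raw
    Wilcoxon/Kruskal p-values are BH-adjusted across the tested taxa and
    both are reported.
    """
    rel = otu.aggregate_rank(table, rank, relative=True)
    order = rel.mean(axis=0).sort_values(ascending=False)
    taxa = list(order.index[:top_n])
    rows = []
    for taxon in taxa:
        res = alpha.compare_groups(rel[taxon], grouping)
        rows.append((taxon, res.test_name, res.statistic, res.p_value))
    out = pd.DataFrame(rows, columns=["taxon", "test", "statistic", "p"])
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    out["mean_relative_abundance"] = [order[t] for t in taxa]
    return out


def run_pipeline(
    config: PipelineConfig,
    table: otu.OtuTable | None = None,
    env_table: pd.DataFrame | None = None,
    guild_reference: guilds.GuildReference | None = None,
) -> dict:
    """Run every stage and write the report bundle; returns the summary dict.

    Inputs may be passed in-memory (as from the synthetic generator) or read
    from the paths in ``config``. Any stage failure aborts with the stage
    name and cause.
    """
    config.validate()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    summary: dict = {"stages": []}

    def stage(name):
        logger.info("stage %s", name)
        summary["stages"].append(name)

    try:
        # ---- load ------------------------------------------------------
        stage("load")
        if table is None:
            if config.otu_table is None:
                raise ValueError("no OTU table given (path or in-memory)")
            table = otu.read_otu_table(
                config.otu_table, config.taxonomy, config.metadata
            )
        if env_table is None and config.env_table:
            env_table = env_mod.read_env_table(config.env_table)
        if guild_reference is None and config.guild_reference:
            guild_reference = guilds.read_guild_reference(config.guild_reference)
        summary["n_samples"] = table.n_samples
        summary["n_otus"] = table.n_otus
        compartments = sorted(table.metadata[config.compartment_column].unique())

        # ---- rarefaction ----------------------------------------------
        stage("rarefy")
        rarefied = otu.rarefy(
            table, config.rarefaction_depth, config.rarefaction_seed
        )
        summary["rarefaction_depth"] = int(rarefied.sample_sums().iloc[0])

        # ---- alpha diversity ------------------------------------------
        stage("alpha_diversity")
        profile = alpha.diversity_profile(rarefied)
        profile.to_csv(os.path.join(outdir, "diversity.tsv"), sep="\t")
        div_tests = {}
        for index in profile.columns:
            res = alpha.compare_groups(
                profile[index], rarefied.metadata[config.compartment_column]
            )
            div_tests[index] = {
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p_value,
                "medians": dict(zip(res.group_labels, res.group_medians)),
            }
        summary["diversity_tests"] = div_tests

        # ---- taxonomy profiles + per-taxon tests ----------------------
        stage("rank_profiles")
        taxon_tests = []
        for rank in ("phylum", "class"):
            rel = otu.aggregate_rank(rarefied, rank, relative=True)
            rel.to_csv(os.path.join(outdir, f"{rank}_relative_abundance.tsv"), sep="\t")
            tt = per_taxon_tests(
                rarefied, rank, rarefied.metadata[config.compartment_column],
                config.top_taxa,
            )
            tt.insert(0, "rank", rank)
            taxon_tests.append(tt)
        pd.concat(taxon_tests).to_csv(
            os.path.join(outdir, "tests.tsv"), sep="\t", index=False
        )

        # ---- core OTU sets --------------------------------------------
        stage("core_otus")
        core = otu.core_otu_sets(rarefied, config.species_column)
        summary["core_otus"] = {
            "global_intersection": len(core.core),
            "per_group": {g: len(s) for g, s in sorted(core.per_group.items())},
        }

        # ---- ordination + PERMANOVA -----------------------------------
        stage("ordination")
        dm = beta.bray_curtis(rarefied)
        dm.to_frame().to_csv(os.path.join(outdir, "bray_curtis.tsv"), sep="\t")
        ord_res = beta.pcoa(dm)
        ord_res.coordinates.to_csv(os.path.join(outdir, "pcoa.tsv"), sep="\t")
        summary["pcoa_percent_explained"] = [
            round(100 * float(p), 4) for p in ord_res.proportion_explained[:2]
        ]
        permanova_rows = {}
        for name, column in (
            ("compartment", config.compartment_column),
            ("species", config.species_column),
        ):
            res = beta.permanova(
                dm, rarefied.metadata[column], config.n_permutations,
                config.permutation_seed, grouping_name=name,
            )
            permanova_rows[name] = {
                "pseudo_F": res.pseudo_f, "R2": res.r2, "p": res.p_value,
            }
        pd.DataFrame(permanova_rows).T.to_csv(
            os.path.join(outdir, "permanova.tsv"), sep="\t"
        )
        summary["permanova"] = permanova_rows

        # ---- guilds ----------------------------------------------------
        if guild_reference is not None:
            stage("guilds")
            gp = guilds.assign_guilds(rarefied, guild_reference)
            gp.mode_abundance.to_csv(
                os.path.join(outdir, "guild_profile.tsv"), sep="\t"
            )
            gtests = guilds.compare_guilds(
                gp, rarefied.metadata[config.compartment_column], on="mode"
            )
            summary["guild_tests"] = {
                label: {"p": r.p_value, "statistic": r.statistic}
                for label, r in sorted(gtests.items())
            }
            status = gp.assignments["status"].value_counts()
            summary["guild_assignment"] = {k: int(v) for k, v in status.items()}

        # ---- co-occurrence networks per compartment --------------------
        stage("networks")
        net_source = rarefied if config.rarefy_networks else table
        summary["networks"] = {}
        role_tables = {}
        for comp in compartments:
            sub = net_source.subset_samples(
                net_source.metadata.index[
                    net_source.metadata[config.compartment_column] == comp
                ]
            )
            abundant = otu.filter_abundant(sub, config.abundance_threshold)
            graph = network.build_network(
                abundant, config.corr_method, config.min_abs_corr,
                config.corr_alpha, config.p_adjust,
            )
            if graph.number_of_nodes() == 0:
                logger.warning("compartment %s produced an empty network", comp)
                continue
            partition = network.greedy_modularity(graph)
            topo = network.topology(graph, partition)
            roles = network.zi_pi(graph, partition)
            roles["role"] = network.classify_roles(
                roles["zi"].to_numpy(), roles["pi"].to_numpy(),
                config.zi_threshold, config.pi_threshold,
            )
            role_tables[comp] = roles
            network.write_edge_list(graph, os.path.join(outdir, f"edges_{comp}.tsv"))
            network.write_graphml(graph, os.path.join(outdir, f"network_{comp}.graphml"))
            network.write_node_table(
                roles, graph, os.path.join(outdir, f"nodes_{comp}.tsv")
            )
            role_counts = roles["role"].value_counts()
            summary["networks"][comp] = {
                **topo.to_dict(),
                "n_modules": partition.n_modules,
                "roles": {k: int(v) for k, v in sorted(role_counts.items())},
            }
        if len(role_tables) >= 2:
            shared = network.shared_keystones(role_tables)
            summary["shared_keystones"] = {
                role: sorted(members) for role, members in shared.items()
            }

        # ---- environment associations ---------------------------------
        if env_table is not None:
            stage("environment")
            summary["env"] = {}
            profile_full = alpha.diversity_profile(rarefied)
            reg_rows = []
            for comp in compartments:
                samples = rarefied.metadata.index[
                    rarefied.metadata[config.compartment_column] == comp
                ]
                sub = rarefied.subset_samples(samples)
                abundant = otu.filter_abundant(sub, config.abundance_threshold)
                assoc = env_mod.bipartite_network(
                    abundant, env_table.loc[samples], config.corr_method,
                    config.min_abs_corr, config.corr_alpha, config.p_adjust,
                )
                assoc.edges.to_csv(
                    os.path.join(outdir, f"env_edges_{comp}.tsv"),
                    sep="\t", index=False,
                )
                summary["env"][comp] = {
                    "n_edges": assoc.n_edges,
                    "factor_degree": {
                        k: int(v) for k, v in assoc.factor_degree.items()
                    },
                    "top_factor": assoc.top_factor(),
                }
                for factor in env_table.columns:
                    if env_table.loc[samples, factor].nunique() <= 1:
                        continue
                    reg = env_mod.diversity_regression(
                        profile_full.loc[samples, "shannon"],
                        env_table, factor,
                    )
                    reg_rows.append(
                        (comp, factor, reg.slope, reg.intercept, reg.r2, reg.p_value)
                    )
            regressions = pd.DataFrame(
                reg_rows,
                columns=["compartment", "factor", "slope", "intercept", "r2", "p"],
            )
            regressions.to_csv(
                os.path.join(outdir, "regressions.tsv"), sep="\t", index=False
            )
            summary["shannon_regressions"] = {
                f"{row.compartment}:{row.factor}": {
                    "slope": row.slope, "r2": row.r2, "p": row.p
                }
                for row in regressions.itertuples()
            }
    except Exception as exc:
        current = summary["stages"][-1] if summary["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary = _round_floats(summary)
    with open(os.path.join(outdir, "summary.json"), "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
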