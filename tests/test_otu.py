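import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from rhizonet.otu import (
    OtuTable,
    aggregate_rank,
    core_otu_sets,
    filter_abundant,
    format_lineage,
    parse_lineage,
    rarefy,
    read_otu_table,
    write_otu_table,
)

from conftest import make_table


class TestLineages:
    def test_parses_named_ranks(self):
        ranks = parse_lineage(
            "k__Fungi;p__Ascomycota;c__Pezizomycetes;o__Pezizales;"
            "f__Tuberaceae;g__Tuber"
        )
        assert ranks["phylum"] == "Ascomycota"
        assert ranks["class"] == "Pezizomycetes"
        assert ranks["genus"] == "Tuber"
        assert ranks["species"] == "unclassified_g__Tuber"

    def test_unresolved_ranks_carry_parent(self):
        ranks = parse_lineage(
            "k__Fungi;p__Ascomycota;c__Dothideomycetes;o__Pleosporales;"
            "f__Melanommataceae"
        )
        assert ranks["genus"] == "unclassified_f__Melanommataceae"

    def test_round_trip(self):
        lineage = "k__Fungi;p__Basidiomycota;c__Agaricomycetes;o__Russulales;f__Russulaceae;g__Russula"
        assert format_lineage(parse_lineage(lineage)) == lineage

    def test_empty_lineage_all_unclassified(self):
        ranks = parse_lineage("")
        assert all(v == "unclassified_k__Fungi" for v in ranks.values())


class TestValidation:
    def test_negative_count_names_cell(self):
        with pytest.raises(ValueError, match="OTU2"):
            make_table([[3, -1], [2, 2]])

    def test_duplicate_sample_id(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["A", "A"], columns=["o1", "o2"])
        meta = pd.DataFrame(
            {"compartment": ["G", "G"], "species": ["PZ", "PZ"], "replicate": [1, 2]},
            index=["A", "A"],
        )
        with pytest.raises(ValueError, match="duplicate sample"):
            OtuTable(counts, meta)

    def test_metadata_must_cover_samples(self):
        counts = pd.DataFrame([[1], [2]], index=["A", "B"], columns=["o1"])
        meta = pd.DataFrame(
            {"compartment": ["G"], "species": ["PZ"], "replicate": [1]}, index=["A"]
        )
        with pytest.raises(ValueError, match="missing from metadata"):
            OtuTable(counts, meta)


class TestIO:
    def test_round_trip(self, tmp_path, dataset):
        paths = write_otu_table(dataset.table, tmp_path)
        loaded = read_otu_table(
            paths["otu_table"], paths["taxonomy"], paths["metadata"]
        )
        assert loaded.n_samples == 24
        pd.testing.assert_frame_equal(loaded.counts, dataset.table.counts)
        pd.testing.assert_frame_equal(
            loaded.metadata.astype(str), dataset.table.metadata.astype(str)
        )
        pd.testing.assert_frame_equal(loaded.taxonomy, dataset.table.taxonomy)


class TestRarefy:
    def test_min_depth_equalises_row_sums(self, dataset):
        rarefied = rarefy(dataset.table, "min", seed=1)
        sums = rarefied.sample_sums()
        assert (sums == dataset.table.sample_sums().min()).all()

    def test_single_otu_forced(self):
        table = make_table([[50]])
        assert rarefy(table, 20, seed=0).counts.iloc[0, 0] == 20

    def test_depth_exceeding_total_errors(self):
        with pytest.raises(ValueError, match="S1"):
            rarefy(make_table([[5, 5]]), 11, seed=0)

    def test_hypergeometric_moments(self):
        # subsampling [30, 10] to depth 20: OTU1 count ~ Hypergeom(40, 30, 20)
        table = make_table([[30, 10]])
        draws = np.array(
            [rarefy(table, 20, seed=s).counts.iloc[0, 0] for s in range(1000)]
        )
        dist = hypergeom(40, 30, 20)
        se = dist.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - dist.mean()) < 3 * se
        assert abs(draws.var() - dist.var()) < 0.3 * dist.var()

    def test_zero_columns_retained(self):
        table = make_table([[100, 1], [100, 1]])
        rarefied = rarefy(table, 10, seed=4)
        assert list(rarefied.counts.columns) == ["OTU1", "OTU2"]


class TestAggregateAndFilter:
    def test_sums_by_rank_label(self):
        tax = pd.DataFrame(
            [parse_lineage("k__Fungi;p__Ascomycota"),
             parse_lineage("k__Fungi;p__Ascomycota")],
            index=["OTU1", "OTU2"],
        )
        table = make_table([[3, 7]], taxonomy=tax)
        agg = aggregate_rank(table, "phylum")
        assert agg.loc["S1", "Ascomycota"] == 10

    def test_all_unclassified_fallback_column(self):
        table = make_table([[3, 7]])
        agg = aggregate_rank(table, "phylum")
        assert list(agg.columns) == ["unclassified_k__Fungi"]

    def test_relative_rows_sum_to_one(self, dataset):
        rel = aggregate_rank(dataset.table, "class", relative=True)
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_rank(self, dataset):
        with pytest.raises(ValueError, match="unknown rank"):
            aggregate_rank(dataset.table, "domain")

    def test_boundary_is_strict(self):
        # grand total 100000; 5 reads is exactly 0.005% -> removed
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [99989, 5, 6]
        filtered = filter_abundant(make_table(counts), 5e-5)
        assert list(filtered.counts.columns) == ["OTU1", "OTU3"]

    def test_zero_threshold_drops_only_empty_otus(self):
        filtered = filter_abundant(make_table([[5, 0], [3, 0]]), 0.0)
        assert list(filtered.counts.columns) == ["OTU1"]

    def test_idempotent(self, compartment_tables):
        once = filter_abundant(compartment_tables["G"])
        twice = filter_abundant(once)
        assert list(once.counts.columns) == list(twice.counts.columns)


class TestCoreOtus:
    def test_disjoint_groups_empty_core(self):
        table = make_table(
            [[5, 0], [0, 5]], species=["PZ", "CZ"]
        )
        sets = core_otu_sets(table, "species")
        assert sets.core == set()
        assert sets.exclusive["PZ"] == {"OTU1"}

    def test_identical_groups(self):
        table = make_table([[1, 2], [1, 2]], species=["PZ", "CZ"])
        sets = core_otu_sets(table, "species")
        assert sets.core == sets.union

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 2, size=(9, 12))
        labels = ["PZ"] * 3 + ["CZ"] * 3 + ["OZ"] * 3
        table = make_table(counts, species=labels)
        sets = core_otu_sets(table, "species")
        # independent set algebra straight from the count matrix
        member = {
            sp: {
                f"OTU{j+1}"
                for j in range(12)
                if sum(counts[i, j] for i in range(9) if labels[i] == sp) > 0
            }
            for sp in ("PZ", "CZ", "OZ")
        }
        assert sets.core == member["PZ"] & member["CZ"] & member["OZ"]
        for (a, b), inter in sets.pairwise.items():
            assert inter == member[a] & member[b]

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            core_otu_sets(make_table([[1], [1]]), "species")
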