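import dataclasses
import json
import time

import numpy as np
import pytest
from scipy import stats

from rhizonet import alpha
from rhizonet.otu import read_otu_table
from rhizonet.synthetic import (
    GroundTruth,
    SyntheticConfig,
    adjusted_rand_index,
    generate_dataset,
    read_truth,
    write_fixture,
)


class TestConfig:
    def test_defaults_describe_study_design(self):
        cfg = SyntheticConfig()
        assert cfg.n_samples_per_compartment == 12
        assert cfg.star_module_size == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(depth_per_sample=0),
            dict(module_within_corr=0.2, module_between_corr=0.5),
            dict(n_planted_hubs=4),  # hubs exceed the available modules
            dict(n_planted_modules=3),  # too few cliques for connectors
            dict(n_species_groups=1, n_replicates=1),  # star cannot fit
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dataclasses.replace(SyntheticConfig(), **kwargs).validate()


class TestDeterminism:
    def test_same_seed_identical_tables(self, dataset):
        again = generate_dataset(SyntheticConfig())
        assert dataset.table.counts.equals(again.table.counts)
        assert dataset.env.equals(again.env)
        assert dataset.truth.module_assignment == again.truth.module_assignment

    def test_different_seeds_differ(self, dataset):
        other = generate_dataset(dataclasses.replace(SyntheticConfig(), seed=99))
        assert not dataset.table.counts.equals(other.table.counts)


class TestPlantedEffects:
    def test_design_shape(self, dataset):
        table = dataset.table
        assert table.n_samples == 24
        assert set(table.metadata["compartment"]) == {"G", "T"}
        assert table.metadata.groupby(["compartment", "species"]).size().eq(3).all()
        assert (table.sample_sums() == 30000).all()

    def test_null_configuration_balances_compartments(self):
        cfg = dataclasses.replace(
            SyntheticConfig(), diversity_effect=1.0, toc_slope=0.0, seed=17
        )
        profile = alpha.diversity_profile(generate_dataset(cfg).table)
        means = profile.groupby(
            generate_dataset(cfg).table.metadata["compartment"]
        )["shannon"].mean()
        assert abs(means["G"] - means["T"]) < 0.25

    def test_diversity_effect_detected_across_seeds(self):
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = dataclasses.replace(SyntheticConfig(), seed=1000 + seed)
            ds = generate_dataset(cfg)
            profile = alpha.diversity_profile(ds.table)
            res = alpha.compare_groups(
                profile["shannon"], ds.table.metadata["compartment"]
            )
            rejections += res.p_value < 0.05
        assert rejections >= 0.95 * n_seeds

    def test_planted_pair_correlations_hold_in_data(self, dataset):
        for comp in ("G", "T"):
            sub = dataset.table.subset_samples(
                dataset.table.metadata.index[
                    dataset.table.metadata["compartment"] == comp
                ]
            )
            rel = sub.relative_abundance()
            rhos = [
                abs(stats.spearmanr(rel[a], rel[b]).statistic)
                for a, b, _ in dataset.truth.planted_pairs[comp]
            ]
            assert np.median(rhos) >= SyntheticConfig().module_within_corr - 0.1

    def test_truth_invariants(self, dataset):
        truth = dataset.truth
        for comp in ("G", "T"):
            hubs = set(truth.hub_otus[comp])
            assert hubs.isdisjoint(truth.connector_otus)
            covered = set(truth.module_assignment[comp])
            assert hubs <= covered
            assert set(truth.connector_otus) <= covered
        assert truth.env_effect["TN"] == 0.0
        assert truth.env_effect["TOC"] > 0

    def test_hub_and_connector_sets_disjoint_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(
                module_assignment={"G": {"OTU1": 0}},
                hub_otus={"G": ["OTU1"]},
                connector_otus=["OTU1"],
                planted_pairs={"G": []},
                true_shannon={},
                env_effect={},
            )


class TestFixtureIO:
    def test_round_trip_and_load_time(self, tmp_path, dataset):
        paths = write_fixture(dataset, tmp_path)
        start = time.time()
        loaded = read_otu_table(
            paths["otu_table"], paths["taxonomy"], paths["metadata"]
        )
        assert time.time() - start < 5.0
        assert loaded.counts.equals(dataset.table.counts)
        truth = read_truth(paths["truth"])
        assert truth.module_assignment == dataset.truth.module_assignment
        with open(paths["truth"]) as fh:
            raw = json.load(fh)
        for comp in ("G", "T"):
            planted = set(raw["module_assignment"][comp])
            assert set(raw["hub_otus"][comp]) <= planted

    def test_fixture_bytes_reproducible(self, tmp_path, dataset):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_fixture(dataset, d1)
        p2 = write_fixture(generate_dataset(SyntheticConfig()), d2)
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


class TestAri:
    def test_identical_partitions(self):
        assert adjusted_rand_index([0, 0, 1, 1], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 4, size=30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                sklearn_metrics.adjusted_rand_score(a, b), abs=1e-12
            )
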