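import itertools

import networkx as nx
import numpy as np
import pytest

from rhizonet import network
from rhizonet.network import (
    ModulePartition,
    build_network,
    classify_roles,
    greedy_modularity,
    keystones,
    shared_keystones,
    topology,
    zi_pi,
)

from conftest import make_table


def exhaustive_best_modularity(graph):
    """Oracle: maximum modularity over all partitions (<= 8 nodes)."""
    nodes = list(graph.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [block + [first]] + part[i + 1 :]
            yield part + [[first]]

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(graph, [set(b) for b in part], weight=None)
        best = max(best, q)
    return best


def brute_force_zi_pi(graph, assignment):
    """Independent Zi/Pi computation written from the definitions."""
    out = {}
    modules = {}
    for node, m in assignment.items():
        modules.setdefault(m, []).append(node)
    for node in graph.nodes:
        m = assignment[node]
        k_is = sum(1 for nb in graph[node] if assignment[nb] == m)
        peers = [
            sum(1 for nb in graph[v] if assignment[nb] == m) for v in modules[m]
        ]
        mean = sum(peers) / len(peers)
        sd = (sum((p - mean) ** 2 for p in peers) / len(peers)) ** 0.5
        zi = 0.0 if sd == 0 else (k_is - mean) / sd
        k = graph.degree(node)
        pi = 0.0
        if k:
            counts = {}
            for nb in graph[node]:
                counts[assignment[nb]] = counts.get(assignment[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
        out[node] = (zi, pi)
    return out


class TestBuildNetwork:
    def test_monotone_pair_gets_positive_edge(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 100, size=12)
        counts = np.column_stack([base, 2 * base] + [
            rng.integers(10, 100, size=12) for _ in range(4)
        ])
        g = build_network(make_table(counts), p_adjust="none")
        assert g.has_edge("OTU1", "OTU2")
        assert g["OTU1"]["OTU2"]["sign"] == "positive"
        assert g["OTU1"]["OTU2"]["rho"] == pytest.approx(1.0)

    def test_antitone_pair_gets_negative_edge(self):
        base = np.arange(10, 22)
        counts = np.column_stack([base, base[::-1], np.full(12, 7)])
        g = build_network(make_table(counts), p_adjust="none")
        assert g["OTU1"]["OTU2"]["sign"] == "negative"
        assert "OTU3" not in g  # constant column excluded

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            build_network(make_table([[1, 2], [3, 4], [5, 6]]))

    def test_planted_edges_recovered(self, dataset, compartment_tables):
        from rhizonet.otu import filter_abundant
        from rhizonet.synthetic import edge_recovery

        for comp, sub in compartment_tables.items():
            g = build_network(filter_abundant(sub))
            assert edge_recovery(g, dataset.truth.planted_pairs[comp]) >= 0.8

    def test_cross_module_edges_rare(self, dataset, compartment_tables):
        from rhizonet.otu import filter_abundant

        for comp, sub in compartment_tables.items():
            g = build_network(filter_abundant(sub))
            planted = dataset.truth.module_assignment[comp]
            conn = set(dataset.truth.connector_otus)
            members = [o for o in planted if o not in conn]
            cross = [
                (a, b)
                for a, b in itertools.combinations(members, 2)
                if planted[a] != planted[b]
            ]
            spurious = sum(1 for a, b in cross if g.has_edge(a, b))
            assert spurious / len(cross) <= 0.05


class TestTopology:
    def test_triangle(self):
        g = nx.complete_graph(3)
        topo = topology(g, ModulePartition({n: 0 for n in g}, 0.0))
        assert topo.average_clustering == pytest.approx(1.0)
        assert topo.density == pytest.approx(1.0)
        assert topo.average_degree == pytest.approx(2.0)

    def test_star_path_length(self):
        g = nx.star_graph(3)  # 4 nodes
        topo = topology(g, ModulePartition({n: 0 for n in g}, 0.0))
        assert topo.average_clustering == pytest.approx(0.0)
        assert topo.average_path_length == pytest.approx(1.5)

    def test_sign_ratio(self):
        g = nx.Graph()
        for i in range(6):
            g.add_edge(f"p{i}", f"q{i}", sign="positive")
        g.add_edge("a", "b", sign="negative")
        g.add_edge("c", "d", sign="negative")
        topo = topology(g, ModulePartition({n: 0 for n in g}, 0.0))
        assert topo.positive_negative_ratio == pytest.approx(3.0)


class TestGreedyModularity:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = greedy_modularity(g)
        assert part.n_modules == 2
        assert part.modularity == pytest.approx(0.5, abs=1e-12)

    def test_bridged_triangles(self):
        g = nx.Graph(
            [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        )
        part = greedy_modularity(g)
        assert part.n_modules == 2
        assert part.modularity == pytest.approx(5 / 14, abs=1e-12)
        assert part.modularity == pytest.approx(exhaustive_best_modularity(g))

    def test_complete_graph_single_module(self):
        part = greedy_modularity(nx.complete_graph(5))
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_reported_q_matches_recomputation(self, compartment_tables):
        from rhizonet.otu import filter_abundant

        g = build_network(filter_abundant(compartment_tables["G"]))
        part = greedy_modularity(g)
        assert part.modularity == pytest.approx(
            network.modularity_q(g, part.assignment), abs=1e-12
        )

    def test_modules_labelled_by_descending_size(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3))
        part = greedy_modularity(g)
        sizes = part.module_sizes
        assert sizes[0] >= sizes[1]


class TestZiPi:
    def test_all_internal_edges_pi_zero(self):
        g = nx.complete_graph(4)
        part = ModulePartition({n: 0 for n in g}, 0.0)
        roles = zi_pi(g, part)
        assert (roles["pi"] == 0).all()
        assert (roles["zi"] == 0).all()  # equal within-degrees

    def test_split_degree_participation(self):
        g = nx.Graph([("x", "a"), ("x", "b"), ("x", "c"), ("x", "d"), ("a", "b")])
        assignment = {"x": 0, "a": 1, "b": 1, "c": 2, "d": 2}
        roles = zi_pi(g, ModulePartition(assignment, 0.0))
        assert roles.loc["x", "pi"] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 2:
                continue
            assignment = {v: int(rng.integers(3)) for v in g.nodes}
            roles = zi_pi(g, ModulePartition(assignment, 0.0))
            oracle = brute_force_zi_pi(g, assignment)
            for v in g.nodes:
                assert roles.loc[v, "zi"] == pytest.approx(oracle[v][0], abs=1e-12)
                assert roles.loc[v, "pi"] == pytest.approx(oracle[v][1], abs=1e-12)

    def test_degree_conservation(self, dataset, compartment_tables):
        from rhizonet.otu import filter_abundant

        g = build_network(filter_abundant(compartment_tables["T"]))
        part = greedy_modularity(g)
        roles = zi_pi(g, part)
        assert (roles["degree"] >= roles["within_degree"]).all()


class TestRoles:
    @pytest.mark.parametrize(
        "zi, pi, expected",
        [
            (3.0, 0.10, "module_hub"),
            (1.0, 0.70, "connector"),
            (3.0, 0.70, "network_hub"),
            (1.0, 0.10, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundaries fall to the lower class
            (2.5, 0.70, "connector"),
            (3.0, 0.62, "module_hub"),
        ],
    )
    def test_threshold_rule(self, zi, pi, expected):
        assert classify_roles(zi, pi) == expected

    def test_roles_partition_nodes(self, compartment_tables):
        from rhizonet.otu import filter_abundant

        g = build_network(filter_abundant(compartment_tables["G"]))
        roles = zi_pi(g, greedy_modularity(g))
        assert set(roles["role"]) <= {
            "peripheral", "connector", "module_hub", "network_hub"
        }
        assert len(roles) == g.number_of_nodes()

    def test_shared_keystones_identity_and_disjoint(self):
        import pandas as pd

        a = pd.DataFrame({"role": ["connector", "module_hub"]}, index=["x", "y"])
        b = pd.DataFrame({"role": ["connector", "peripheral"]}, index=["x", "y"])
        shared = shared_keystones({"A": a, "B": b})
        assert shared["connector"] == {"x"}
        assert shared["module_hub"] == set()
        identical = shared_keystones({"A": a, "B": a})
        assert identical["any_keystone"] == set(keystones(a))
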