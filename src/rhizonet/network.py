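"""Co-occurrence networks, module detection and Zi-Pi keystone classification.

Edges connect abundant OTUs whose relative abundances correlate with
|rho| >= a threshold at an adjusted p below alpha. Modules come from greedy
modularity (CNM) agglomeration on the unsigned, unweighted graph; node roles
follow the within-module degree z-score (Zi) and participation coefficient
(Pi) with the conventional thresholds Zi 2.5 and Pi 0.62 (strict
inequalities; non-peripheral nodes are the keystone candidates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .otu import OtuTable

logger = logging.getLogger("rhizonet")

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module_hub"
ROLE_NETWORK_HUB = "network_hub"
KEYSTONE_ROLES = (ROLE_CONNECTOR, ROLE_MODULE_HUB, ROLE_NETWORK_HUB)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def correlation_matrix(data: np.ndarray, method: str = "spearman"):
    """Pairwise correlations and two-sided p-values over columns."""
    if method == "spearman":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(data)
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
    elif method == "pearson":
        n_col = data.shape[1]
        rho = np.corrcoef(data, rowvar=False)
        n = data.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.eye(n_col, dtype=bool)] = 0.0
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return np.atleast_2d(rho), np.atleast_2d(p)


def build_network(
    table: OtuTable,
    corr_method: str = "spearman",
    min_abs_corr: float = 0.6,
    alpha: float = 0.05,
    p_adjust: str = "bh",
) -> nx.Graph:
    """Build a signed co-occurrence network over the table's OTUs.

    Correlations are computed on relative abundances; an edge is kept iff
    |rho| >= ``min_abs_corr`` AND the adjusted p < ``alpha`` (BH by default).
    Constant OTU columns are excluded with a warning and isolated nodes are
    dropped, so the node count can be below the OTU count.
    """
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples to estimate correlations")
    rel = table.relative_abundance()
    constant = rel.columns[rel.nunique() <= 1]
    if len(constant):
        logger.warning("excluding %d constant OTU columns", len(constant))
        rel = rel.drop(columns=constant)
    otus = list(rel.columns)
    rho, p = correlation_matrix(rel.to_numpy(), corr_method)

    iu = np.triu_indices(len(otus), 1)
    p_flat = p[iu]
    if p_adjust == "bh":
        p_adj = multipletests(p_flat, method="fdr_bh")[1]
    elif p_adjust == "bonferroni":
        p_adj = np.minimum(p_flat * len(p_flat), 1.0)
    elif p_adjust == "none":
        p_adj = p_flat
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    g = nx.Graph()
    keep = (np.abs(rho[iu]) >= min_abs_corr) & (p_adj < alpha)
    for k in np.flatnonzero(keep):
        i, j = iu[0][k], iu[1][k]
        r = float(rho[i, j])
        g.add_edge(
            otus[i], otus[j], rho=r, p_adj=float(p_adj[k]),
            sign="positive" if r > 0 else "negative",
        )
    phyla = table.taxonomy["phylum"]
    for node in g.nodes:
        g.nodes[node]["phylum"] = str(phyla.get(node, "unclassified_k__Fungi"))
    return g


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Node -> module id map with the modularity Q of the partition.

    Module ids are relabeled 0, 1, ... by descending module size.
    """

    assignment: dict
    modularity: float

    @property
    def module_sizes(self) -> dict:
        sizes: dict = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


def modularity_q(graph: nx.Graph, assignment: dict) -> float:
    """Q = sum_i (e_ii - a_i^2) on the unsigned, unweighted graph."""
    modules: dict = {}
    for node, m in assignment.items():
        modules.setdefault(m, set()).add(node)
    return nx.community.modularity(graph, modules.values(), weight=None)


def greedy_modularity(graph: nx.Graph) -> ModulePartition:
    """Greedy (Clauset-Newman-Moore) modularity agglomeration.

    Starts from singleton communities and merges the pair with the largest
    modularity gain until no merge improves Q; deterministic for a given
    graph. Module ids are assigned by descending size, ties broken by the
    smallest member label.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    communities = nx.community.greedy_modularity_communities(graph, weight=None)
    ordered = sorted(communities, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    assignment = {node: i for i, comm in enumerate(ordered) for node in comm}
    q = nx.community.modularity(graph, ordered, weight=None)
    return ModulePartition(assignment, float(q))


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    positive_negative_ratio: float
    average_degree: float
    average_clustering: float
    modularity: float
    average_path_length: float
    density: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def topology(graph: nx.Graph, partition: ModulePartition | None = None) -> NetworkTopology:
    """Standard topology metrics; path length over the largest component."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    m = graph.number_of_edges()
    signs = [d.get("sign", "positive") for _, _, d in graph.edges(data=True)]
    pos = signs.count("positive")
    neg = signs.count("negative")
    ratio = pos / neg if neg else float("inf")
    clustering = nx.average_clustering(graph) if n else 0.0
    components = sorted(nx.connected_components(graph), key=len)
    giant = graph.subgraph(components[-1])
    apl = (
        nx.average_shortest_path_length(giant)
        if giant.number_of_nodes() > 1
        else 0.0
    )
    if partition is None:
        partition = greedy_modularity(graph)
    return NetworkTopology(
        n_nodes=n,
        n_edges=m,
        n_positive=pos,
        n_negative=neg,
        positive_negative_ratio=float(ratio),
        average_degree=2 * m / n,
        average_clustering=float(clustering),
        modularity=partition.modularity,
        average_path_length=float(apl),
        density=nx.density(graph),
    )


# ---------------------------------------------------------------------------
# Zi-Pi node roles
# ---------------------------------------------------------------------------

def zi_pi(graph: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against the members of its
    own module (population sd; Zi = 0 when the sd is 0). Pi = 1 - sum over
    modules of (k_it / k_i)^2 with k_i the node's total degree.
    """
    missing = set(graph.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    nodes = list(graph.nodes)
    modules: dict = {}
    for node in nodes:
        modules.setdefault(partition.assignment[node], []).append(node)

    within = {}
    for node in nodes:
        m = partition.assignment[node]
        within[node] = sum(
            1 for nbr in graph.neighbors(node) if partition.assignment[nbr] == m
        )
    rows = []
    for m, members in modules.items():
        ks = np.array([within[v] for v in members], dtype=float)
        mean, sd = ks.mean(), ks.std()  # population sd
        for v in members:
            zi = 0.0 if sd == 0 else (within[v] - mean) / sd
            k = graph.degree(v)
            shares: dict = {}
            for nbr in graph.neighbors(v):
                t = partition.assignment[nbr]
                shares[t] = shares.get(t, 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in shares.values()) if k else 0.0
            rows.append((v, m, k, within[v], zi, pi))
    roles = pd.DataFrame(
        rows, columns=["otu", "module", "degree", "within_degree", "zi", "pi"]
    ).set_index("otu")
    roles["role"] = classify_roles(
        roles["zi"].to_numpy(), roles["pi"].to_numpy()
    )
    return roles.loc[nodes]


def classify_roles(zi, pi, zi_threshold: float = 2.5, pi_threshold: float = 0.62):
    """Four-way role labels with strict inequalities.

    Boundary values (Zi == 2.5 or Pi == 0.62) fall to the lower class, so a
    node at exactly the thresholds is peripheral.
    """
    scalar = np.ndim(zi) == 0 and np.ndim(pi) == 0
    zi = np.asarray(zi, dtype=float)
    pi = np.asarray(pi, dtype=float)
    roles = np.where(
        zi > zi_threshold,
        np.where(pi > pi_threshold, ROLE_NETWORK_HUB, ROLE_MODULE_HUB),
        np.where(pi > pi_threshold, ROLE_CONNECTOR, ROLE_PERIPHERAL),
    )
    return str(roles[()]) if scalar else roles


def keystones(roles: pd.DataFrame) -> pd.Index:
    """Non-peripheral nodes (module hubs, connectors, network hubs)."""
    return roles.index[roles["role"].isin(KEYSTONE_ROLES)]


def shared_keystones(role_tables: dict[str, pd.DataFrame]) -> dict[str, set]:
    """Intersect keystone OTU ids across >= 2 analysed networks, by role."""
    if len(role_tables) < 2:
        raise ValueError("need role tables for >= 2 networks")
    out: dict[str, set] = {}
    for role in KEYSTONE_ROLES:
        sets = [
            set(t.index[t["role"] == role]) for t in role_tables.values()
        ]
        out[role] = set.intersection(*sets)
    out["any_keystone"] = set.intersection(
        *(set(keystones(t)) for t in role_tables.values())
    )
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        (u, v, d["rho"], d["p_adj"], d["sign"])
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_node_table(roles: pd.DataFrame, graph: nx.Graph, path) -> None:
    out = roles.copy()
    out.insert(0, "phylum", [graph.nodes[n].get("phylum", "") for n in out.index])
    out.index.name = "otu"
    out.to_csv(path, sep="\t")
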