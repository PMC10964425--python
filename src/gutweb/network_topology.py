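"""Network-level and node-level topology: modules, hubs, keystone roles.

Module detection, betweenness and shortest paths run on the unweighted
version of the graph — edge weights are signed and modularity/shortest
paths are undefined for negative weights — while the sign layer is kept
for reporting. Keystone roles follow the within-module degree z-score (Zi)
versus among-module participation coefficient (Pi) framework: peripherals,
connectors, module hubs and network hubs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from gutweb.network_inference import AssociationNetwork

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class ModulePartition:
    assignment: dict  # node -> module id (0-based ints)
    modularity: float
    method: str = "fast_greedy"

    def __post_init__(self) -> None:
        if not -0.5 - 1e-12 <= self.modularity <= 1 + 1e-12:
            raise ValueError(f"modularity {self.modularity} outside [-0.5, 1]")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id) -> list:
        return [n for n, m in self.assignment.items() if m == module_id]


@dataclass
class NodeTopologyProfile:
    node: object
    degree: int
    betweenness: float
    zi: float
    pi: float
    role: str = "peripheral"

    def __post_init__(self) -> None:
        if not -1e-12 <= self.pi <= 1 + 1e-12:
            raise ValueError(f"pi {self.pi} outside [0, 1]")
        if self.betweenness < 0 or self.degree < 0:
            raise ValueError("degree and betweenness must be >= 0")


def _as_graph(net) -> nx.Graph:
    if isinstance(net, AssociationNetwork):
        return net.to_networkx()
    if isinstance(net, nx.Graph):
        return net
    raise TypeError(f"expected AssociationNetwork or networkx Graph, got {type(net)}")


# ---------------------------------------------------------------------------
# global statistics
# ---------------------------------------------------------------------------

def global_stats(net) -> dict:
    """Edge density, transitivity, module count/modularity, % negative edges."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global_stats needs at least 2 nodes")
    m = g.number_of_edges()
    density = 2 * m / (n * (n - 1))
    transitivity = nx.transitivity(g)
    partition = fast_greedy_modules(net)
    if m == 0:
        warnings.warn("graph has no edges; pct_negative_edges set to 0",
                      stacklevel=2)
        pct_negative = 0.0
    else:
        neg = sum(1 for _, _, d in g.edges(data=True)
                  if d.get("weight", 1) < 0)
        pct_negative = 100.0 * neg / m
    return {
        "n_nodes": n,
        "n_edges": m,
        "edge_density": density,
        "transitivity": transitivity,
        "n_modules": partition.n_modules,
        "modularity": partition.modularity,
        "pct_negative_edges": pct_negative,
    }


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def modularity_of_partition(g: nx.Graph, communities) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2) on the unweighted graph."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        comm = set(comm)
        internal = sum(1 for u, v in g.edges() if u in comm and v in comm)
        ends = sum(g.degree(u) for u in comm)
        q += internal / m - (ends / (2 * m)) ** 2
    return q


def fast_greedy_modules(net) -> ModulePartition:
    """Greedy agglomerative modularity maximization (Clauset–Newman–Moore).

    Runs on the unweighted graph; isolated nodes become singleton modules;
    an empty graph yields an empty partition with Q = 0.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        return ModulePartition(assignment={}, modularity=0.0)
    unweighted = nx.Graph()
    unweighted.add_nodes_from(g.nodes())
    unweighted.add_edges_from(g.edges())
    if unweighted.number_of_edges() == 0:
        assignment = {n: k for k, n in enumerate(unweighted.nodes())}
        return ModulePartition(assignment=assignment, modularity=0.0)
    communities = nx.community.greedy_modularity_communities(unweighted)
    assignment = {}
    for k, comm in enumerate(communities):
        for node in comm:
            assignment[node] = k
    q = modularity_of_partition(unweighted, communities)
    return ModulePartition(assignment=assignment, modularity=q)


# ---------------------------------------------------------------------------
# Zi / Pi and roles
# ---------------------------------------------------------------------------

def zi_pi(net, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    zi = (k_within - mean over the node's module) / sd over the module, with
    zi = 0 when the sd is 0; pi = 1 - sum_c (k_ic / k_i)^2, with pi = 0 for
    isolated nodes.
    """
    g = _as_graph(net)
    missing = [n for n in g.nodes() if n not in partition.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    module_of = partition.assignment
    k_within = {}
    k_per_module: dict = {}
    for node in g.nodes():
        counts: dict = {}
        for nbr in g.neighbors(node):
            m = module_of[nbr]
            counts[m] = counts.get(m, 0) + 1
        k_per_module[node] = counts
        k_within[node] = counts.get(module_of[node], 0)

    rows = []
    for node in g.nodes():
        deg = g.degree(node)
        mod = module_of[node]
        members = [n for n in g.nodes() if module_of[n] == mod]
        vals = np.array([k_within[n] for n in members], float)
        sd = vals.std()
        zi = 0.0 if sd == 0 else (k_within[node] - vals.mean()) / sd
        if deg == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((k / deg) ** 2 for k in k_per_module[node].values())
        rows.append({"node": node, "degree": deg, "zi": zi, "pi": pi,
                     "module": mod})
    return pd.DataFrame(rows).set_index("node")


def classify_roles(zipi: pd.DataFrame, zi_threshold: float = ZI_THRESHOLD,
                   pi_threshold: float = PI_THRESHOLD) -> pd.Series:
    """Assign each node one of the four keystone-role categories.

    network_hub: zi >= zi_threshold and pi > pi_threshold; module_hub:
    zi >= zi_threshold and pi <= pi_threshold; connector: zi < zi_threshold
    and pi > pi_threshold; peripheral otherwise.
    """
    zi = zipi["zi"]
    pi = zipi["pi"]
    role = pd.Series("peripheral", index=zipi.index, dtype=object)
    role[(zi >= zi_threshold) & (pi > pi_threshold)] = "network_hub"
    role[(zi >= zi_threshold) & (pi <= pi_threshold)] = "module_hub"
    role[(zi < zi_threshold) & (pi > pi_threshold)] = "connector"
    return role


def node_profiles(net, partition: ModulePartition | None = None,
                  zi_threshold: float = ZI_THRESHOLD,
                  pi_threshold: float = PI_THRESHOLD) -> list[NodeTopologyProfile]:
    """Full per-node topology profiles with role classification."""
    g = _as_graph(net)
    if partition is None:
        partition = fast_greedy_modules(net)
    zipi = zi_pi(net, partition)
    betw = nx.betweenness_centrality(
        nx.Graph(g.edges()) if g.number_of_edges() else g, normalized=True
    )
    roles = classify_roles(zipi, zi_threshold, pi_threshold)
    return [
        NodeTopologyProfile(
            node=node,
            degree=int(zipi.loc[node, "degree"]),
            betweenness=float(betw.get(node, 0.0)),
            zi=float(zipi.loc[node, "zi"]),
            pi=float(zipi.loc[node, "pi"]),
            role=str(roles[node]),
        )
        for node in g.nodes()
    ]


# ---------------------------------------------------------------------------
# hub subnetworks
# ---------------------------------------------------------------------------

def hub_subnetwork(net: AssociationNetwork, top_fraction: float = 0.30
                   ) -> AssociationNetwork:
    """Induced subgraph on the ceil(top_fraction * n) highest-degree nodes.

    Ties are broken by betweenness (unweighted shortest paths), then by node
    id.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    g = _as_graph(net)
    n_keep = math.ceil(top_fraction * g.number_of_nodes())
    betw = nx.betweenness_centrality(g, normalized=True)
    ranked = sorted(g.nodes(), key=lambda u: (-g.degree(u), -betw[u], str(u)))
    keep = set(ranked[:n_keep])
    edges = [(u, v, w) for u, v, w in net.edges if u in keep and v in keep]
    return AssociationNetwork(
        nodes=[n for n in net.nodes if n in keep],
        edges=edges,
        node_domain={n: d for n, d in net.node_domain.items() if n in keep},
        lambda_path=net.lambda_path, selected_lambda=net.selected_lambda,
        instability_per_lambda=net.instability_per_lambda,
        subsample_count=net.subsample_count, seed=net.seed,
    )
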