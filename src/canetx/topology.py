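"""Network-topology profiling: node connectivity and 12 summary measures.

Node connectivity chi_i is the sum of absolute weights of a node's incident
edges in the thresholded network (equivalently, the row sum of |weights|
including the implicit unit diagonal, minus 1).  The 12 network-level
measures summarise one association network as a row of a topology table
that downstream classification and PCA operate on.  All measures except
mean connectivity are computed on the unweighted skeleton (edge present iff
weight != 0).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd

from .netinfer import AssociationNetwork

__all__ = [
    "NodeConnectivity",
    "TopologyProfile",
    "node_connectivity",
    "topology_profile",
    "mean_degree_from_counts",
]


def mean_degree_from_counts(n_nodes: int, n_edges: int) -> float:
    """Normalised mean degree (edge density) 2E/(N(N-1)) from counts."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))

MEASURES = (
    "nodes",
    "edges",
    "mean_connectivity",
    "mean_degree",
    "mean_closeness",
    "mean_betweenness",
    "diameter",
    "mean_minimal_distance",
    "mean_page_rank",
    "hub_nodes",
    "centralization",
    "transitivity",
)


@dataclass(frozen=True)
class NodeConnectivity:
    chi: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self):
        chi = np.asarray(self.chi, dtype=float)
        object.__setattr__(self, "chi", chi)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        if np.any(chi < -1e-12):
            raise ValueError("connectivity must be nonnegative")


@dataclass(frozen=True)
class TopologyProfile:
    """The 12 named scalar topology measures of one network."""

    nodes: int
    edges: int
    mean_connectivity: float
    mean_degree: float
    mean_closeness: float
    mean_betweenness: float
    diameter: int
    mean_minimal_distance: float
    mean_page_rank: float
    hub_nodes: int
    centralization: float
    transitivity: float

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)}, name=name)


def node_connectivity(net: AssociationNetwork) -> NodeConnectivity:
    """chi_i = sum_j |r_ij| over incident thresholded edges."""
    chi = np.abs(net.weights).sum(axis=1)
    return NodeConnectivity(chi=chi, node_ids=net.node_ids)


def _skeleton(net: AssociationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


def topology_profile(
    net: AssociationNetwork,
    *,
    hub_rule: str = "mean_degree",
    hub_k: float = 1.0,
) -> TopologyProfile:
    """Compute the 12-measure profile of an association network.

    Definitions (unweighted skeleton unless noted):

    - nodes, edges: counts.
    - mean connectivity: mean of chi_i over nodes (weighted, the only
      weighted measure).
    - mean degree: edge density 2E/(N(N-1)).
    - mean closeness: Wasserman-Faust closeness (r/(N-1)) * (r/sum d) with
      r the number of nodes reachable from the node; isolated nodes 0.
    - mean betweenness: shortest-path betweenness normalised by
      (N-1)(N-2)/2.
    - diameter: maximum eccentricity within the largest connected
      component.
    - mean minimal distance: mean shortest-path length over connected
      unordered pairs.
    - mean PageRank: damping 0.85, uniform teleport (identically 1/N).
    - hub nodes: count of nodes with raw degree strictly greater than the
      mean raw degree (``hub_rule="mean_degree"``) or greater than
      mean + hub_k * SD (``hub_rule="mean_plus_sd"``).
    - centralization: Freeman degree centralization
      sum(dmax - d_i) / ((N-1)(N-2)).
    - transitivity: global clustering coefficient 3*triangles / triads.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("cannot profile an empty graph")
    g = _skeleton(net)
    e = g.number_of_edges()

    chi = node_connectivity(net).chi
    degrees = np.array([g.degree(v) for v in range(n)], dtype=float)

    mean_degree = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    closeness = nx.closeness_centrality(g, wf_improved=True)
    mean_closeness = float(np.mean(list(closeness.values())))
    betweenness = nx.betweenness_centrality(g, normalized=True)
    mean_betweenness = float(np.mean(list(betweenness.values())))

    if e == 0:
        diameter = 0
        mean_min_dist = 0.0
    else:
        comp = max(nx.connected_components(g), key=len)
        diameter = int(nx.diameter(g.subgraph(comp)))
        total, pairs = 0.0, 0
        for _, dists in nx.all_pairs_shortest_path_length(g):
            for d in dists.values():
                if d > 0:
                    total += d
                    pairs += 1
        mean_min_dist = total / pairs  # each unordered pair counted twice; ratio unchanged

    pr = nx.pagerank(g, alpha=0.85) if e > 0 else {v: 1.0 / n for v in range(n)}
    mean_page_rank = float(np.mean(list(pr.values())))

    mean_raw_degree = degrees.mean()
    if hub_rule == "mean_degree":
        hub_cut = mean_raw_degree
    elif hub_rule == "mean_plus_sd":
        hub_cut = mean_raw_degree + hub_k * degrees.std(ddof=0)
    else:
        raise ValueError(f"unknown hub rule {hub_rule!r}")
    hub_nodes = int(np.sum(degrees > hub_cut))

    if n > 2:
        centralization = float(np.sum(degrees.max() - degrees) / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0

    transitivity = float(nx.transitivity(g))

    return TopologyProfile(
        nodes=n,
        edges=e,
        mean_connectivity=float(chi.mean()),
        mean_degree=float(mean_degree),
        mean_closeness=mean_closeness,
        mean_betweenness=mean_betweenness,
        diameter=diameter,
        mean_minimal_distance=float(mean_min_dist),
        mean_page_rank=mean_page_rank,
        hub_nodes=hub_nodes,
        centralization=centralization,
        transitivity=transitivity,
    )
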