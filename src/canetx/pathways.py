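"""Pathway over-representation and topology-weighted impact analysis.

Enrichment is the hypergeometric upper tail of the observed hit count
among a pathway's members within the tested universe.  Pathway impact
weights each member by its relative betweenness centrality in the pathway
graph, so hits on structurally central metabolites or genes count more:

    impact = sum_{v in hits} w(v) / sum_{v in graph} w(v),   in [0, 1].

Joint analysis pools gene and compound hits/universes (identifiers must be
kind-prefixed to avoid namespace collisions) and runs the same machinery
on the pooled pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffnet import adjust_pvalues

__all__ = [
    "PathwaySet",
    "PathwayResult",
    "read_gmt",
    "read_sif",
    "pathway_enrichment",
    "pathway_impact",
    "joint_pathway_analysis",
]


@dataclass(frozen=True)
class PathwaySet:
    """Named pathways (member feature-id sets) with optional member graphs."""

    pathways: dict[str, frozenset]
    graphs: dict[str, nx.Graph] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "pathways", {k: frozenset(v) for k, v in self.pathways.items()}
        )
        for name, g in self.graphs.items():
            if name not in self.pathways:
                raise ValueError(f"graph for unknown pathway {name!r}")
            extra = set(g.nodes) - set(self.pathways[name])
            if extra:
                raise ValueError(
                    f"graph nodes not in pathway {name!r}: {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.pathways)

    def names(self) -> list[str]:
        return list(self.pathways)


@dataclass(frozen=True)
class PathwayResult:
    pathway: str
    hits: int
    size: int
    p: float
    p_adj: float
    impact: float | None = None

    def __post_init__(self):
        if self.hits > self.size:
            raise ValueError("hits cannot exceed pathway size")
        if self.impact is not None and not (0 <= self.impact <= 1 + 1e-12):
            raise ValueError("impact must lie in [0, 1]")


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    """Read GMT pathway memberships (name, description, members...)."""
    pathways = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name = parts[0]
        if name in pathways:
            raise ValueError(f"duplicate pathway name {name!r}")
        pathways[name] = frozenset(parts[2:])
    return pathways


def read_sif(path: str | Path) -> nx.Graph:
    """Read a SIF edge list (node relation node) as an undirected graph."""
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:
            g.add_node(parts[0])
        elif len(parts) >= 3:
            for target in parts[2:]:
                g.add_edge(parts[0], target, relation=parts[1])
        else:
            raise ValueError(f"malformed SIF line: {line!r}")
    return g


def pathway_enrichment(
    hits: set, universe: set, ps: PathwaySet, *, with_impact: bool = True
) -> list[PathwayResult]:
    """Hypergeometric over-representation of ``hits`` in each pathway.

    Only pathway members inside ``universe`` count toward pathway size; p is
    the upper-tail probability of at least the observed overlap.  BH
    adjustment across pathways; impact is attached when a pathway graph is
    available and ``with_impact`` is set.
    """
    hits, universe = set(hits), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    m_univ = len(universe)
    n_hits = len(hits)
    raw = []
    for name, members in ps.pathways.items():
        members_in = members & universe
        k = len(members_in & hits)
        size = len(members_in)
        # P(X >= k), X ~ Hypergeom(M=m_univ, K=size, n=n_hits)
        p = float(stats.hypergeom.sf(k - 1, m_univ, size, n_hits)) if size else 1.0
        raw.append((name, k, size, min(1.0, p)))
    p_adj = adjust_pvalues([r[3] for r in raw], "BH")
    results = []
    for (name, k, size, p), q in zip(raw, p_adj):
        impact = None
        if with_impact and name in ps.graphs:
            impact = pathway_impact(hits, ps.graphs[name])
        results.append(
            PathwayResult(pathway=name, hits=k, size=size, p=p, p_adj=float(q), impact=impact)
        )
    return results


def pathway_impact(
    hits: set, pathway_graph: nx.Graph, *, zero_floor: str = "degree"
) -> float:
    """Fraction of the pathway's betweenness-centrality mass carried by hits.

    Node weights are relative betweenness centralities (computed per
    connected component for disconnected graphs).  With the default
    ``zero_floor="degree"`` a node whose betweenness is zero (e.g. a leaf)
    receives a small floor weight proportional to its degree — scaled by
    the smallest positive betweenness in the graph — so peripheral hits
    still register; ``zero_floor="none"`` uses pure betweenness.
    """
    if pathway_graph.number_of_nodes() == 0:
        raise ValueError("empty pathway graph")
    bc = nx.betweenness_centrality(pathway_graph, normalized=True)
    weights = dict(bc)
    if zero_floor == "degree":
        positive = [v for v in bc.values() if v > 0]
        scale = min(positive) if positive else 1.0
        max_deg = max((d for _, d in pathway_graph.degree()), default=0) or 1
        for node, v in bc.items():
            if v == 0:
                weights[node] = scale * pathway_graph.degree(node) / max_deg
    elif zero_floor != "none":
        raise ValueError(f"unknown zero_floor {zero_floor!r}")
    total = sum(weights.values())
    if total == 0:
        # no structure at all (e.g. edgeless graph): fall back to hit fraction
        return len(set(hits) & set(pathway_graph.nodes)) / pathway_graph.number_of_nodes()
    hit_mass = sum(w for node, w in weights.items() if node in hits)
    return float(min(1.0, hit_mass / total))


def joint_pathway_analysis(
    gene_hits: set,
    met_hits: set,
    gene_universe: set,
    met_universe: set,
    ps: PathwaySet,
) -> list[PathwayResult]:
    """Pooled gene + metabolite enrichment and impact.

    Gene and compound identifier namespaces must be disjoint (use kind
    prefixes such as ``gene:`` / ``cpd:``); hits and universes are pooled
    and a single hypergeometric test is run per pathway on the pooled
    counts, with impact on the pooled pathway graph.
    """
    if set(gene_universe) & set(met_universe):
        overlap = sorted(set(gene_universe) & set(met_universe))[:5]
        raise ValueError(
            f"gene and metabolite identifier namespaces overlap (e.g. {overlap}); "
            "prefix identifiers by kind"
        )
    hits = set(gene_hits) | set(met_hits)
    universe = set(gene_universe) | set(met_universe)
    return pathway_enrichment(hits, universe, ps)


def impact_matrix(results_by_analysis: dict[str, list[PathwayResult]]) -> pd.DataFrame:
    """Assemble an (analysis x pathway) impact-score matrix for PCA/clustering.

    Missing impacts become 0; column order is the sorted pathway union, so
    assembly is independent of input ordering.
    """
    pathways = sorted({r.pathway for results in results_by_analysis.values() for r in results})
    out = pd.DataFrame(0.0, index=sorted(results_by_analysis), columns=pathways)
    for analysis, results in results_by_analysis.items():
        for r in results:
            out.loc[analysis, r.pathway] = r.impact if r.impact is not None else 0.0
    return out
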