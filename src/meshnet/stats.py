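"""Connectivity statistics for semantic networks.

All statistics treat the graph as unweighted and simple: edge weights
(document counts) play no role here.  Degree centralization is Freeman's
statistic, sum(d_max - d_i) / ((N-1)(N-2)): 1 for a star, 0 for any
regular graph — a measure of how much a few hubs dominate connectivity.

The average clustering coefficient is exposed in two conventions, because
network tools differ on whether nodes of degree < 2 (whose local
coefficient is undefined) enter the mean as zeros or are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .network import SemanticNetwork


@dataclass
class NetworkStatsReport:
    n_nodes: int
    n_edges: int
    density: float
    avg_neighbors: float
    avg_clustering: float
    avg_clustering_deg2: float  # mean over nodes of degree >= 2 only
    centralization: float
    n_components: int
    degree_table: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self, precision: int = 3) -> dict:
        """JSON-ready view, floats rounded to the reporting precision."""
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": round(self.density, precision),
            "avg_neighbors": round(self.avg_neighbors, precision),
            "avg_clustering": round(self.avg_clustering, precision),
            "avg_clustering_deg2": round(self.avg_clustering_deg2, precision),
            "centralization": round(self.centralization, precision),
            "n_components": self.n_components,
            "degree_table": [list(row) for row in self.degree_table],
        }


def degree_table(net: SemanticNetwork) -> list[tuple[str, int]]:
    """(label, degree) sorted by degree descending, ties lexicographic."""
    return sorted(net.graph.degree(), key=lambda t: (-t[1], t[0]))


def avg_neighbors(net: SemanticNetwork) -> float:
    """Mean degree, 2E/N."""
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network")
    return 2.0 * net.n_edges / n


def local_clustering(net: SemanticNetwork, label: str) -> float:
    """Fraction of a node's neighbor pairs that are themselves linked;
    0 for degree < 2."""
    if label not in net.graph:
        raise KeyError(f"unknown node label {label!r}")
    return nx.clustering(net.graph, label)


def avg_clustering(net: SemanticNetwork, include_low_degree: bool = True) -> float:
    """Mean local clustering.

    With ``include_low_degree`` (default) every node contributes, degree<2
    nodes as 0; otherwise the mean runs over degree>=2 nodes only.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    cc = nx.clustering(net.graph)
    if include_low_degree:
        return sum(cc.values()) / len(cc)
    vals = [c for n, c in cc.items() if net.graph.degree(n) >= 2]
    return sum(vals) / len(vals) if vals else 0.0


def degree_centralization(net: SemanticNetwork) -> float:
    """Freeman degree centralization on the global graph."""
    n = net.n_nodes
    if n < 3:
        raise ValueError("centralization undefined for fewer than 3 nodes")
    degrees = [d for _, d in net.graph.degree()]
    d_max = max(degrees)
    return sum(d_max - d for d in degrees) / ((n - 1) * (n - 2))


def full_report(net: SemanticNetwork) -> NetworkStatsReport:
    """All connectivity statistics in one report."""
    n, e = net.n_nodes, net.n_edges
    return NetworkStatsReport(
        n_nodes=n,
        n_edges=e,
        density=(2.0 * e / (n * (n - 1))) if n >= 2 else 0.0,
        avg_neighbors=avg_neighbors(net) if n >= 1 else 0.0,
        avg_clustering=avg_clustering(net, True) if n >= 1 else 0.0,
        avg_clustering_deg2=avg_clustering(net, False) if n >= 1 else 0.0,
        centralization=degree_centralization(net) if n >= 3 else 0.0,
        n_components=nx.number_connected_components(net.graph),
        degree_table=degree_table(net),
    )
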