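"""First-neighbor (ego) subnetworks.

An ego subnetwork of a seed term contains the seed, its direct neighbors,
and ALL parent edges among those members (induced-subgraph semantics, the
behavior of Cytoscape's "select first neighbors" followed by "new network
from selection").  Edge weights and supporting PMID sets are carried over
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import SemanticNetwork
from .stats import NetworkStatsReport, full_report


@dataclass
class EgoSubnetwork:
    seed: str
    members: frozenset[str]
    graph: SemanticNetwork
    stats: NetworkStatsReport


def _suggest(net: SemanticNetwork, seed_label: str) -> list[str]:
    needle = seed_label.lower()
    return sorted(n for n in net.graph.nodes if needle in str(n).lower())


def find_labels(net: SemanticNetwork, query: str) -> list[str]:
    """Case-insensitive substring search over node labels (a helper; it
    never silently substitutes for an exact seed)."""
    return _suggest(net, query)


def ego_subnetwork(net: SemanticNetwork, seed_label: str) -> EgoSubnetwork:
    """Extract the induced subnetwork on a seed and its first neighbors."""
    if seed_label not in net.graph:
        matches = _suggest(net, seed_label)
        hint = f"; close matches: {matches[:5]}" if matches else ""
        raise KeyError(f"seed {seed_label!r} not in network{hint}")
    members = frozenset({seed_label} | set(net.graph.neighbors(seed_label)))
    sub = SemanticNetwork(
        graph=net.graph.subgraph(members).copy(), config=net.config
    )
    return EgoSubnetwork(
        seed=seed_label, members=members, graph=sub, stats=full_report(sub)
    )


def compare_subnets(
    subs: list[EgoSubnetwork], n_listed: int = 10, low_degree_max: int = 10
) -> pd.DataFrame:
    """Side-by-side connectivity comparison of ego subnetworks.

    One row per subnet: counts, clustering, centralization, mean degree,
    the top hubs, and the under-represented members — those of degree at
    most ``low_degree_max``, lowest first, capped at ``n_listed``.
    """
    if len(subs) < 2:
        raise ValueError("need at least two subnetworks to compare")
    rows = []
    for s in subs:
        table = s.stats.degree_table
        low = [lab for lab, d in reversed(table) if d <= low_degree_max]
        rows.append(
            {
                "seed": s.seed,
                "n_nodes": s.stats.n_nodes,
                "n_edges": s.stats.n_edges,
                "avg_clustering": s.stats.avg_clustering,
                "centralization": s.stats.centralization,
                "avg_neighbors": s.stats.avg_neighbors,
                "top_hubs": [lab for lab, _ in table[:n_listed]],
                "under_represented": low[:n_listed],
            }
        )
    return pd.DataFrame(rows)
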