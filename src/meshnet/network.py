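"""MeSH co-occurrence semantic networks.

Nodes are rendered MeSH term labels; an undirected edge links two terms
whenever at least one document carries both, weighted by the number of such
documents (repeat co-occurrence strengthens the link), with the supporting
PMIDs kept on the edge.  The graph is simple: no self-loops, at most one
edge per unordered pair.

Rendering conventions are configurable because corpora differ in whether a
qualified heading (``Ethics, Medical/education``) and a major-topic starred
variant (``*Bioethical Issues``) count as terms of their own.  The defaults
— composite qualifier handling, starred variants distinct — match corpora
in which both forms appear as separate nodes.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

from .medline import Corpus, MeshHeading

logger = logging.getLogger(__name__)

QUALIFIER_MODES = ("composite", "descriptor_only")
MAJOR_MODES = ("distinct", "merged")
FORMATS = ("sif", "graphml", "edge-csv")


@dataclass(frozen=True)
class NetworkBuildConfig:
    """Knobs that decide how headings become node labels and which edges
    survive.

    qualifier_mode
        ``composite`` renders descriptor and qualifiers joined by ``/`` as
        one label; ``descriptor_only`` drops qualifiers.
    major_mode
        ``distinct`` re-attaches the ``*`` so starred and unstarred
        variants are different nodes; ``merged`` drops the star.
    min_edge_weight
        Edges supported by fewer documents are pruned (then isolated
        nodes are removed).  1 keeps everything.
    """

    qualifier_mode: str = "composite"
    major_mode: str = "distinct"
    min_edge_weight: int = 1

    def __post_init__(self) -> None:
        if self.qualifier_mode not in QUALIFIER_MODES:
            raise ValueError(f"qualifier_mode must be one of {QUALIFIER_MODES}")
        if self.major_mode not in MAJOR_MODES:
            raise ValueError(f"major_mode must be one of {MAJOR_MODES}")
        if self.min_edge_weight < 1:
            raise ValueError("min_edge_weight must be >= 1")


@dataclass
class SemanticNetwork:
    """Undirected weighted term co-occurrence graph.

    Wraps a :class:`networkx.Graph` whose nodes carry ``doc_count`` and
    whose edges carry ``weight`` (int) and ``pmids`` (frozenset of str).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    config: NetworkBuildConfig = field(default_factory=NetworkBuildConfig)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            pmids = d.get("pmids")
            if pmids is not None and d.get("weight") != len(pmids):
                raise ValueError(f"edge {u!r}-{v!r} weight != |pmids|")


def render_heading(h: MeshHeading, config: NetworkBuildConfig) -> list[str]:
    """Render a parsed heading to the node label(s) it contributes."""
    star = config.major_mode == "distinct"
    desc = ("*" if star and h.descriptor_major else "") + h.descriptor
    if config.qualifier_mode == "descriptor_only" or not h.qualifiers:
        return [desc]
    parts = [desc]
    for q, major in zip(h.qualifiers, h.qualifier_major):
        parts.append(("*" if star and major else "") + q)
    return ["/".join(parts)]


def build_cooccurrence_network(
    corpus: Corpus, config: NetworkBuildConfig | None = None
) -> SemanticNetwork:
    """Build the co-occurrence network of a corpus.

    Every unordered pair of distinct rendered labels within one document
    contributes that document's PMID to the pair's edge.  Edges below
    ``min_edge_weight`` are dropped, then isolated nodes.
    """
    config = config or NetworkBuildConfig()
    g = nx.Graph()
    doc_count: dict[str, int] = {}
    support: dict[tuple[str, str], set[str]] = {}
    any_heading = False
    for record in corpus.records:
        labels: set[str] = set()
        for h in record.headings:
            labels.update(render_heading(h, config))
        if labels:
            any_heading = True
        for lab in labels:
            doc_count[lab] = doc_count.get(lab, 0) + 1
        for a, b in combinations(sorted(labels), 2):
            support.setdefault((a, b), set()).add(record.pmid)
    if not any_heading:
        logger.warning("corpus has no MeSH headings; network is empty")
        return SemanticNetwork(graph=g, config=config)
    for (a, b), pmids in support.items():
        if len(pmids) >= config.min_edge_weight:
            g.add_edge(a, b, weight=len(pmids), pmids=frozenset(pmids))
    for node in g.nodes:
        g.nodes[node]["doc_count"] = doc_count[node]
    return SemanticNetwork(graph=g, config=config)


# ---------------------------------------------------------------------------
# I/O: SIF (+ sidecar attribute CSV), GraphML, edge-list CSV
# ---------------------------------------------------------------------------

def write_sif(net: SemanticNetwork, interaction_label: str = "co") -> str:
    """Simple Interaction Format text: ``source<TAB>label<TAB>target``,
    endpoints lexicographic within a line, lines sorted; isolated nodes as
    single-field lines.  Weights/PMIDs do not fit SIF — see
    :func:`edge_attributes_csv`."""
    lines = []
    for u, v in net.graph.edges:
        a, b = sorted((u, v))
        lines.append(f"{a}\t{interaction_label}\t{b}")
    for n in net.graph.nodes:
        if net.graph.degree(n) == 0:
            lines.append(str(n))
    return "\n".join(sorted(lines)) + ("\n" if lines else "")


def edge_attributes_csv(net: SemanticNetwork) -> str:
    """Sidecar table for SIF: source,target,weight,pmids (pmids ;-joined)."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["source", "target", "weight", "pmids"])
    for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: sorted(e[:2])):
        a, b = sorted((u, v))
        pmids = ";".join(sorted(d.get("pmids", ()))) if d.get("pmids") else ""
        w.writerow([a, b, d.get("weight", 1), pmids])
    return buf.getvalue()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".attrs.csv")


def save_network(net: SemanticNetwork, path: str | Path, format: str = "sif") -> None:
    path = Path(path)
    if format == "sif":
        path.write_text(write_sif(net))
        _sidecar_path(path).write_text(edge_attributes_csv(net))
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.graph.nodes)
        for n, d in net.graph.nodes(data=True):
            if "doc_count" in d:
                g.nodes[n]["doc_count"] = int(d["doc_count"])
        for u, v, d in net.graph.edges(data=True):
            attrs = {"weight": int(d.get("weight", 1))}
            if d.get("pmids"):
                attrs["pmids"] = ";".join(sorted(d["pmids"]))
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    elif format == "edge-csv":
        path.write_text(edge_attributes_csv(net))
    else:
        raise ValueError(f"unknown network format {format!r}")


def _add_edge_once(g: nx.Graph, u: str, v: str, **attrs) -> None:
    if u == v:
        logger.warning("ignoring self-loop %r", u)
        return
    if g.has_edge(u, v):
        logger.warning("duplicate edge %r-%r ignored", u, v)
        return
    g.add_edge(u, v, **attrs)


def read_network(path: str | Path, format: str = "sif") -> SemanticNetwork:
    """Read a network from SIF (with optional sidecar), GraphML or edge CSV.

    Missing weights default to 1; duplicate edge lines are ignored with a
    warning (weights are not summed).
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected {FORMATS}")
    g = nx.Graph()
    if format == "sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                g.add_node(parts[0].strip())
            else:
                source, _label, *targets = parts
                for t in targets:
                    _add_edge_once(g, source, t, weight=1)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            for row in csv.DictReader(io.StringIO(sidecar.read_text())):
                if g.has_edge(row["source"], row["target"]):
                    pmids = frozenset(p for p in row["pmids"].split(";") if p)
                    g.edges[row["source"], row["target"]].update(
                        weight=int(row["weight"]), pmids=pmids
                    )
    elif format == "graphml":
        raw = nx.read_graphml(path)
        g.add_nodes_from(str(n) for n in raw.nodes)
        for n, d in raw.nodes(data=True):
            if "doc_count" in d:
                g.nodes[str(n)]["doc_count"] = int(d["doc_count"])
        for u, v, d in raw.edges(data=True):
            attrs = {"weight": int(d.get("weight", 1))}
            if d.get("pmids"):
                attrs["pmids"] = frozenset(d["pmids"].split(";"))
            _add_edge_once(g, str(u), str(v), **attrs)
    else:  # edge-csv
        for row in csv.DictReader(io.StringIO(path.read_text())):
            attrs = {"weight": int(row.get("weight") or 1)}
            if row.get("pmids"):
                attrs["pmids"] = frozenset(p for p in row["pmids"].split(";") if p)
            _add_edge_once(g, row["source"], row["target"], **attrs)
    return SemanticNetwork(graph=g)
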