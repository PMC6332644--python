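import networkx as nx
import pytest

from meshnet import (
    Corpus,
    MedlineRecord,
    SemanticNetwork,
    merge_and_dedupe,
    parse_mesh_heading,
)

# Hand-written three-record MEDLINE fixture: wrapped abstract continuation
# lines, affiliations, and the descriptor/qualifier/major-star MH notation.
MEDLINE_3RECORDS = """\
PMID- 10000001
DP  - 2005 Jan
TI  - Advisory committees and public policy in bioethics
AB  - This is a wrapped abstract that continues
      on a second line for parsing.
AD  - Department of Bioethics, Somewhere University, United States.
PL  - United States
MH  - Humans
MH  - *Public Policy
MH  - Ethics, Medical/*education

PMID- 10000002
TI  - Research ethics committees at work
MH  - Humans
MH  - Advisory Committees
MH  - Bioethical Issues

PMID- 10000003
TI  - Social control and government regulation
AB  - Short abstract about regulation.
MH  - Government Regulation
MH  - Social Control, Formal
MH  - Institutionalization/ethics
"""


def make_record(pmid, headings=(), title="t", abstract="", **kw):
    return MedlineRecord(
        pmid=str(pmid),
        title=title,
        abstract=abstract,
        headings=[parse_mesh_heading(h) for h in headings],
        **kw,
    )


def corpus_of(docs, titles=None, abstracts=None):
    """Corpus from {pmid: [raw MH strings]} plus optional per-pmid text."""
    records = []
    for pmid, headings in docs.items():
        records.append(
            make_record(
                pmid,
                headings,
                title=(titles or {}).get(pmid, f"Title {pmid}"),
                abstract=(abstracts or {}).get(pmid, ""),
            )
        )
    return merge_and_dedupe([("q", records)])


def net_of(edges, nodes=(), **edge_attrs):
    """SemanticNetwork from an edge list (weights default 1)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            u, v, w = e
        else:
            (u, v), w = e, 1
        g.add_edge(u, v, weight=w, **edge_attrs)
    return SemanticNetwork(graph=g)


@pytest.fixture
def medline_text():
    return MEDLINE_3RECORDS


@pytest.fixture
def triangle():
    return net_of([("A", "B"), ("A", "C"), ("B", "C")])
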