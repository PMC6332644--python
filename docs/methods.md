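# Methods

This note records the models, conventions and design choices behind
`meshnet`, in the order the pipeline runs.

## MEDLINE parsing

The parser accepts PubMed's tagged plain-text export: a tag of 2–4
uppercase characters, optional padding, `- `, value; indented lines
continue the previous value and are joined with a single space; blank
lines separate citations. Tag padding is tolerated in both directions
(`MH  - ` and `MH - `) because exports differ across PubMed eras. Input
bytes are decoded as UTF-8 with replacement of invalid sequences (logged).
A block with no `PMID` tag is skipped with a warning; a malformed line
inside a block is ignored with a warning. MeSH heading values are split on
`/` into descriptor plus qualifiers; a leading `*` on either is parsed
into a major-topic flag, so no star character ever survives inside a
label. Country is taken from the `PL` (place of publication) field when
present. The writer emits unwrapped values; round-tripping a corpus
through write/parse is field-identical up to line wrapping.

Merging keeps the **first** occurrence of each PMID in input order,
retaining its query label; colliding records with differing titles are
collapsed anyway and logged. Deduplication is by PMID equality alone —
the natural key of MEDLINE records. The bookkeeping identity
`duplicates_removed = Σ per-query retrieved − unique records` is enforced
as a container invariant.

## Co-occurrence network

Nodes are rendered heading labels; configuration decides the rendering:

- `qualifier_mode`: `composite` (default) joins descriptor and qualifiers
  with `/` into one label; `descriptor_only` collapses qualified variants
  onto the bare descriptor.
- `major_mode`: `distinct` (default) re-attaches the `*`, so a starred
  (major-topic) variant is a different node from the unstarred one;
  `merged` drops the star.

The defaults reflect corpora in which qualified composites
(`Ethics, Medical/education`) and starred variants (`*Bioethical Issues`)
are counted as terms of their own. Within each document, every unordered
pair of distinct rendered labels contributes the document's PMID to that
pair's edge; the edge weight is the size of its supporting PMID set. The
graph is simple and undirected — weights encode repeat co-occurrence, so
multi-edges are unnecessary — and self-loops are meaningless under set
semantics. `min_edge_weight` (default 1, i.e. keep everything) prunes
weak edges and then isolated nodes; raising it only ever shrinks the edge
set.

SIF cannot carry attributes, so the SIF writer pairs each `.sif` with a
sidecar `.sif.attrs.csv` (`source,target,weight,pmids`); GraphML carries
weight and the `;`-joined PMID set inline. On read, missing weights
default to 1 and duplicate edge lines are ignored (not summed) with a
warning, since a repeated line in these formats is almost always an
export artifact rather than a second observation.

## Connectivity statistics

All statistics are computed on the unweighted simple graph — the usual
convention of desktop network tools, and the only one under which the
closed forms below hold. Local clustering of a node with degree `k ≥ 2`
is `2·t/(k(k−1))` with `t` the edge count among its neighbors; nodes with
`k < 2` have coefficient 0. Because tools differ on whether such nodes
enter the network average as zeros or are excluded, both means are
computed and reported side by side (`avg_clustering`,
`avg_clustering_deg2`); the including-as-zero convention is the default.
Degree centralization is Freeman's `Σ_i(d_max − d_i)/((N−1)(N−2))`,
undefined below 3 nodes (an error), computed globally with the global
maximum even on disconnected graphs. Reports round to 3 decimals for
display; internal computation is full precision. Standard graph
primitives (local clustering, components) are delegated to networkx; the
test suite checks both clustering and centralization against independent
brute-force enumerations on an exhaustive small-graph sweep (tolerance
1e-12) and against the star/regular closed forms up to 1000 nodes.

## Ego subnetworks

`ego_subnetwork` uses induced-subgraph semantics: seed plus first
neighbors, with **all** parent edges among members and their original
weights and PMID sets. Consequently the subnet has exactly
`degree(seed) + 1` nodes, and re-extracting the same seed inside the
subnet is idempotent. Seed matching is exact on rendered labels; a
substring search helper exists for discovery but never substitutes
silently — an unknown seed raises, listing close matches. The comparison
table lists "under-represented" members as those with degree at most 10
(configurable), mirroring how low-connectivity concepts are singled out
in hub-dominated networks.

## Content coding

The codebook engine is a deterministic, file-based replacement for
interactive CAQDAS coding. A codebook is an ordered list of category
columns, each with codes, each code with one or more case-insensitive
patterns (literal or regex; literals are regex-escaped). Coding is at the
**document** level over the concatenated selected fields (title and/or
abstract): a code attaches iff any of its patterns matches; no stemming
or lemmatization. Character spans of matches are stored for audit but do
not affect counts — the quantitative outputs (frequencies, flows) are
per-document, so quotation-level spans would add bookkeeping without
changing any number. Flow magnitude between adjacent columns counts
document-level code-pair combinations (a document with 2 left and 2 right
codes contributes 4), matching how long-format alluvial inputs are built;
zero flows are omitted and output order is sorted for determinism.

The inductive (emergent-category) step of qualitative analysis is
inherently human; the tool supports it as a loop: `recode` re-applies a
revised codebook and reports categories/codes added and removed plus
per-document assignment changes. Each coding result records its
codebook's full (category, code) universe so the diff is exact even for
codes that never matched. The shipped example codebooks demonstrate a
six-column a-priori protocol and a four-column emergent remodel; their
match patterns are illustrative cues only.

## Synthetic corpus generator

The generator emulates the corpus shape of a multi-query retrieval. Its
defaults are fixed study conditions: five queries of sizes
4/18/42/433/666 (1163 retrieved) with per-query duplicate counts
(0, 2, 6, 50, 335) — 393 collisions, 770 unique records. Duplicates are
realised by re-emitting earlier unique records into later query files,
which is how cross-query overlap arises in reality; the explicit
per-query counts exist because a corpus with an exact collision total
cannot be pinned down by a rate alone (`duplicate_rate` drives the counts
when they are not given). PMIDs are drawn without replacement from a
fixed integer range.

Headings are sampled from a ~700-label MeSH-like vocabulary (a curated
core of policy/bioethics terms, qualified variants, and generated
composites) with Zipf-skewed popularity (`rank^-0.8`), 5–15 headings per
record; `Humans` behaves like a MEDLINE check tag, attached to ~90% of
records. Each record draws one planted term community whose members'
weights are boosted (default ×3), creating clustered co-occurrence
structure. Under these defaults a 770-record corpus yields a network of
roughly 680 nodes, density ≈ 0.09, mean degree ≈ 60, average clustering
≈ 0.6 and centralization ≈ 0.91 with `Humans`/`United States`-type hubs —
the sparse, highly centralized, clustered topology characteristic of real
MeSH co-occurrence networks. What the generator does **not** emulate:
natural-language abstracts (text is templated), real MeSH tree structure,
temporal drift of vocabulary, and journal/author metadata. Passing tests
therefore demonstrate correctness of the mechanics (parsing, dedup
arithmetic, edge counting, coding), not fidelity to any particular real
corpus.

`ground_truth_check` closes the loop: it runs parse → merge → build →
stats → code on the generated files and compares every recoverable
quantity (unique/duplicate counts, per-query provenance, exact edge
weights, node document counts, planted-keyword code assignments) with the
generator's own record, reporting all mismatches.

## Pipeline and CLI

Every stage reads and writes plain files (MEDLINE text, SIF + sidecar,
JSON, CSV) and no hidden state, so any stage can be rerun independently —
in particular the recode-and-re-run loop. A run writes a manifest with a
config hash and per-stage counts; reruns under the same config and inputs
produce identical manifests. Corpus files are MEDLINE text with a JSON
sidecar for provenance, which the format itself cannot carry.

## Verification scale and limitations

The test suite's oracle sweeps use exhaustive random-graph batches at ≤ 8
nodes, closed forms to 1000 nodes, corpora of ≤ 20 documents for builder
equivalence, and 50 generator seeds for end-to-end recovery; these sizes
make the full suite run in a few seconds while covering every code path.
The published-network re-analysis in the acceptance tests requires the
originally deposited Cytoscape network file, which is not
redistributable here; the check runs whenever an exported edge table is
placed under `data/deposited/`. Known limitations: no MeSH ontology
expansion (terms are literal labels), no weighted clustering variants or
betweenness/eigenvector centrality, no live NCBI querying (the toolkit
consumes exported files), and no automatic emergent-code induction.
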