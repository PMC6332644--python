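# meshnet

Semantic-network and content-coding analysis of biomedical literature
corpora, built for qualitative health-policy research that starts from a
PubMed/MEDLINE search.

Studies of how a topic (for example, the institutionalisation of bioethics
committees and their role in public health policy) is represented in the
published literature often proceed in three stages: assemble a documental
corpus from several PubMed queries; map the conceptual structure of that
corpus as a network of co-occurring MeSH index terms; and close-read the
texts under a codebook of analytic categories. `meshnet` implements that
workflow as a reproducible toolkit:

- **Corpus assembly** — parse MEDLINE plain-text exports (`PMID-`, `TI -`,
  `AB -`, `MH -` tagged fields, including descriptor/qualifier/major-topic
  structure of MeSH headings), merge several query result sets, and
  deduplicate by PMID with full provenance accounting.
- **Semantic network** — build the MeSH co-occurrence graph: nodes are
  rendered term labels, an edge joins two terms whenever a document carries
  both, with weight `w(u,v) = |{d : u,v ∈ MeSH(d)}|` and the supporting
  PMIDs stored per edge. Read/write SIF (+ attribute sidecar), GraphML and
  edge-list CSV.
- **Connectivity statistics** — density, average neighbors `2E/N`, average
  local clustering `C̄ = mean_i C_i` with
  `C_i = 2·t_i / (k_i(k_i−1))`, and Freeman degree centralization
  `C = Σ_i (d_max − d_i) / ((N−1)(N−2))` (1 for a star, 0 for any regular
  graph), plus degree tables, hubs and components.
- **Ego subnetworks** — first-neighbor (induced) subnetworks around seed
  terms, re-analysed with the same statistics and compared side by side.
- **Content coding** — a deterministic codebook engine standing in for
  interactive CAQDAS coding: ordered category columns with
  pattern-matched codes, document-level assignment over title/abstract,
  code frequencies, a-priori → emergent recoding with diffs, and
  long-format alluvial flow tables where the flow `l → r` between adjacent
  columns counts documents coded with both.
- **Synthetic corpora** — a seeded generator of MEDLINE-format fixtures
  with known ground truth (duplicate counts, exact edge weights, planted
  keyword assignments), so the whole pipeline is testable offline.

## Worked example

Generate a five-query synthetic retrieval (sizes 4/18/42/433/666 with
cross-query overlap), then run the pipeline from the shell:

```bash
python -c "from meshnet import GeneratorSpec, generate; \
           generate(GeneratorSpec(seed=42), outdir='queries')"
meshnet merge queries/*.medline --out corpus.medline
# 770 unique records (393 duplicates removed)
meshnet build-net corpus.medline --out net.sif
# 681 nodes, 21850 edges -> net.sif
meshnet stats net.sif --report stats.json
meshnet subnet net.sif --seed "Government Regulation" --out gr.sif --report gr.json
# seed 'Government Regulation': 472 nodes, 15917 edges
```

`stats` prints:

```json
{
  "n_nodes": 681,
  "n_edges": 21850,
  "density": 0.094,
  "avg_neighbors": 64.17,
  "avg_clustering": 0.593,
  "avg_clustering_deg2": 0.593,
  "centralization": 0.908,
  "n_components": 1
}
```

Read: 770 documents index 681 distinct MeSH labels; each concept
co-occurs with 64 others on average; clustering 0.59 means most neighbor
pairs of a term also co-occur with each other; centralization 0.91 says a
handful of hubs (here `Humans`, `United States`, `Advisory Committees`)
dominate the connectivity — the topology typical of indexing vocabularies,
where a few check-tag-like terms attach to most documents. The ego
subnetwork around `Government Regulation` keeps the seed, its 471
neighbors and every edge among them.

Content coding uses a YAML codebook (see `examples/codebook_a_priori.yaml`
for a six-column protocol and `examples/codebook_emergent.yaml` for a
remodelled four-column one; their match patterns are illustrative):

```bash
meshnet code corpus.medline --codebook examples/codebook_a_priori.yaml --out coding.json
meshnet flows coding.json --columns "Political discourse,Symbolic role" --out flows.csv
meshnet recode coding.json corpus.medline \
    --codebook examples/codebook_emergent.yaml --out recoded.json --diff diff.json
```

`flows.csv` is a long-format `(step, source, target, value)` table readable
by alluvial-diagram tools. The full pipeline can also run from one YAML
config: `meshnet run pipeline.yaml`.

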