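"""Deterministic synthetic MEDLINE corpora with known ground truth.

The generator emulates the shape of a multi-query PubMed retrieval on a
policy/bioethics topic: several query result files in MEDLINE format,
overlapping through cross-query duplicates, each record carrying PMID,
title, abstract, publication date, affiliation, country, and MH lines
with descriptor/qualifier/major-topic structure.  Its defaults mirror a
five-query retrieval of sizes 4/18/42/433/666 with 393 cross-query
collisions, collapsing to 770 unique records.

Alongside the files it returns a :class:`GroundTruth` carrying every
recoverable quantity — unique/duplicate counts, the exact co-occurrence
edge weights implied by the generated headings, and the document set of
each planted codebook keyword — so the whole pipeline can be verified
end to end without any download.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from .coding import Codebook, Category, Code, CodePattern, apply_codebook
from .medline import MedlineRecord, parse_medline, parse_mesh_heading, merge_and_dedupe, write_medline
from .network import NetworkBuildConfig, build_cooccurrence_network, render_heading
from .stats import full_report

# A MeSH-like vocabulary (raw MH syntax: "/" qualifiers, "*" major topics)
# centered on bioethics-committee / health-policy literature.
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "Humans",
    "United States",
    "Advisory Committees",
    "Public Policy",
    "*Public Policy",
    "Government Regulation",
    "Social Control, Formal",
    "Bioethical Issues",
    "*Bioethical Issues",
    "Ethics, Medical/*education",
    "Ethics, Medical",
    "Institutionalization/ethics",
    "Ethics Committees",
    "Ethics Committees, Research",
    "Ethics Committees, Clinical",
    "Federal Government",
    "Bioethics",
    "Risk Assessment",
    "Informed Consent",
    "Social Values",
    "Health Policy",
    "Public Health",
    "Policy Making",
    "Government Agencies",
    "*Government Agencies",
    "Decision Making",
    "Morals",
    "Social Responsibility",
    "Politics",
    "Legislation, Medical",
    "Jurisprudence",
    "Human Experimentation",
    "Research Ethics",
    "Biomedical Research/ethics",
    "Delivery of Health Care",
    "Health Services/*standards",
    "Safety/*standards",
    "Organizational Culture",
    "Community Participation",
    "Education, Medical",
    "International Cooperation",
    "Democracy",
)

# The default vocabulary is widened far beyond the curated core the way a
# real corpus is: a few hundred plausible descriptor labels plus qualified
# variants ("Descriptor/qualifier"), so that several hundred records yield
# a sparse graph with genuine hubs rather than a near-complete one.
_QUALIFIERS = (
    "ethics", "economics", "history", "legislation & jurisprudence",
    "organization & administration", "standards", "trends",
)
_MODIFIERS = (
    "Health", "Ethics", "Policy", "Community", "Institutional", "Clinical",
    "Research", "Social", "Public", "Professional", "Regulatory", "Legal",
    "Medical", "Hospital", "National", "International", "Governmental",
    "Academic", "Patient", "Population",
)
_HEADS = (
    "Committees", "Consultation", "Review", "Oversight", "Guidelines",
    "Standards", "Education", "Participation", "Governance",
    "Accountability", "Legislation", "Deliberation", "Advocacy",
    "Administration", "Evaluation", "Priorities", "Trust",
    "Responsibility", "Autonomy", "Justice",
)
_GENERATED = tuple(f"{m} {h}" for m in _MODIFIERS for h in _HEADS)
DEFAULT_VOCABULARY = (
    DEFAULT_VOCABULARY
    + tuple(
        f"{d}/{q}"
        for i, d in enumerate(DEFAULT_VOCABULARY)
        if "/" not in d and not d.startswith("*")
        for j, q in enumerate(_QUALIFIERS)
        if (i + j) % 2 == 0  # a deterministic half of the combinations
    )
    + _GENERATED
    + tuple(
        f"{d}/{_QUALIFIERS[i % len(_QUALIFIERS)]}"
        for i, d in enumerate(_GENERATED)
        if i % 3 == 0
    )
)

# Planted term communities: headings within one group co-occur more often,
# giving the network a clustered, hub-dominated structure.
DEFAULT_COMMUNITIES: tuple[tuple[str, ...], ...] = (
    (
        "Humans", "United States", "Advisory Committees", "Public Policy",
        "Government Regulation", "Federal Government", "Policy Making",
        "Health Policy", "Politics",
    ),
    (
        "Bioethical Issues", "*Bioethical Issues", "Ethics, Medical",
        "Bioethics", "Morals", "Ethics Committees", "Research Ethics",
        "Human Experimentation", "Informed Consent",
    ),
    (
        "Social Control, Formal", "Social Values", "Social Responsibility",
        "Community Participation", "Democracy", "Jurisprudence",
        "Legislation, Medical",
    ),
)

# The five retrieval queries whose result sizes the defaults emulate.
DEFAULT_QUERY_LABELS: tuple[str, ...] = (
    "Institutionalization of bioethics and public health policy",
    "Institutionalization of bioethics and public health",
    "Institutionalization of bioethics",
    "Bioethics committees and public health policy",
    "Bioethics committees and public policy",
)

_COUNTRIES = ("United States", "England", "Mexico", "Canada", "Spain", "France")


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic retrieval.

    ``duplicates_per_query`` pins the exact number of records in each
    query file that re-emit a record already produced by an earlier query;
    when None, per-query counts are derived from ``duplicate_rate``.
    """

    n_queries: int = 5
    records_per_query: tuple[int, ...] = (4, 18, 42, 433, 666)
    duplicate_rate: float = 393 / 1163
    duplicates_per_query: tuple[int, ...] | None = (0, 2, 6, 50, 335)
    query_labels: tuple[str, ...] = DEFAULT_QUERY_LABELS
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    headings_per_record: tuple[int, int] = (5, 15)
    term_communities: tuple[tuple[str, ...], ...] = DEFAULT_COMMUNITIES
    community_boost: float = 3.0
    planted_keywords: dict[str, str] = field(default_factory=dict)
    planted_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.records_per_query) != self.n_queries:
            raise ValueError("records_per_query must have length n_queries")
        if len(self.query_labels) != self.n_queries:
            raise ValueError("query_labels must have length n_queries")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if self.headings_per_record[1] > len(self.vocabulary):
            raise ValueError(
                "vocabulary smaller than headings_per_record maximum"
            )
        if self.duplicates_per_query is not None:
            if len(self.duplicates_per_query) != self.n_queries:
                raise ValueError("duplicates_per_query must have length n_queries")

    def resolved_duplicates(self) -> list[int]:
        """Per-query duplicate counts, checked against the cumulative pool
        of earlier unique records."""
        if self.duplicates_per_query is not None:
            dups = list(self.duplicates_per_query)
        else:
            dups = [round(self.duplicate_rate * n) for n in self.records_per_query]
            dups[0] = 0
        pool = 0
        for i, (n, d) in enumerate(zip(self.records_per_query, dups)):
            if d > min(pool, n):
                raise ValueError(
                    f"query {i}: {d} duplicates infeasible (pool {pool}, size {n})"
                )
            pool += n - d
        return dups


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from the generated files."""

    n_unique: int
    n_duplicates: int
    per_query_retrieved: dict[str, int]
    edge_weights: dict[tuple[str, str], int]
    node_doc_counts: dict[str, int]
    code_docs: dict[str, set[str]]
    planted_keywords: dict[str, str]
    build_config: NetworkBuildConfig


class _HeadingSampler:
    """Zipf-skewed heading sampler with per-community boosted weights.

    Term popularity follows rank^-0.8 over the vocabulary order (curated
    core terms first), so early terms become hubs; picking a community per
    record multiplies its members' weights by the boost factor, planting
    clustered co-occurrence structure.
    """

    ZIPF_EXPONENT = 0.8

    def __init__(self, spec: "GeneratorSpec") -> None:
        from itertools import accumulate

        self.vocab = list(spec.vocabulary)
        base = [1.0 / (i + 1) ** self.ZIPF_EXPONENT for i in range(len(self.vocab))]
        idx = {v: i for i, v in enumerate(self.vocab)}
        self.cum_weights: list[list[float]] = []
        for group in spec.term_communities or ((),):
            w = base[:]
            for term in group:
                if term in idx:
                    w[idx[term]] *= spec.community_boost
            self.cum_weights.append(list(accumulate(w)))

    def sample(self, rng: random.Random, k: int) -> list[str]:
        cw = self.cum_weights[rng.randrange(len(self.cum_weights))]
        chosen: list[str] = []
        seen: set[str] = set()
        while len(chosen) < k:
            for v in rng.choices(self.vocab, cum_weights=cw, k=k):
                if v not in seen:
                    seen.add(v)
                    chosen.append(v)
                    if len(chosen) == k:
                        break
        return chosen


def _make_record(
    rng: random.Random, pmid: int, spec: GeneratorSpec, sampler: _HeadingSampler
) -> MedlineRecord:
    k = rng.randint(*spec.headings_per_record)
    raw_headings = sampler.sample(rng, k)
    # "Humans" behaves like a MEDLINE check tag: indexed on nearly every
    # citation, so it emerges as the dominant hub of the network.
    if "Humans" in sampler.vocab and "Humans" not in raw_headings and rng.random() < 0.9:
        raw_headings.insert(0, "Humans")
    headings = [parse_mesh_heading(v) for v in raw_headings]
    lead = headings[0].descriptor
    second = headings[1].descriptor if len(headings) > 1 else "health policy"
    title = f"Synthetic report {pmid}: {lead} in the context of {second}"
    abstract = (
        f"Synthetic abstract for record {pmid}. This study considers {lead} "
        f"alongside {second} within institutional bioethics and public "
        f"health policy. Additional indexed concepts include "
        f"{', '.join(h.descriptor for h in headings[2:5]) or 'none'}."
    )
    for code_name in sorted(spec.planted_keywords):
        if rng.random() < spec.planted_rate:
            abstract += f" Keyword marker: {spec.planted_keywords[code_name]}."
    year = rng.randint(1990, 2017)
    country = rng.choice(_COUNTRIES)
    return MedlineRecord(
        pmid=str(pmid),
        title=title,
        abstract=abstract,
        headings=headings,
        pub_date=f"{year} {rng.choice(('Jan', 'Apr', 'Jul', 'Oct'))}",
        affiliations=[f"Synthetic Institute of Policy Studies, {country}."],
        country=country,
    )


def _brute_force_weights(
    records: list[MedlineRecord], config: NetworkBuildConfig
) -> tuple[dict[tuple[str, str], int], dict[str, int]]:
    weights: dict[tuple[str, str], int] = {}
    doc_counts: dict[str, int] = {}
    for r in records:
        labels = set()
        for h in r.headings:
            labels.update(render_heading(h, config))
        for lab in labels:
            doc_counts[lab] = doc_counts.get(lab, 0) + 1
        for a, b in combinations(sorted(labels), 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    return weights, doc_counts


def generate(
    spec: GeneratorSpec, outdir: str | Path | None = None
) -> tuple[dict[str, str], GroundTruth]:
    """Generate one MEDLINE text per query plus the ground truth.

    Duplicates are realised by re-emitting earlier unique records into
    later query files, mirroring real cross-query overlap.  A fixed seed
    yields byte-identical files.
    """
    dups = spec.resolved_duplicates()
    rng = random.Random(spec.seed)
    sampler = _HeadingSampler(spec)
    n_unique = sum(spec.records_per_query) - sum(dups)
    pmids = rng.sample(range(10_000_000, 39_999_999), n_unique)
    unique_records: list[MedlineRecord] = []
    files: dict[str, str] = {}
    per_query: dict[str, int] = {}
    next_new = 0
    for label, n, d in zip(spec.query_labels, spec.records_per_query, dups):
        reemitted = rng.sample(unique_records, d) if d else []
        fresh = []
        for _ in range(n - d):
            fresh.append(_make_record(rng, pmids[next_new], spec, sampler))
            next_new += 1
        unique_records.extend(fresh)
        query_records = reemitted + fresh
        rng.shuffle(query_records)
        files[label] = write_medline(query_records)
        per_query[label] = n
    config = NetworkBuildConfig()
    edge_weights, node_doc_counts = _brute_force_weights(unique_records, config)
    code_docs = {
        code: {
            r.pmid
            for r in unique_records
            if keyword.lower() in f"{r.title} {r.abstract}".lower()
        }
        for code, keyword in spec.planted_keywords.items()
    }
    truth = GroundTruth(
        n_unique=n_unique,
        n_duplicates=sum(dups),
        per_query_retrieved=per_query,
        edge_weights=edge_weights,
        node_doc_counts=node_doc_counts,
        code_docs=code_docs,
        planted_keywords=dict(spec.planted_keywords),
        build_config=config,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, (label, text) in enumerate(files.items(), start=1):
            (outdir / f"query{i}.medline").write_text(text)
    return files, truth


def keywords_codebook(planted_keywords: dict[str, str]) -> Codebook:
    """One-column codebook matching the planted keywords literally."""
    codes = tuple(
        Code(name=code, patterns=(CodePattern(kw, is_regex=False),))
        for code, kw in sorted(planted_keywords.items())
    )
    return Codebook(
        columns=(Category(name="Planted", codes=codes),),
        version_label="planted-keywords",
    )


def ground_truth_check(files: dict[str, str], truth: GroundTruth) -> dict:
    """Run the full pipeline on generated files and compare every
    recoverable quantity with the ground truth.

    Returns a report with a ``passed`` flag and a list of mismatches.
    """
    mismatches: list[str] = []
    record_lists = [
        (label, parse_medline(text, label)) for label, text in files.items()
    ]
    corpus = merge_and_dedupe(record_lists)
    if len(corpus.records) != truth.n_unique:
        mismatches.append(
            f"unique records: pipeline {len(corpus.records)}, truth {truth.n_unique}"
        )
    if corpus.n_duplicates_removed != truth.n_duplicates:
        mismatches.append(
            f"duplicates: pipeline {corpus.n_duplicates_removed}, "
            f"truth {truth.n_duplicates}"
        )
    if corpus.provenance != truth.per_query_retrieved:
        mismatches.append("per-query retrieved counts differ")
    net = build_cooccurrence_network(corpus, truth.build_config)
    got_weights = {
        tuple(sorted((u, v))): d["weight"]
        for u, v, d in net.graph.edges(data=True)
    }
    if got_weights != truth.edge_weights:
        mismatches.append(
            f"edge weights differ ({len(got_weights)} built vs "
            f"{len(truth.edge_weights)} expected)"
        )
    got_counts = dict(net.graph.nodes(data="doc_count"))
    expected_counts = {
        n: c for n, c in truth.node_doc_counts.items() if n in got_counts
    }
    if got_counts != expected_counts:
        mismatches.append("node document counts differ")
    report_stats = full_report(net).to_dict() if net.n_nodes else {}
    if truth.planted_keywords:
        cb = keywords_codebook(truth.planted_keywords)
        result = apply_codebook(corpus, cb, fields=("title", "abstract"))
        for code, expected in sorted(truth.code_docs.items()):
            got = {
                pmid
                for pmid, cats in result.assignments.items()
                if code in cats.get("Planted", ())
            }
            if got != expected:
                mismatches.append(
                    f"code {code!r}: {len(got)} docs coded, expected {len(expected)}"
                )
    return {
        "passed": not mismatches,
        "mismatches": mismatches,
        "n_records": len(corpus.records),
        "network_stats": report_stats,
    }
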