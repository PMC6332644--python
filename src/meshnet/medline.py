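"""Parsing, merging and deduplication of MEDLINE plain-text exports.

PubMed's "MEDLINE format" is a tagged flat-file layout: each field starts
with a tag of up to four characters, padded with spaces, followed by ``- ``
and the value; continuation lines are indented; citations are separated by
blank lines.  MeSH heading (``MH``) values carry additional structure:
``Descriptor/qualifier1/qualifier2`` with a leading ``*`` marking a
major-topic descriptor or qualifier, e.g. ``Ethics, Medical/*education``.

This module parses that layout into :class:`MedlineRecord` objects, merges
result sets from several queries into a deduplicated :class:`Corpus`, and
writes records back out so corpora can round-trip through files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

# Tag line: 2-4 char uppercase/digit tag, optional padding, "- ", value.
# Padding is tolerant because export dialects differ across PubMed eras.
_TAG_RE = re.compile(r"^([A-Z][A-Z0-9]{1,3})\s{0,3}- (.*)$")


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH heading: descriptor, ordered qualifiers, major-topic flags.

    The ``*`` star notation of the raw format is parsed into the boolean
    flags; no star character remains inside the labels themselves.
    """

    descriptor: str
    qualifiers: tuple[str, ...] = ()
    descriptor_major: bool = False
    qualifier_major: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not self.descriptor.strip():
            raise ValueError("MeshHeading descriptor must be non-empty")
        if "*" in self.descriptor or any("*" in q for q in self.qualifiers):
            raise ValueError("star markers must be parsed into flags, not labels")
        if len(self.qualifier_major) != len(self.qualifiers):
            raise ValueError("qualifier_major must align with qualifiers")


@dataclass
class MedlineRecord:
    """A single parsed MEDLINE citation."""

    pmid: str
    title: str = ""
    abstract: str = ""
    headings: list[MeshHeading] = field(default_factory=list)
    pub_date: str = ""
    affiliations: list[str] = field(default_factory=list)
    country: str = ""
    source_query: str = ""

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise ValueError(f"pmid must be numeric and non-empty, got {self.pmid!r}")


@dataclass
class Corpus:
    """Deduplicated record collection with per-query provenance."""

    records: list[MedlineRecord]
    provenance: dict[str, int]
    n_duplicates_removed: int

    def __post_init__(self) -> None:
        pmids = [r.pmid for r in self.records]
        if len(pmids) != len(set(pmids)):
            raise ValueError("corpus contains duplicate PMIDs")
        expected = sum(self.provenance.values()) - len(self.records)
        if self.n_duplicates_removed != expected:
            raise ValueError(
                f"n_duplicates_removed={self.n_duplicates_removed} inconsistent "
                f"with provenance (expected {expected})"
            )


def parse_mesh_heading(value: str) -> MeshHeading:
    """Parse one MH field value, e.g. ``Ethics, Medical/*education``."""
    parts = [p.strip() for p in value.split("/")]
    desc = parts[0]
    desc_major = desc.startswith("*")
    if desc_major:
        desc = desc[1:].strip()
    quals: list[str] = []
    qmajor: list[bool] = []
    for q in parts[1:]:
        if not q:
            continue
        major = q.startswith("*")
        if major:
            q = q[1:].strip()
        quals.append(q)
        qmajor.append(major)
    return MeshHeading(desc, tuple(quals), desc_major, tuple(qmajor))


def _decode(text: str | bytes) -> str:
    if isinstance(text, bytes):
        try:
            return text.decode("utf-8")
        except UnicodeDecodeError:
            logger.warning("invalid UTF-8 bytes in input replaced")
            return text.decode("utf-8", errors="replace")
    return text


def _split_blocks(text: str) -> list[list[str]]:
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "":
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(line)
    if current:
        blocks.append(current)
    return blocks


def _parse_block(lines: list[str]) -> dict[str, list[str]] | None:
    """Collect tag -> list of values, joining continuation lines with one space."""
    fields: dict[str, list[str]] = {}
    tag: str | None = None
    for line in lines:
        m = _TAG_RE.match(line)
        if m:
            tag = m.group(1)
            fields.setdefault(tag, []).append(m.group(2))
        elif line.startswith((" ", "\t")) and tag is not None:
            fields[tag][-1] += " " + line.strip()
        else:
            logger.warning("ignoring malformed line in MEDLINE block: %r", line)
    return fields or None


def parse_medline(text: str | bytes, query_label: str = "") -> list[MedlineRecord]:
    """Parse raw MEDLINE-format text into records.

    Blocks without a PMID tag are skipped with a warning; malformed lines
    inside a block are ignored with a warning.
    """
    records: list[MedlineRecord] = []
    for lines in _split_blocks(_decode(text)):
        fields = _parse_block(lines)
        if fields is None:
            continue
        pmids = fields.get("PMID")
        if not pmids:
            logger.warning("skipping block without PMID (starts: %r)", lines[0])
            continue
        headings = [parse_mesh_heading(v) for v in fields.get("MH", [])]
        records.append(
            MedlineRecord(
                pmid=pmids[0].strip(),
                title=fields.get("TI", [""])[0],
                abstract=fields.get("AB", [""])[0],
                headings=headings,
                pub_date=fields.get("DP", [""])[0],
                affiliations=fields.get("AD", []),
                country=fields.get("PL", [""])[0],
                source_query=query_label,
            )
        )
    return records


def format_mesh_heading(h: MeshHeading) -> str:
    """Render a heading back to raw MH syntax (stars re-attached)."""
    parts = [("*" if h.descriptor_major else "") + h.descriptor]
    for q, major in zip(h.qualifiers, h.qualifier_major):
        parts.append(("*" if major else "") + q)
    return "/".join(parts)


def write_medline(records: list[MedlineRecord]) -> str:
    """Serialize records to MEDLINE format (long values are not wrapped)."""
    out: list[str] = []
    for r in records:
        lines = [f"PMID- {r.pmid}"]
        if r.pub_date:
            lines.append(f"DP  - {r.pub_date}")
        if r.title:
            lines.append(f"TI  - {r.title}")
        if r.abstract:
            lines.append(f"AB  - {r.abstract}")
        for ad in r.affiliations:
            lines.append(f"AD  - {ad}")
        if r.country:
            lines.append(f"PL  - {r.country}")
        for h in r.headings:
            lines.append(f"MH  - {format_mesh_heading(h)}")
        out.append("\n".join(lines))
    return "\n\n".join(out) + ("\n" if out else "")


def merge_and_dedupe(
    record_lists: list[tuple[str, list[MedlineRecord]]],
) -> Corpus:
    """Merge per-query record lists, collapsing duplicate PMIDs.

    The first occurrence (in input order) wins and keeps its source_query;
    a colliding record with a differing title is logged.
    """
    seen: dict[str, MedlineRecord] = {}
    provenance: dict[str, int] = {}
    for label, records in record_lists:
        provenance[label] = provenance.get(label, 0) + len(records)
        for r in records:
            if r.pmid in seen:
                if r.title != seen[r.pmid].title:
                    logger.warning(
                        "PMID %s duplicated with differing titles (%r vs %r)",
                        r.pmid, seen[r.pmid].title, r.title,
                    )
                continue
            seen[r.pmid] = r
    records = list(seen.values())
    n_dup = sum(provenance.values()) - len(records)
    return Corpus(records=records, provenance=provenance, n_duplicates_removed=n_dup)


def corpus_summary(corpus: Corpus) -> dict:
    """Summary counts: per-query retrieved, unique, duplicates, empty
    abstracts, and the distinct rendered-MeSH vocabulary size."""
    vocab = {format_mesh_heading(h) for r in corpus.records for h in r.headings}
    return {
        "per_query_retrieved": dict(corpus.provenance),
        "total_retrieved": sum(corpus.provenance.values()),
        "unique_records": len(corpus.records),
        "duplicates_removed": corpus.n_duplicates_removed,
        "records_without_abstract": sum(1 for r in corpus.records if not r.abstract),
        "mesh_vocabulary_size": len(vocab),
    }
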