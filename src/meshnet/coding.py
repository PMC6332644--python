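"""Codebook-driven content coding and alluvial flow tables.

A codebook is an ordered list of analytic category columns, each holding
codes with case-insensitive match patterns (literals or regular
expressions).  Applying it to a corpus assigns codes at the document
level: a code attaches to a document when any of its patterns matches the
concatenated selected fields (title and/or abstract); no stemming, pure
text matching.  Matched spans are kept for audit but play no role in
counts.  This realizes the deductive (a-priori) pass of a combined
deductive/inductive coding strategy; the inductive step — a human
revising the codebook — is supported by :func:`recode`, which re-applies
a new codebook and reports the diff.

Flow magnitudes between adjacent category columns count document-level
code pair combinations: a document holding 2 codes in the left column and
2 in the right contributes 4, the way long-format alluvial inputs are
usually built.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .medline import Corpus

CODING_FIELDS = ("title", "abstract")


@dataclass(frozen=True)
class CodePattern:
    text: str
    is_regex: bool = False

    def compile(self) -> re.Pattern:
        pattern = self.text if self.is_regex else re.escape(self.text)
        try:
            return re.compile(pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(
                f"invalid regular expression {self.text!r} at position "
                f"{exc.pos}: {exc.msg}"
            ) from exc


@dataclass(frozen=True)
class Code:
    name: str
    patterns: tuple[CodePattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"code {self.name!r} has no patterns")


@dataclass(frozen=True)
class Category:
    name: str
    codes: tuple[Code, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.codes]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate code names in category {self.name!r}")


@dataclass(frozen=True)
class Codebook:
    columns: tuple[Category, ...]
    version_label: str = ""

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("codebook has no category columns")
        names = [c.name for c in self.columns]
        if len(names) != len(set(names)):
            raise ValueError("duplicate category column names")

    def column(self, name: str) -> Category:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(f"unknown category column {name!r}")


@dataclass
class MatchSpan:
    """Audit record of one pattern hit: where and what matched."""

    category: str
    code: str
    start: int
    end: int
    text: str


@dataclass
class CodingResult:
    """Per-document code assignments: pmid -> category -> set of codes.

    Every codebook category appears for every document, empty when no code
    of that category matched.
    """

    assignments: dict[str, dict[str, set[str]]]
    codebook_version: str = ""
    # full (category, code) universe of the codebook that produced this
    # result, so a later recode can diff codes that never matched anything
    codebook_codes: frozenset[tuple[str, str]] = frozenset()
    spans: dict[str, list[MatchSpan]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "codebook_version": self.codebook_version,
            "codebook_codes": sorted(list(p) for p in self.codebook_codes),
            "assignments": {
                pmid: {cat: sorted(codes) for cat, codes in cats.items()}
                for pmid, cats in self.assignments.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CodingResult":
        payload = json.loads(text)
        return cls(
            assignments={
                pmid: {cat: set(codes) for cat, codes in cats.items()}
                for pmid, cats in payload["assignments"].items()
            },
            codebook_version=payload.get("codebook_version", ""),
            codebook_codes=frozenset(
                (cat, code) for cat, code in payload.get("codebook_codes", [])
            ),
        )


@dataclass
class AlluvialTable:
    """Flows between codes of adjacent category columns.

    ``flows[(left_col, right_col)]`` is a list of (left code, right code,
    magnitude) triples, magnitude > 0, sorted by left then right code.
    """

    column_order: list[str]
    flows: dict[tuple[str, str], list[tuple[str, str, int]]]

    def to_long_csv(self) -> str:
        """Long-format CSV (step, source, target, value) for alluvial tools."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["step", "source", "target", "value"])
        for step, (left_col, right_col) in enumerate(
            zip(self.column_order, self.column_order[1:])
        ):
            for left, right, mag in self.flows[(left_col, right_col)]:
                w.writerow([step, left, right, mag])
        return buf.getvalue()


def _parse_patterns(raw: list) -> tuple[CodePattern, ...]:
    patterns = []
    for item in raw:
        if isinstance(item, str):
            patterns.append(CodePattern(item, is_regex=False))
        elif isinstance(item, dict) and len(item) == 1:
            ((kind, text),) = item.items()
            if kind not in ("literal", "regex"):
                raise ValueError(f"pattern kind must be literal or regex, got {kind!r}")
            patterns.append(CodePattern(str(text), is_regex=kind == "regex"))
        else:
            raise ValueError(f"malformed pattern entry {item!r}")
    return tuple(patterns)


def load_codebook(source: str | Path) -> Codebook:
    """Load a codebook from YAML/JSON text or a file path.

    Schema: ``version`` (optional) and ``columns``, each column a mapping
    with ``name`` and ``codes``, each code a mapping with ``name`` and
    ``patterns`` (strings are literals; one-key mappings ``literal:`` /
    ``regex:`` select the kind).  Every pattern is compiled at load time so
    an invalid regex fails here, with its text and position.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
    ):
        text = Path(source).read_text()
    else:
        text = source
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or not doc.get("columns"):
        raise ValueError("codebook must define a non-empty 'columns' list")
    columns = []
    for col in doc["columns"]:
        codes = tuple(
            Code(name=str(c["name"]), patterns=_parse_patterns(c["patterns"]))
            for c in col.get("codes", [])
        )
        columns.append(Category(name=str(col["name"]), codes=codes))
    cb = Codebook(columns=tuple(columns), version_label=str(doc.get("version", "")))
    for cat in cb.columns:
        for code in cat.codes:
            for p in code.patterns:
                p.compile()
    return cb


def apply_codebook(
    corpus: Corpus,
    cb: Codebook,
    fields: tuple[str, ...] = ("title", "abstract"),
) -> CodingResult:
    """Deductive pass: tag every document with every code whose pattern
    matches its selected text fields (case-insensitive)."""
    unknown = set(fields) - set(CODING_FIELDS)
    if unknown:
        raise ValueError(f"unknown coding fields {sorted(unknown)}")
    compiled = [
        (cat.name, code.name, [p.compile() for p in code.patterns])
        for cat in cb.columns
        for code in cat.codes
    ]
    assignments: dict[str, dict[str, set[str]]] = {}
    spans: dict[str, list[MatchSpan]] = {}
    for record in corpus.records:
        text = " ".join(getattr(record, f) for f in fields)
        doc = {cat.name: set() for cat in cb.columns}
        doc_spans: list[MatchSpan] = []
        for cat_name, code_name, patterns in compiled:
            for pat in patterns:
                m = pat.search(text)
                if m:
                    doc[cat_name].add(code_name)
                    doc_spans.append(
                        MatchSpan(cat_name, code_name, m.start(), m.end(), m.group())
                    )
        assignments[record.pmid] = doc
        if doc_spans:
            spans[record.pmid] = doc_spans
    return CodingResult(
        assignments=assignments,
        codebook_version=cb.version_label,
        codebook_codes=frozenset(
            (cat.name, code.name) for cat in cb.columns for code in cat.codes
        ),
        spans=spans,
    )


def code_frequencies(result: CodingResult, cb: Codebook):
    """Document counts per (category, code); zero-count codes included."""
    import pandas as pd

    rows = []
    for cat in cb.columns:
        for code in cat.codes:
            n = sum(
                1
                for cats in result.assignments.values()
                if code.name in cats.get(cat.name, ())
            )
            rows.append({"category": cat.name, "code": code.name, "n_documents": n})
    return pd.DataFrame(rows)


def category_flows(result: CodingResult, column_order: list[str]) -> AlluvialTable:
    """Flows between adjacent columns: magnitude of (l, r) = number of
    documents coded both l in the left column and r in the right.  Zero
    flows are omitted; output order is deterministic."""
    known = set()
    for cats in result.assignments.values():
        known.update(cats)
    unknown = [c for c in column_order if c not in known]
    if unknown and result.assignments:
        raise KeyError(f"unknown category column(s) {unknown}")
    flows: dict[tuple[str, str], list[tuple[str, str, int]]] = {}
    for left_col, right_col in zip(column_order, column_order[1:]):
        counts: dict[tuple[str, str], int] = {}
        for cats in result.assignments.values():
            for left in cats.get(left_col, ()):
                for right in cats.get(right_col, ()):
                    counts[(left, right)] = counts.get((left, right), 0) + 1
        flows[(left_col, right_col)] = [
            (left, right, n) for (left, right), n in sorted(counts.items())
        ]
    return AlluvialTable(column_order=list(column_order), flows=flows)


def recode(
    result_old: CodingResult,
    cb_new: Codebook,
    corpus: Corpus,
    fields: tuple[str, ...] = ("title", "abstract"),
) -> tuple[CodingResult, dict]:
    """Re-apply a revised codebook and report what changed.

    The diff lists categories and codes added/removed and, per document,
    the (category, code) assignments gained and lost.
    """
    result_new = apply_codebook(corpus, cb_new, fields)
    old_codes = set(result_old.codebook_codes)
    old_cats = {cat for cat, _ in old_codes}
    for cats in result_old.assignments.values():
        for cat, codes in cats.items():
            old_cats.add(cat)
            old_codes.update((cat, c) for c in codes)
    new_cats = {c.name for c in cb_new.columns}
    new_codes = {(cat.name, code.name) for cat in cb_new.columns for code in cat.codes}

    def _pairs(result: CodingResult, pmid: str) -> set[tuple[str, str]]:
        return {
            (cat, code)
            for cat, codes in result.assignments.get(pmid, {}).items()
            for code in codes
        }

    doc_changes = {}
    for pmid in sorted(set(result_old.assignments) | set(result_new.assignments)):
        gained = _pairs(result_new, pmid) - _pairs(result_old, pmid)
        lost = _pairs(result_old, pmid) - _pairs(result_new, pmid)
        if gained or lost:
            doc_changes[pmid] = {
                "gained": sorted(gained),
                "lost": sorted(lost),
            }
    diff = {
        "categories_added": sorted(new_cats - old_cats),
        "categories_removed": sorted(old_cats - new_cats),
        "codes_added": sorted(new_codes - old_codes),
        "codes_removed": sorted(old_codes - new_codes),
        "documents_changed": doc_changes,
    }
    return result_new, diff
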