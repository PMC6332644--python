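"""Codebook loading, document coding, frequencies, flows and recoding."""

import re
from pathlib import Path

import pytest

from meshnet import (
    apply_codebook,
    category_flows,
    code_frequencies,
    load_codebook,
    recode,
)
from meshnet.coding import CodingResult

from conftest import corpus_of

EXAMPLES = Path(__file__).resolve().parents[1] / "examples"

SMALL_CODEBOOK = """
version: test-v1
columns:
  - name: Institutionalisation
    codes:
      - name: Advisory
        patterns:
          - regex: "advisory committee"
      - name: Research ethics
        patterns:
          - literal: research ethics
  - name: Governance
    codes:
      - name: Regulation
        patterns:
          - regex: "regulat(e|ion|ory)"
      - name: Declaration
        patterns:
          - literal: universal declaration
  - name: Symbolic role
    codes:
      - name: Authority
        patterns:
          - literal: authority
      - name: Forum
        patterns:
          - literal: forum
"""


@pytest.fixture
def small_cb():
    return load_codebook(SMALL_CODEBOOK)


def planted_corpus():
    titles = {
        1: "Advisory committees and public policy",
        2: "Research ethics under regulation",
        3: "A forum for moral authority",
        4: "Universal declaration and regulation debates",
        5: "Nothing relevant here",
        6: "Advisory committee regulation forum",
    }
    return corpus_of({p: ["Humans"] for p in titles}, titles=titles)


class TestLoadCodebook:
    def test_six_column_example_file(self):
        cb = load_codebook(EXAMPLES / "codebook_a_priori.yaml")
        assert [c.name for c in cb.columns] == [
            "Forms of institutionalisation",
            "Forms of governance",
            "Institutional structure",
            "Political discourse",
            "Mechanism power",
            "Symbolic role",
        ]
        symbolic = cb.column("Symbolic role")
        assert [c.name for c in symbolic.codes] == [
            "Government elites", "Power elite", "Control mechanism",
            "Intellectual and moral authority", "Discussion forums",
            "Passive actors",
        ]

    def test_minimal_codebook(self):
        cb = load_codebook(
            "columns:\n - name: A\n   codes:\n    - name: c\n      patterns: [kw]\n"
        )
        assert len(cb.columns) == 1
        assert cb.columns[0].codes[0].patterns[0].text == "kw"

    def test_malformed_regex_reported(self):
        bad = (
            "columns:\n - name: A\n   codes:\n  "
            "  - name: c\n      patterns:\n       - regex: '(['\n"
        )
        with pytest.raises(ValueError, match=re.escape("([")):
            load_codebook(bad)

    def test_duplicate_code_names_rejected(self):
        bad = (
            "columns:\n - name: A\n   codes:\n"
            "    - name: c\n      patterns: [x]\n"
            "    - name: c\n      patterns: [y]\n"
        )
        with pytest.raises(ValueError, match="duplicate code"):
            load_codebook(bad)

    def test_empty_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            load_codebook("columns: []\n")


class TestApplyCodebook:
    def test_advisory_committee_example(self, small_cb):
        corpus = planted_corpus()
        result = apply_codebook(corpus, small_cb, fields=("title",))
        assert "Advisory" in result.assignments["1"]["Institutionalisation"]
        # all categories present even when empty
        assert result.assignments["5"] == {
            "Institutionalisation": set(), "Governance": set(), "Symbolic role": set()
        }

    def test_case_insensitive_no_stemming(self, small_cb):
        corpus = corpus_of(
            {1: ["Humans"], 2: ["Humans"]},
            titles={1: "ADVISORY COMMITTEE report", 2: "advising committees"},
        )
        result = apply_codebook(corpus, small_cb, fields=("title",))
        assert "Advisory" in result.assignments["1"]["Institutionalisation"]
        assert result.assignments["2"]["Institutionalisation"] == set()

    def test_matches_bruteforce_pattern_sweep(self, small_cb):
        corpus = planted_corpus()
        result = apply_codebook(corpus, small_cb, fields=("title", "abstract"))
        for record in corpus.records:
            text = f"{record.title} {record.abstract}"
            for cat in small_cb.columns:
                for code in cat.codes:
                    expected = any(
                        re.search(
                            p.text if p.is_regex else re.escape(p.text),
                            text,
                            re.IGNORECASE,
                        )
                        for p in code.patterns
                    )
                    got = code.name in result.assignments[record.pmid][cat.name]
                    assert got == expected, (record.pmid, cat.name, code.name)

    def test_order_independent(self, small_cb):
        corpus = planted_corpus()
        reversed_corpus = corpus_of(
            {int(r.pmid): [] for r in reversed(corpus.records)},
            titles={int(r.pmid): r.title for r in corpus.records},
        )
        a = apply_codebook(corpus, small_cb, fields=("title",))
        b = apply_codebook(reversed_corpus, small_cb, fields=("title",))
        assert a.assignments == b.assignments

    def test_spans_recorded_for_audit(self, small_cb):
        result = apply_codebook(planted_corpus(), small_cb, fields=("title",))
        spans = result.spans["1"]
        assert any(
            s.code == "Advisory" and s.text.lower() == "advisory committee"
            for s in spans
        )

    def test_unknown_field_rejected(self, small_cb):
        with pytest.raises(ValueError, match="unknown coding fields"):
            apply_codebook(planted_corpus(), small_cb, fields=("journal",))

    def test_json_round_trip(self, small_cb):
        result = apply_codebook(planted_corpus(), small_cb, fields=("title",))
        back = CodingResult.from_json(result.to_json())
        assert back.assignments == result.assignments
        assert back.codebook_codes == result.codebook_codes


class TestFrequenciesAndFlows:
    def test_frequencies_hand_counts(self, small_cb):
        result = apply_codebook(planted_corpus(), small_cb, fields=("title",))
        freq = code_frequencies(result, small_cb).set_index("code")["n_documents"]
        assert freq["Advisory"] == 2          # docs 1, 6
        assert freq["Regulation"] == 3        # docs 2, 4, 6
        assert freq["Declaration"] == 1       # doc 4
        assert freq["Forum"] == 2             # docs 3, 6

    def test_zero_count_codes_included(self, small_cb):
        result = apply_codebook(
            corpus_of({9: ["Humans"]}, titles={9: "blank"}), small_cb, ("title",)
        )
        freq = code_frequencies(result, small_cb)
        assert len(freq) == 6
        assert (freq["n_documents"] == 0).all()

    def test_single_column_no_flows(self, small_cb):
        result = apply_codebook(planted_corpus(), small_cb, fields=("title",))
        table = category_flows(result, ["Governance"])
        assert table.flows == {}

    def test_two_docs_one_flow(self, small_cb):
        corpus = corpus_of(
            {1: ["Humans"], 2: ["Humans"]},
            titles={
                1: "advisory committee regulation",
                2: "advisory committee under regulation",
            },
        )
        result = apply_codebook(corpus, small_cb, fields=("title",))
        table = category_flows(result, ["Institutionalisation", "Governance"])
        assert table.flows[("Institutionalisation", "Governance")] == [
            ("Advisory", "Regulation", 2)
        ]

    def test_flows_match_bruteforce_intersections(self, small_cb):
        result = apply_codebook(planted_corpus(), small_cb, ("title", "abstract"))
        order = ["Institutionalisation", "Governance", "Symbolic role"]
        table = category_flows(result, order)
        for left_col, right_col in zip(order, order[1:]):
            for left, right, mag in table.flows[(left_col, right_col)]:
                expected = sum(
                    1
                    for cats in result.assignments.values()
                    if left in cats[left_col] and right in cats[right_col]
                )
                assert mag == expected and mag > 0

    def test_unknown_column_rejected(self, small_cb):
        result = apply_codebook(planted_corpus(), small_cb, ("title",))
        with pytest.raises(KeyError):
            category_flows(result, ["Governance", "Bogus"])

    def test_long_csv_format(self, small_cb):
        result = apply_codebook(planted_corpus(), small_cb, ("title",))
        csv_text = category_flows(
            result, ["Institutionalisation", "Governance"]
        ).to_long_csv()
        header, *rows = csv_text.strip().splitlines()
        assert header == "step,source,target,value"
        assert all(r.startswith("0,") for r in rows)


class TestRecode:
    def test_identical_codebook_empty_diff(self, small_cb):
        corpus = planted_corpus()
        old = apply_codebook(corpus, small_cb, ("title",))
        new, diff = recode(old, small_cb, corpus, ("title",))
        assert new.assignments == old.assignments
        assert diff["categories_added"] == diff["categories_removed"] == []
        assert diff["codes_added"] == diff["codes_removed"] == []
        assert diff["documents_changed"] == {}

    def test_dropping_a_column(self, small_cb):
        corpus = planted_corpus()
        old = apply_codebook(corpus, small_cb, ("title",))
        reduced = load_codebook(
            "columns:\n - name: Governance\n   codes:\n"
            "    - name: Regulation\n      patterns:\n"
            "       - regex: 'regulat(e|ion|ory)'\n"
        )
        new, diff = recode(old, reduced, corpus, ("title",))
        assert "Institutionalisation" in diff["categories_removed"]
        assert all("Governance" in cats for cats in new.assignments.values())
        assert all("Symbolic role" not in cats for cats in new.assignments.values())

    def test_emergent_remodel_enumerated(self):
        corpus = corpus_of(
            {1: ["Humans"], 2: ["Humans"]},
            titles={
                1: "political support for committees",
                2: "political will and oversight",
            },
        )
        cb_old = load_codebook(
            "columns:\n"
            " - name: Political discourse\n   codes:\n"
            "    - name: Political field\n      patterns: [politic]\n"
            " - name: Mechanism power\n   codes:\n"
            "    - name: Oversight\n      patterns: [oversight]\n"
        )
        cb_new = load_codebook(
            "columns:\n"
            " - name: Political discourse\n   codes:\n"
            "    - name: Political field\n      patterns: [politic]\n"
            " - name: Resistance\n   codes:\n"
            "    - name: political support\n      patterns: [political support]\n"
            "    - name: political will\n      patterns: [political will]\n"
        )
        old = apply_codebook(corpus, cb_old, ("title",))
        _, diff = recode(old, cb_new, corpus, ("title",))
        assert diff["categories_added"] == ["Resistance"]
        assert diff["categories_removed"] == ["Mechanism power"]
        assert diff["codes_added"] == [
            ("Resistance", "political support"), ("Resistance", "political will")
        ]
        assert diff["codes_removed"] == [("Mechanism power", "Oversight")]
        assert set(diff["documents_changed"]) == {"1", "2"}

    def test_recode_idempotent_in_result(self, small_cb):
        corpus = planted_corpus()
        old = apply_codebook(corpus, small_cb, ("title",))
        emergent = load_codebook(EXAMPLES / "codebook_emergent.yaml")
        once, _ = recode(old, emergent, corpus, ("title",))
        twice, diff2 = recode(once, emergent, corpus, ("title",))
        assert twice.assignments == once.assignments
        assert diff2["documents_changed"] == {}
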