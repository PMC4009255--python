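"""Dictionary curation rules, source merging, and lexicon statistics."""

from __future__ import annotations

import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markermine import (
    Concept,
    EntityClass,
    Lexicon,
    TermEntry,
    curate,
    generate_acronym_variants,
    generate_greek_variants,
    generate_numeral_variants,
    lexicon_stats,
    merge_sources,
    normalize_term,
    strip_affix_labels,
)
from markermine.lexicon import Provenance

from oracles import union_find_components


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("FALDH deficiency", "faldh deficiency"),
            ("hnf-3-gamma", "hnf 3 gamma"),
            ("abc", "abc"),
            ("Sjögren-Larsson syndrome", "sjogren larsson syndrome"),
            ("à, ö, ç, û", "a o c u"),
            ("  spaced   out  ", "spaced out"),
        ],
    )
    def test_folding(self, raw, expected):
        assert normalize_term(raw) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_term("")

    @given(st.text(min_size=1, max_size=40))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_idempotent(self, term):
        once = normalize_term(term) if term else ""
        if once:  # all-punctuation strings normalize to nothing
            assert normalize_term(once) == once


class TestAffixLabels:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("[X]Gastric neurosis", "Gastric neurosis"),
            ("Leber Congenital Amaurosis [Disease/Finding]", "Leber Congenital Amaurosis"),
            ("Gastric neurosis", "Gastric neurosis"),
            ("[D]middle [not stripped] term [V]", "middle [not stripped] term"),
        ],
    )
    def test_stripping(self, raw, expected):
        assert strip_affix_labels(raw) == expected


class TestVariantGeneration:
    def test_acronym_separator_variants(self):
        assert generate_acronym_variants("IL2") == {"IL2", "IL 2", "IL(2)", "IL-2"}

    def test_acronym_variants_for_longer_symbol(self):
        variants = generate_acronym_variants("TP53")
        assert {"TP-53", "TP 53"} <= variants

    def test_non_conforming_symbol_is_singleton(self):
        assert generate_acronym_variants("CD") == {"CD"}

    @pytest.mark.parametrize(
        "term, expected_member",
        [
            (
                "Adenylosuccinate lyase deficiency type 4",
                "Adenylosuccinate lyase deficiency type IV",
            ),
            ("type 9 disease", "type IX disease"),
        ],
    )
    def test_roman_numeral_variants(self, term, expected_member):
        assert expected_member in generate_numeral_variants(term)

    def test_numbers_outside_range_untouched(self):
        assert generate_numeral_variants("cohort of 2019 patients") == {
            "cohort of 2019 patients"
        }
        assert generate_numeral_variants("no numbers here") == {"no numbers here"}

    def test_greek_both_directions(self):
        assert "HP1-α" in generate_greek_variants("HP1-alpha")
        assert "HP1-beta" in generate_greek_variants("HP1-β")
        assert generate_greek_variants("HP1") == {"HP1"}

    @given(st.sampled_from(["IL2", "HP1-alpha", "type 4 disease", "plain term", "TCC"]))
    @settings(deadline=None, derandomize=True)
    def test_variant_generation_is_inflationary(self, term):
        for gen in (generate_acronym_variants, generate_numeral_variants, generate_greek_variants):
            assert term in gen(term)


def _entries(terms, cid="gene:1"):
    return [TermEntry(t, normalize_term(t), frozenset({cid})) for t in terms]


class TestCurate:
    def test_minimum_surviving_length_is_three(self):
        entries = _entries(["a", "ab", "abc", "abcd", "abcde", "abcdef"])
        survivors = curate(entries)
        lengths = sorted(len(e.surface) for e in survivors if e.provenance is Provenance.SOURCE)
        assert min(lengths) == 3
        assert all(len(e.surface) >= 3 for e in survivors)

    def test_blocklisted_general_terms_removed(self):
        survivors = curate(_entries(["disease", "interleukin 2"]), {"disease"})
        assert all(e.normalized != "disease" for e in survivors)
        assert any(e.normalized == "interleukin 2" for e in survivors)

    def test_empty_input(self):
        assert curate([]) == []

    def test_never_increases_source_entries_and_dedupes(self):
        entries = _entries(["TCC", "tcc", "T.C.C."])
        survivors = curate(entries, entity_class=EntityClass.DISEASE)
        sources = [e for e in survivors if e.provenance is Provenance.SOURCE]
        assert len({(e.normalized, tuple(sorted(e.concept_ids))) for e in survivors}) == len(survivors)
        assert len(sources) <= len(entries)

    def test_variant_expansion_marks_provenance(self):
        survivors = curate(_entries(["IL2"]), entity_class=EntityClass.GENE)
        normalized = {e.normalized for e in survivors}
        assert "il2" in normalized and "il 2" in normalized
        generated = {e.normalized for e in survivors if e.provenance is Provenance.GENERATED_VARIANT}
        assert "il 2" in generated


class TestMergeSources:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["source", "source_id", "term", "xrefs"])

    def test_cross_referenced_rows_collapse(self):
        a = self._table([("hgnc", "LCN2", "Lipocalin-2", "ncbi_gene:3934")])
        b = self._table([("ncbi_gene", "3934", "NGAL", "hgnc:LCN2")])
        lex = merge_sources([a, b], EntityClass.GENE, id_source="ncbi_gene")
        assert len(lex.concepts) == 1
        assert "gene:3934" in lex.concepts
        assert {e.surface for e in lex.entries} == {"Lipocalin-2", "NGAL"}

    def test_unlinked_rows_stay_separate(self):
        t = self._table([("src", "1", "alpha unit", ""), ("src", "2", "beta unit", "")])
        assert len(merge_sources([t], EntityClass.GENE).concepts) == 2

    def test_transitive_links_form_one_concept(self):
        t = self._table(
            [
                ("s1", "a", "term a", "s2:b"),
                ("s2", "b", "term b", "s3:c"),
                ("s3", "c", "term c", ""),
            ]
        )
        lex = merge_sources([t], EntityClass.GENE)
        assert len(lex.concepts) == 1
        assert {e.surface for e in lex.entries} == {"term a", "term b", "term c"}

    def test_component_count_matches_union_find_oracle(self):
        rng = random.Random(20240917)
        for _ in range(25):
            n = rng.randint(2, 18)
            nodes = [f"s:{i}" for i in range(n)]
            edges = [
                (nodes[rng.randrange(n)], nodes[rng.randrange(n)])
                for _ in range(rng.randint(0, n))
            ]
            xrefs = {node: [] for node in nodes}
            for a, b in edges:
                xrefs[a].append(b)
            table = pd.DataFrame(
                [
                    ("s", str(i), f"term {i}", ";".join(xrefs[nodes[i]]))
                    for i in range(n)
                ],
                columns=["source", "source_id", "term", "xrefs"],
            )
            lex = merge_sources([table], EntityClass.GENE)
            expected = union_find_components(nodes, edges)
            assert len(lex.concepts) == len(expected)


class TestLexiconStats:
    @staticmethod
    def _lexicon(term_map):
        """term_map: normalized term -> set of concept numbers."""
        lex = Lexicon(entity_class=EntityClass.GENE)
        cids = {c for ids in term_map.values() for c in ids}
        for c in sorted(cids):
            lex.add_concept(Concept(f"gene:{c}", f"g{c}", EntityClass.GENE))
        for term, ids in term_map.items():
            lex.add_entry(
                TermEntry(term, term, frozenset(f"gene:{c}" for c in ids))
            )
        return lex

    def test_unambiguous_lexicon(self):
        stats = lexicon_stats(self._lexicon({"aaa": {1}, "bbb": {2}}))
        assert stats.ambiguity == 1.0

    def test_shared_term_toy_example(self):
        # 2 concepts, 3 distinct terms, one term shared by both:
        # incidences = 4 over 3 terms -> ambiguity 4/3; 2 terms per concept
        stats = lexicon_stats(self._lexicon({"aaa": {1}, "bbb": {2}, "ccc": {1, 2}}))
        assert stats.ambiguity == pytest.approx(4 / 3)
        assert stats.variability == pytest.approx(2.0)

    def test_new_unambiguous_synonym_increases_variability(self):
        # adding synonym "ddd" for concept 1: 5 incidences over 4 terms
        base = self._lexicon({"aaa": {1}, "bbb": {2}, "ccc": {1, 2}})
        extended = self._lexicon({"aaa": {1}, "bbb": {2}, "ccc": {1, 2}, "ddd": {1}})
        s0, s1 = lexicon_stats(base), lexicon_stats(extended)
        assert s1.variability > s0.variability
        assert s1.ambiguity == pytest.approx(5 / 4)

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            lexicon_stats(Lexicon(entity_class=EntityClass.GENE))

    def test_brute_force_on_random_toy_lexicons(self):
        rng = random.Random(73)
        for _ in range(20):
            n_concepts = rng.randint(1, 50)
            n_terms = rng.randint(1, 60)
            term_map = {
                f"t{j:03d}": {
                    rng.randrange(n_concepts)
                    for _ in range(rng.randint(1, min(3, n_concepts)))
                }
                for j in range(n_terms)
            }
            # brute force over the full term-concept incidence list
            incidences = [(t, c) for t, ids in term_map.items() for c in ids]
            terms = {t for t, _ in incidences}
            concepts = {c for _, c in incidences}
            amb = len(incidences) / len(terms)
            var = len(incidences) / len(concepts)
            stats = lexicon_stats(self._lexicon(term_map))
            assert stats.ambiguity == pytest.approx(amb)
            assert stats.variability == pytest.approx(var)
            assert stats.ambiguity >= 1.0 and stats.variability >= 1.0
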