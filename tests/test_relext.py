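"""Co-occurrence extraction and the idf-weighted association score."""

from __future__ import annotations

import math
import random

import pandas as pd
import pytest

from markermine import (
    Cooccurrence,
    EntityClass,
    Section,
    abstract_frequency,
    extract_cooccurrences,
    overlap_with_reference,
    score_associations,
    specificity_profiles,
)
from markermine.ner import Mention

from oracles import brute_force_scores


def _mention(pmid, section, idx, entity_class, cids, start=0, end=3):
    return Mention(
        pmid=pmid,
        section=section,
        sentence_index=idx,
        char_start=start,
        char_end=end,
        surface="xxx",
        entity_class=entity_class,
        concept_ids=tuple(sorted(cids)),
    )


def _cooc(pmid, section, idx, disease, gene):
    return Cooccurrence(pmid, section, idx, disease, gene)


class TestExtractCooccurrences:
    def test_two_genes_one_disease_gives_two_pairs(self):
        mentions = [
            _mention("21740336", Section.BODY, 0, EntityClass.GENE, {"gene:3934"}, 0, 4),
            _mention("21740336", Section.BODY, 0, EntityClass.GENE, {"gene:9423"}, 10, 14),
            _mention("21740336", Section.BODY, 0, EntityClass.DISEASE, {"disease:C0022660"}, 20, 24),
        ]
        pairs = extract_cooccurrences(mentions)
        assert {(c.disease_id, c.gene_id) for c in pairs} == {
            ("disease:C0022660", "gene:3934"),
            ("disease:C0022660", "gene:9423"),
        }

    def test_single_class_sentence_gives_nothing(self):
        mentions = [
            _mention("1", Section.BODY, 0, EntityClass.GENE, {"gene:1"}),
            _mention("1", Section.BODY, 0, EntityClass.GENE, {"gene:2"}, 5, 8),
        ]
        assert extract_cooccurrences(mentions) == []

    def test_cartesian_product_and_per_sentence_dedup(self):
        mentions = [
            _mention("1", Section.BODY, 0, EntityClass.GENE, {"gene:1"}, 0, 3),
            _mention("1", Section.BODY, 0, EntityClass.GENE, {"gene:2"}, 4, 7),
            _mention("1", Section.BODY, 0, EntityClass.DISEASE, {"disease:C1"}, 8, 11),
            _mention("1", Section.BODY, 0, EntityClass.DISEASE, {"disease:C2"}, 12, 15),
            # repeated mention of the same gene: no extra pair
            _mention("1", Section.BODY, 0, EntityClass.GENE, {"gene:1"}, 16, 19),
        ]
        pairs = extract_cooccurrences(mentions)
        assert len(pairs) == 4

    def test_ambiguous_mention_contributes_each_candidate_once(self):
        mentions = [
            _mention("1", Section.BODY, 0, EntityClass.GENE, {"gene:1", "gene:2"}),
            _mention("1", Section.BODY, 0, EntityClass.DISEASE, {"disease:C1"}, 5, 8),
        ]
        pairs = extract_cooccurrences(mentions)
        assert {(c.disease_id, c.gene_id) for c in pairs} == {
            ("disease:C1", "gene:1"),
            ("disease:C1", "gene:2"),
        }


class TestAbstractFrequency:
    def test_title_weight(self):
        assert abstract_frequency([_cooc("1", Section.TITLE, 0, "d", "g")]) == {("d", "g"): 2.0}

    def test_body_weight(self):
        assert abstract_frequency([_cooc("1", Section.BODY, 0, "d", "g")]) == {("d", "g"): 1.0}

    def test_conclusions_weight_matches_title(self):
        assert abstract_frequency([_cooc("1", Section.CONCLUSIONS, 0, "d", "g")]) == {
            ("d", "g"): 2.0
        }

    def test_title_plus_body_sums(self):
        f = abstract_frequency(
            [
                _cooc("1", Section.TITLE, 0, "d", "g"),
                _cooc("1", Section.BODY, 2, "d", "g"),
            ]
        )
        assert f == {("d", "g"): 3.0}

    def test_mixed_abstracts_rejected(self):
        with pytest.raises(ValueError):
            abstract_frequency(
                [_cooc("1", Section.BODY, 0, "d", "g"), _cooc("2", Section.BODY, 0, "d", "g")]
            )


def _random_corpus(rng: random.Random):
    n_abstracts = rng.randint(1, 20)
    diseases = [f"disease:C{i}" for i in range(rng.randint(1, 3))]
    genes = [f"gene:{i}" for i in range(rng.randint(1, 3))]
    cooccs = []
    for a in range(n_abstracts):
        pmid = str(100 + a)
        n_sent = rng.randint(0, 5)
        for s in range(n_sent):
            section = rng.choice(list(Section))
            for d in diseases:
                for g in genes:
                    if rng.random() < 0.4:
                        cooccs.append(_cooc(pmid, section, s, d, g))
    return cooccs


class TestScoreAssociations:
    def test_pair_in_every_abstract_scores_zero(self):
        cooccs = [_cooc(str(i), Section.BODY, 0, "d", "g") for i in range(5)]
        (rec,) = score_associations(cooccs)
        assert rec.idf == 0.0 and rec.score == 0.0

    def test_pair_in_one_of_ten_abstracts_has_idf_one(self):
        cooccs = [_cooc("0", Section.BODY, 0, "d", "g")]
        cooccs += [_cooc(str(i), Section.BODY, 0, "d2", "g2") for i in range(1, 10)]
        by_pair = {r.pair: r for r in score_associations(cooccs)}
        assert by_pair[("d", "g")].idf == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            score_associations([])

    def test_score_factorizes(self):
        rng = random.Random(42)
        for _ in range(20):
            cooccs = _random_corpus(rng)
            if not cooccs:
                continue
            for rec in score_associations(cooccs):
                assert rec.score == pytest.approx(rec.idf * rec.af_sum, abs=1e-9)
                assert rec.n_abstracts >= 1 and rec.idf >= 0
                assert all(0 < f for f in rec.per_abstract_f.values())

    def test_af_max_is_one_in_every_abstract(self):
        rng = random.Random(7)
        for _ in range(20):
            cooccs = _random_corpus(rng)
            if not cooccs:
                continue
            records = score_associations(cooccs)
            by_abstract: dict[str, list[float]] = {}
            for rec in records:
                for pmid, f in rec.per_abstract_f.items():
                    by_abstract.setdefault(pmid, []).append(f)
            for fs in by_abstract.values():
                max_f = max(fs)
                afs = [f / max_f for f in fs]
                assert max(afs) == 1.0  # the most frequent pair normalizes to exactly 1
                assert all(0 < af <= 1 for af in afs)

    def test_matches_brute_force_oracle_on_random_corpora(self):
        rng = random.Random(20240501)
        checked = 0
        while checked < 60:
            cooccs = _random_corpus(rng)
            if not cooccs:
                continue
            records = score_associations(cooccs)
            expected = brute_force_scores(
                [(c.pmid, c.section.value, c.sentence_index, c.disease_id, c.gene_id) for c in cooccs]
            )
            assert {r.pair for r in records} == set(expected)
            for rec in records:
                exp = expected[rec.pair]
                assert rec.n_abstracts == exp["n_abstracts"]
                assert rec.idf == exp["idf"]
                assert math.isclose(rec.af_sum, exp["af_sum"], rel_tol=0, abs_tol=1e-12)
                assert math.isclose(rec.score, exp["score"], rel_tol=0, abs_tol=1e-12)
            checked += 1

    def test_sorted_by_score_with_deterministic_ties(self):
        rng = random.Random(13)
        cooccs = _random_corpus(rng) or [_cooc("1", Section.BODY, 0, "d", "g")]
        records = score_associations(cooccs)
        keys = [(-r.score, -r.n_abstracts, r.disease_id, r.gene_id) for r in records]
        assert keys == sorted(keys)

    def test_new_abstract_grows_af_sum(self):
        base = [
            _cooc("1", Section.BODY, 0, "d", "g"),
            _cooc("2", Section.BODY, 0, "d2", "g"),
        ]
        extended = base + [_cooc("3", Section.BODY, 0, "d", "g")]
        before = {r.pair: r for r in score_associations(base)}
        after = {r.pair: r for r in score_associations(extended)}
        assert after[("d", "g")].af_sum >= before[("d", "g")].af_sum

    def test_n_total_abstracts_override(self):
        cooccs = [_cooc("1", Section.BODY, 0, "d", "g")]
        (rec,) = score_associations(cooccs, n_total_abstracts=100)
        assert rec.idf == pytest.approx(2.0)
        with pytest.raises(ValueError):
            score_associations(cooccs, n_total_abstracts=0)


class TestSpecificityProfiles:
    def test_gene_with_three_diseases(self):
        cooccs = [_cooc("1", Section.BODY, i, f"disease:C{i}", "gene:1") for i in range(3)]
        per_gene, per_disease = specificity_profiles(score_associations(cooccs))
        assert per_gene == {"gene:1": 3}
        assert per_disease == {f"disease:C{i}": 1 for i in range(3)}

    def test_empty_records(self):
        assert specificity_profiles([]) == ({}, {})


class TestOverlapWithReference:
    def _records(self, pairs):
        cooccs = [
            _cooc(str(i), Section.BODY, 0, d, g) for i, (d, g) in enumerate(pairs)
        ]
        return score_associations(cooccs)

    def test_identical_reference_full_overlap(self):
        pairs = [("disease:C1", "gene:1"), ("disease:C2", "gene:2")]
        ref = pd.DataFrame(pairs, columns=["disease_id", "gene_id"])
        overall, _ = overlap_with_reference(self._records(pairs), ref)
        assert overall == 1.0

    def test_disjoint_reference_zero(self):
        pairs = [("disease:C1", "gene:1")]
        ref = pd.DataFrame([("disease:C9", "gene:9")], columns=["disease_id", "gene_id"])
        overall, _ = overlap_with_reference(self._records(pairs), ref)
        assert overall == 0.0

    def test_half_overlap_and_classes(self):
        pairs = [("disease:C1", "gene:1"), ("disease:C2", "gene:2")]
        ref = pd.DataFrame([("disease:C1", "gene:1")], columns=["disease_id", "gene_id"])
        classes = {"disease:C1": "C04", "disease:C2": "C10"}
        overall, per_class = overlap_with_reference(self._records(pairs), ref, classes)
        assert overall == 0.5
        assert per_class["C04"] == (1, 1, 1.0)
        assert per_class["C10"] == (1, 0, 0.0)

    def test_malformed_reference_rejected(self):
        with pytest.raises(ValueError):
            overlap_with_reference(
                self._records([("disease:C1", "gene:1")]),
                pd.DataFrame({"a": [1]}),
            )
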