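"""Synthetic lexicons and corpora with exactly known ground truth.

Real runs of the pipeline need licensed vocabulary snapshots (UMLS,
NCBI Gene) and a MEDLINE corpus. For development and testing this module
generates both sides from a seed: small gene/disease lexicons exhibiting
the surface phenomena the curation rules target (acronym separators,
Greek letters, Arabic/Roman numerals, a deliberately shared ambiguous
term), and template-sentence corpora in which every entity mention,
every disease-gene pair, and every section placement is planted at a
controlled rate and recorded as ground truth.

The templates use a closed function-word vocabulary that the generator
checks against the lexicon patterns, so the planted mention set is
exactly the recoverable mention set — no accidental matches, no misses.
Synthetic prose makes no attempt to look like real English abstracts;
what it controls is the combinatorics the pipeline must get right.

Default generation parameters mirror the published corpus where it
reports them: planted pair sentences fall 10% in the title, 85% in the
body, and 5% in the conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Document, Section
from .lexicon import (
    Concept,
    EntityClass,
    Lexicon,
    Provenance,
    TermEntry,
    curate,
    normalize_term,
)

__all__ = ["FixtureSpec", "GroundTruth", "make_lexicon", "make_corpus", "planted_signal_spec"]

#: term deliberately shared between the first two gene concepts
#: (exercises ambiguity handling); never planted in corpora
SHARED_GENE_TERM = "pan lineage factor"

_JOURNALS = ("J Synth Biomark", "Ann Fixture Med", "Mol Test Rep")

_PAIR_TEMPLATES = (
    "Levels of {gene} were measured in patients with {disease} here.",
    "Expression of {gene} correlated with {disease} in this cohort.",
)
_PAIR_TRIGGER_TEMPLATES = (
    "Notably, {gene} is a promising biomarker of {disease} in this cohort.",
    "Serum {gene} was evaluated as a candidate marker for {disease} here.",
)
_FILLER_TITLE = "Synthetic abstract record {pmid}."
_FILLER_BODY = "No additional findings were reported."


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters for one synthetic study.

    ``pair_rate_matrix`` holds the expected number of co-occurrence
    sentences per abstract for each (disease, gene) pair; the realized
    count is Poisson. ``p_title``/``p_conclusions`` place each planted
    sentence; ``trigger_rate`` is the probability that a planted pair
    sentence also carries a biomarker trigger term.
    """

    n_genes: int = 3
    n_diseases: int = 3
    n_abstracts: int = 20
    p_title: float = 0.10
    p_conclusions: float = 0.05
    pair_rate_matrix: tuple[tuple[float, ...], ...] | None = None
    trigger_rate: float = 0.5
    seed: int = 0
    synonyms_per_concept: int = 3
    shared_term: bool = True

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_diseases, self.n_abstracts) < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.p_title, self.p_conclusions, self.trigger_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_title + self.p_conclusions > 1.0:
            raise ValueError("p_title + p_conclusions must not exceed 1")
        if self.pair_rate_matrix is not None:
            rates = np.asarray(self.pair_rate_matrix, dtype=float)
            if rates.shape != (self.n_diseases, self.n_genes):
                raise ValueError(
                    f"pair_rate_matrix shape {rates.shape} != "
                    f"({self.n_diseases}, {self.n_genes})"
                )
            if (rates < 0).any():
                raise ValueError("pair rates must be >= 0")

    def rates(self) -> np.ndarray:
        if self.pair_rate_matrix is None:
            return np.full((self.n_diseases, self.n_genes), 0.3)
        return np.asarray(self.pair_rate_matrix, dtype=float)


def planted_signal_spec(seed: int = 0) -> FixtureSpec:
    """The planted-signal study design: one pair at 10x the background rate.

    A 10x10 entity grid over 200 abstracts with a background
    co-occurrence rate of 0.02 sentences per abstract per pair and the
    (first disease, first gene) pair planted at 0.2. The grid and corpus
    sizes keep every pair — the planted one included — present in only a
    small fraction of the co-occurring abstracts, which is the document-
    frequency regime the idf-weighted score is designed for: in a real
    biomarker corpus even the most-reported association appears in on
    the order of 2% of the abstracts.
    """
    n = 10
    rates = [[0.02] * n for _ in range(n)]
    rates[0][0] = 0.2
    return FixtureSpec(
        n_genes=n,
        n_diseases=n,
        n_abstracts=200,
        pair_rate_matrix=tuple(tuple(r) for r in rates),
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way the pipeline reports."""

    #: (pmid, section value, sentence index, entity class value, concept id)
    mentions: list[tuple[str, str, int, str, str]] = field(default_factory=list)
    #: (pmid, section value, sentence index, disease id, gene id)
    pairs: list[tuple[str, str, int, str, str]] = field(default_factory=list)
    #: sentence keys carrying a biomarker trigger term
    trigger_sentences: set[tuple[str, str, int]] = field(default_factory=set)
    #: planted pair sentences per section
    per_section: dict[str, int] = field(default_factory=dict)

    def pair_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs,
            columns=["pmid", "section", "sentence_index", "disease_id", "gene_id"],
        )

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.pair_df().to_csv(directory / "truth_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            self.mentions,
            columns=["pmid", "section", "sentence_index", "entity_class", "concept_id"],
        ).to_csv(directory / "truth_mentions.tsv", sep="\t", index=False)


def _gene_id(i: int) -> str:
    return f"gene:{1001 + i}"


def _disease_id(i: int) -> str:
    return f"disease:C{900001 + i:07d}"


def make_lexicon(spec: FixtureSpec) -> tuple[Lexicon, Lexicon]:
    """Build curated synthetic gene and disease lexicons.

    Gene ``i`` gets the acronym symbol ``GF<i>`` (exercising the
    separator-variant rule), a spelled-out name, and a Greek-suffixed
    synonym; disease ``i`` gets a numbered name (exercising the
    Roman-numeral rule) and a short code. When ``shared_term`` is set the
    first two genes also share one synonym, so the lexicon has ambiguity
    strictly above 1.
    """
    genes = Lexicon(entity_class=EntityClass.GENE)
    raw_gene_entries: list[TermEntry] = []
    for i in range(spec.n_genes):
        cid = _gene_id(i)
        symbol = f"GF{i + 1}"
        name = f"synthetic gene factor {i + 1}"
        genes.add_concept(Concept(cid, name, EntityClass.GENE))
        surfaces = [name, symbol, f"{symbol}-alpha"][: max(2, spec.synonyms_per_concept)]
        for surface in surfaces:
            raw_gene_entries.append(
                TermEntry(surface, normalize_term(surface), frozenset({cid}))
            )
    if spec.shared_term and spec.n_genes >= 2:
        raw_gene_entries.append(
            TermEntry(
                SHARED_GENE_TERM,
                normalize_term(SHARED_GENE_TERM),
                frozenset({_gene_id(0), _gene_id(1)}),
            )
        )
    for entry in curate(raw_gene_entries, entity_class=EntityClass.GENE):
        genes.add_entry(entry)

    diseases = Lexicon(entity_class=EntityClass.DISEASE)
    raw_dis_entries: list[TermEntry] = []
    for i in range(spec.n_diseases):
        cid = _disease_id(i)
        name = f"synthetic disorder {i + 1}"
        code = f"SDX{i + 1}"
        diseases.add_concept(Concept(cid, name, EntityClass.DISEASE, ("T047",)))
        for surface in [name, code][: max(2, spec.synonyms_per_concept)]:
            raw_dis_entries.append(
                TermEntry(surface, normalize_term(surface), frozenset({cid}))
            )
    for entry in curate(raw_dis_entries, entity_class=EntityClass.DISEASE):
        diseases.add_entry(entry)
    return genes, diseases


def _plantable_surfaces(lex: Lexicon, concept_id: str) -> list[str]:
    """Source surfaces of a concept, minus the deliberately ambiguous one."""
    shared_norm = normalize_term(SHARED_GENE_TERM)
    return sorted(
        {
            e.surface
            for e in lex.entries
            if concept_id in e.concept_ids
            and e.provenance is Provenance.SOURCE
            and e.normalized != shared_norm
        }
    )


def _template_vocabulary() -> set[str]:
    words: set[str] = set()
    for template in (
        *_PAIR_TEMPLATES,
        *_PAIR_TRIGGER_TEMPLATES,
        _FILLER_TITLE,
        _FILLER_BODY,
    ):
        skeleton = template.replace("{gene}", " ").replace("{disease}", " ").replace("{pmid}", " ")
        words.update(normalize_term(skeleton).split())
    return words


def _check_template_collisions(gene_lex: Lexicon, disease_lex: Lexicon) -> None:
    """Fail fast if any dictionary pattern could match template prose.

    Trigger words ("biomarker", "marker") are template vocabulary on
    purpose; dictionary terms must not be.
    """
    vocab = _template_vocabulary()
    for lex in (gene_lex, disease_lex):
        for term in lex.term_index():
            tokens = term.split(" ")
            if all(tok in vocab for tok in tokens):
                raise ValueError(
                    f"dictionary term {term!r} collides with sentence templates"
                )


def make_corpus(
    spec: FixtureSpec, lexicons: tuple[Lexicon, Lexicon]
) -> tuple[list[Document], GroundTruth]:
    """Generate a corpus of template abstracts plus its ground truth.

    For every abstract and every (disease, gene) pair, a Poisson draw at
    the pair's rate decides how many sentences mention the two together;
    each sentence is placed in the title, body, or conclusions and may
    carry a biomarker trigger term. Identical spec (seed included) gives
    a byte-identical corpus.
    """
    gene_lex, disease_lex = lexicons
    if not gene_lex.entries or not disease_lex.entries:
        raise ValueError("lexicons must be non-empty")
    _check_template_collisions(gene_lex, disease_lex)
    rng = np.random.default_rng(spec.seed)
    rates = spec.rates()

    gene_surfaces = {_gene_id(g): _plantable_surfaces(gene_lex, _gene_id(g)) for g in range(spec.n_genes)}
    disease_surfaces = {
        _disease_id(d): _plantable_surfaces(disease_lex, _disease_id(d))
        for d in range(spec.n_diseases)
    }

    docs: list[Document] = []
    truth = GroundTruth(per_section={s.value: 0 for s in Section})
    p_body = 1.0 - spec.p_title - spec.p_conclusions
    for k in range(spec.n_abstracts):
        pmid = str(9000001 + k)
        planted: dict[Section, list[tuple[str, str, str, bool]]] = {s: [] for s in Section}
        for d in range(spec.n_diseases):
            for g in range(spec.n_genes):
                count = rng.poisson(rates[d, g])
                for _ in range(count):
                    section = Section(
                        rng.choice(
                            ["TITLE", "BODY", "CONCLUSIONS"],
                            p=[spec.p_title, p_body, spec.p_conclusions],
                        )
                    )
                    with_trigger = bool(rng.random() < spec.trigger_rate)
                    planted[section].append((_disease_id(d), _gene_id(g), pmid, with_trigger))

        sections_text: dict[Section, str] = {}
        for section in Section:
            sentences: list[str] = []
            for idx, (did, gid, _, with_trigger) in enumerate(planted[section]):
                pool = _PAIR_TRIGGER_TEMPLATES if with_trigger else _PAIR_TEMPLATES
                template = pool[int(rng.integers(len(pool)))]
                gsurf = gene_surfaces[gid][int(rng.integers(len(gene_surfaces[gid])))]
                dsurf = disease_surfaces[did][int(rng.integers(len(disease_surfaces[did])))]
                sentences.append(template.format(gene=gsurf, disease=dsurf))
                key = (pmid, section.value, idx)
                truth.mentions.append((pmid, section.value, idx, "GENE", gid))
                truth.mentions.append((pmid, section.value, idx, "DISEASE", did))
                truth.pairs.append((pmid, section.value, idx, did, gid))
                truth.per_section[section.value] += 1
                if with_trigger:
                    truth.trigger_sentences.add(key)
            sections_text[section] = " ".join(sentences)

        title = sections_text[Section.TITLE] or _FILLER_TITLE.format(pmid=pmid)
        body_parts = [sections_text[Section.BODY], _FILLER_BODY]
        body = " ".join(p for p in body_parts if p)
        docs.append(
            Document(
                pmid=pmid,
                year=int(1990 + rng.integers(0, 25)),
                journal=_JOURNALS[int(rng.integers(len(_JOURNALS)))],
                title=title,
                body=body,
                conclusions=sections_text[Section.CONCLUSIONS],
            )
        )
    return docs, truth
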