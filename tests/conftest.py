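"""Shared fixtures: worked-example lexicons and documents.

The worked corpus consists of seven published abstract sentences whose
disease-gene pairs, concept identifiers, and section placements are
known, together with a hand-built dictionary covering exactly the
entities they mention.
"""

from __future__ import annotations

import pytest

from markermine import (
    Concept,
    Document,
    EntityClass,
    Lexicon,
    TermEntry,
    normalize_term,
)
from markermine.lexicon import read_wordlist
from markermine.pipeline import default_wordlist_path


def _build(entity_class: EntityClass, concepts: dict[str, list[str]]) -> Lexicon:
    lex = Lexicon(entity_class=entity_class)
    for cid, terms in concepts.items():
        lex.add_concept(Concept(cid, terms[0], entity_class))
        for term in terms:
            lex.add_entry(TermEntry(term, normalize_term(term), frozenset({cid})))
    return lex


@pytest.fixture(scope="session")
def worked_gene_lexicon() -> Lexicon:
    return _build(
        EntityClass.GENE,
        {
            "gene:268": ["Anti-Mullerian hormone"],
            "gene:54474": ["CK20"],
            "gene:627": ["brain-derived neurotrophic factor", "BDNF"],
            "gene:3934": ["Neutrophil gelatinase-associated lipocalin", "NGAL"],
            "gene:9423": ["netrin-1"],
            "gene:7137": ["cardiac troponin I"],
            "gene:4072": ["MOC-31"],
            "gene:6094": ["ROM"],
        },
    )


@pytest.fixture(scope="session")
def worked_disease_lexicon() -> Lexicon:
    return _build(
        EntityClass.DISEASE,
        {
            "disease:C0019829": ["Hodgkin's lymphoma"],
            "disease:C1861305": ["TCC"],
            "disease:C0004352": ["autism"],
            "disease:C0022660": ["acute kidney injury", "AKI"],
            "disease:C0264716": ["chronic heart failure"],
            "disease:C0001418": ["adenocarcinomas"],
            "disease:C0152013": ["lung adenocarcinoma"],
        },
    )


_NEUTRAL_BODY = "The study design is described below."

_WORKED_SENTENCES = {
    "17726078": (
        2007,
        "TITLE",
        "Anti-Mullerian hormone is a sensitive serum marker for gonadal function "
        "in women treated for Hodgkin's lymphoma during childhood.",
    ),
    "17397492": (
        2007,
        "CONCLUSIONS",
        "CK20 is an important biomarker that can be used to identify TCC "
        "in urine cytology smears.",
    ),
    "19119429": (
        2008,
        "BODY",
        "To investigate levels of brain-derived neurotrophic factor (BDNF) in "
        "midpregnancy and neonatal blood specimens as early biologic markers for "
        "autism; we conducted a population-based case-control study nested within "
        "the cohort of infants born from July 2000 to September 2001 to women who "
        "participated in the prenatal screening program in Orange County, CA.",
    ),
    "21740336": (
        2011,
        "BODY",
        "Neutrophil gelatinase-associated lipocalin (NGAL) and netrin-1 have been "
        "proposed over the past years as emergent biomarkers for the early and "
        "accurate diagnosis and monitoring of acute kidney injury (AKI).",
    ),
    "21751783": (
        2011,
        "TITLE",
        "Top-down quantitative proteomics identified phosphorylation of cardiac "
        "troponin I as a candidate biomarker for chronic heart failure.",
    ),
    "21732548": (
        2011,
        "BODY",
        "MOC-31 is an established immunologic marker to detect adenocarcinomas.",
    ),
    "21748260": (
        2012,
        "BODY",
        "Hence, serum ROM level may be a useful biomarker for staging of "
        "lung adenocarcinoma.",
    ),
}

#: (pmid, section, disease_id, gene_id) expected from the worked corpus
WORKED_EXPECTED_PAIRS = frozenset(
    {
        ("17726078", "TITLE", "disease:C0019829", "gene:268"),
        ("17397492", "CONCLUSIONS", "disease:C1861305", "gene:54474"),
        ("19119429", "BODY", "disease:C0004352", "gene:627"),
        ("21740336", "BODY", "disease:C0022660", "gene:3934"),
        ("21740336", "BODY", "disease:C0022660", "gene:9423"),
        ("21751783", "TITLE", "disease:C0264716", "gene:7137"),
        ("21732548", "BODY", "disease:C0001418", "gene:4072"),
        ("21748260", "BODY", "disease:C0152013", "gene:6094"),
    }
)


@pytest.fixture(scope="session")
def worked_documents() -> list[Document]:
    docs = []
    for pmid, (year, section, sentence) in _WORKED_SENTENCES.items():
        docs.append(
            Document(
                pmid=pmid,
                year=year,
                journal="J Worked Examples",
                title=sentence if section == "TITLE" else f"Record {pmid} title.",
                body=sentence if section == "BODY" else _NEUTRAL_BODY,
                conclusions=sentence if section == "CONCLUSIONS" else "",
            )
        )
    return docs


@pytest.fixture(scope="session")
def stopwords() -> frozenset[str]:
    return read_wordlist(default_wordlist_path("stopwords.txt"))


@pytest.fixture(scope="session")
def triggers() -> frozenset[str]:
    return read_wordlist(default_wordlist_path("triggers.txt"))


@pytest.fixture(scope="session")
def blocklist() -> frozenset[str]:
    return read_wordlist(default_wordlist_path("blocklist.txt"))
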