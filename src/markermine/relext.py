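"""Sentence co-occurrence relation extraction and idf-based scoring.

A disease and a gene are taken as putatively associated whenever they are
mentioned together in one sentence. Associations are ranked with a
section-weighted inverse-document-frequency score:

    Score_DB  = idf(DB, A) * sum_i af(DB, A_i)
    idf(DB,A) = log10( |A| / |{a in A : DB in a}| )
    af(DB,A_i)= f(DB, A_i) / max{ f(XY, A_i) : XY in A_i }

where ``f(DB, A_i)`` counts the sentences of abstract ``A_i`` containing
the pair, each weighted 2 when it sits in the title or conclusions and 1
in the body — the sections where a publication's final message concentrates.
``af`` normalizes that count by the most frequent pair of the same
abstract, and the idf factor discounts associations that are ubiquitous
across the corpus. ``|A|`` is by default the number of abstracts
contributing at least one co-occurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Section
from .lexicon import EntityClass
from .ner import Mention

__all__ = [
    "Cooccurrence",
    "AssociationRecord",
    "extract_cooccurrences",
    "abstract_frequency",
    "score_associations",
    "specificity_profiles",
    "overlap_with_reference",
    "read_reference_table",
    "write_cooccurrences_tsv",
    "write_associations_tsv",
]

#: section weight for f(DB, A_i): title and conclusions double the body
DEFAULT_SECTION_WEIGHT = 2.0


@dataclass(frozen=True, order=True)
class Cooccurrence:
    """A disease-gene pair mentioned together in one sentence."""

    pmid: str
    section: Section
    sentence_index: int
    disease_id: str
    gene_id: str


@dataclass(frozen=True)
class AssociationRecord:
    """A scored disease-gene association."""

    disease_id: str
    gene_id: str
    n_abstracts: int
    per_abstract_f: Mapping[str, float]
    idf: float
    af_sum: float
    score: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.disease_id, self.gene_id)


def extract_cooccurrences(mentions: Sequence[Mention]) -> list[Cooccurrence]:
    """All sentence-level disease-gene pairs, deduplicated per sentence.

    Within each sentence the distinct disease concept ids and distinct
    gene concept ids form a Cartesian product; an ambiguous mention
    contributes every candidate concept, but each (disease, gene) pair
    counts at most once per sentence.
    """
    by_sentence: dict[tuple[str, Section, int], tuple[set[str], set[str]]] = {}
    for m in mentions:
        key = (m.pmid, m.section, m.sentence_index)
        diseases, genes = by_sentence.setdefault(key, (set(), set()))
        target = genes if m.entity_class is EntityClass.GENE else diseases
        target.update(m.concept_ids)
    out: list[Cooccurrence] = []
    for (pmid, section, idx), (diseases, genes) in by_sentence.items():
        for disease_id in diseases:
            for gene_id in genes:
                out.append(Cooccurrence(pmid, section, idx, disease_id, gene_id))
    return sorted(out)


def abstract_frequency(
    cooccs: Sequence[Cooccurrence],
    *,
    section_weight: float = DEFAULT_SECTION_WEIGHT,
) -> dict[tuple[str, str], float]:
    """Within-abstract weighted pair frequencies f(DB, A_i).

    All co-occurrences must come from a single abstract. Each distinct
    sentence containing the pair contributes ``section_weight`` when in
    the title or conclusions, 1 in the body.
    """
    pmids = {c.pmid for c in cooccs}
    if len(pmids) > 1:
        raise ValueError(f"co-occurrences span several abstracts: {sorted(pmids)}")
    freq: dict[tuple[str, str], float] = {}
    for c in set(cooccs):  # invariant: one per (sentence, pair); enforce anyway
        weight = section_weight if c.section in (Section.TITLE, Section.CONCLUSIONS) else 1.0
        pair = (c.disease_id, c.gene_id)
        freq[pair] = freq.get(pair, 0.0) + weight
    return freq


def score_associations(
    cooccs: Sequence[Cooccurrence],
    *,
    n_total_abstracts: int | None = None,
    section_weight: float = DEFAULT_SECTION_WEIGHT,
    idf_base: float = 10.0,
) -> list[AssociationRecord]:
    """Score and rank every disease-gene association of a corpus.

    ``n_total_abstracts`` overrides |A| (it must be at least the number
    of abstracts with co-occurrences); by default |A| counts the
    abstracts contributing at least one pair. Records are sorted by score
    descending, ties broken by abstract count descending then identifier
    order, which makes the output byte-reproducible.
    """
    if not cooccs:
        raise ValueError("cannot score an empty co-occurrence list")
    by_abstract: dict[str, list[Cooccurrence]] = {}
    for c in cooccs:
        by_abstract.setdefault(c.pmid, []).append(c)
    n_abstracts_total = len(by_abstract)
    if n_total_abstracts is not None:
        if n_total_abstracts < n_abstracts_total:
            raise ValueError(
                f"|A|={n_total_abstracts} smaller than the {n_abstracts_total} "
                "abstracts with co-occurrences"
            )
        n_abstracts_total = n_total_abstracts

    per_pair_f: dict[tuple[str, str], dict[str, float]] = {}
    for pmid, chunk in by_abstract.items():
        freqs = abstract_frequency(chunk, section_weight=section_weight)
        max_f = max(freqs.values())
        for pair, f in freqs.items():
            per_pair_f.setdefault(pair, {})[pmid] = f / max_f  # af(DB, A_i)

    records = []
    for pair, af_by_abstract in per_pair_f.items():
        n_abs = len(af_by_abstract)
        if idf_base == 10.0:
            idf = math.log10(n_abstracts_total / n_abs)
        else:
            idf = math.log(n_abstracts_total / n_abs) / math.log(idf_base)
        af_sum = sum(sorted(af_by_abstract.values()))  # stable accumulation
        raw_f = {
            pmid: abstract_frequency(by_abstract[pmid], section_weight=section_weight)[pair]
            for pmid in af_by_abstract
        }
        records.append(
            AssociationRecord(
                disease_id=pair[0],
                gene_id=pair[1],
                n_abstracts=n_abs,
                per_abstract_f=raw_f,
                idf=idf,
                af_sum=af_sum,
                score=idf * af_sum,
            )
        )
    records.sort(key=lambda r: (-r.score, -r.n_abstracts, r.disease_id, r.gene_id))
    return records


def specificity_profiles(
    records: Sequence[AssociationRecord],
) -> tuple[dict[str, int], dict[str, int]]:
    """Distinct diseases per gene and distinct genes per disease.

    A gene associated with hundreds of diseases (IL6, TNF, CD4 in the
    published corpus) is an unspecific biomarker; one associated with a
    single disease is highly specific.
    """
    diseases_per_gene: dict[str, set[str]] = {}
    genes_per_disease: dict[str, set[str]] = {}
    for r in records:
        diseases_per_gene.setdefault(r.gene_id, set()).add(r.disease_id)
        genes_per_disease.setdefault(r.disease_id, set()).add(r.gene_id)
    return (
        {g: len(ds) for g, ds in sorted(diseases_per_gene.items())},
        {d: len(gs) for d, gs in sorted(genes_per_disease.items())},
    )


def overlap_with_reference(
    records: Sequence[AssociationRecord],
    reference: pd.DataFrame,
    disease_classes: Mapping[str, str] | None = None,
) -> tuple[float, dict[str, tuple[int, int, float]]]:
    """Fraction of extracted pairs present in a reference association table.

    ``reference`` needs columns ``disease_id`` and ``gene_id``. Returns
    the overall fraction in [0, 1] and, when ``disease_classes`` maps
    disease ids to class labels, per-class tuples
    (n_extracted, n_validated, fraction).
    """
    if not {"disease_id", "gene_id"} <= set(reference.columns):
        raise ValueError("reference table needs disease_id and gene_id columns")
    ref_pairs = set(zip(reference["disease_id"].astype(str), reference["gene_id"].astype(str)))
    pairs = {r.pair for r in records}
    if not pairs:
        return 0.0, {}
    overall = len(pairs & ref_pairs) / len(pairs)
    per_class: dict[str, tuple[int, int, float]] = {}
    if disease_classes:
        by_class: dict[str, set[tuple[str, str]]] = {}
        for pair in pairs:
            cls = disease_classes.get(pair[0])
            if cls is not None:
                by_class.setdefault(cls, set()).add(pair)
        for cls, class_pairs in sorted(by_class.items()):
            hit = len(class_pairs & ref_pairs)
            per_class[cls] = (len(class_pairs), hit, hit / len(class_pairs))
    return overall, per_class


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_cooccurrences_tsv(cooccs: Sequence[Cooccurrence], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pmid": c.pmid,
                "section": c.section.value,
                "sentence_index": c.sentence_index,
                "disease_id": c.disease_id,
                "gene_id": c.gene_id,
            }
            for c in sorted(cooccs)
        ],
        columns=["pmid", "section", "sentence_index", "disease_id", "gene_id"],
    ).to_csv(path, sep="\t", index=False)


def write_associations_tsv(
    records: Sequence[AssociationRecord],
    path: str | Path,
    *,
    disease_names: Mapping[str, str] | None = None,
    gene_names: Mapping[str, str] | None = None,
) -> None:
    disease_names = disease_names or {}
    gene_names = gene_names or {}
    pd.DataFrame(
        [
            {
                "disease_id": r.disease_id,
                "disease_name": disease_names.get(r.disease_id, ""),
                "gene_id": r.gene_id,
                "gene_symbol": gene_names.get(r.gene_id, ""),
                "n_abstracts": r.n_abstracts,
                "idf": f"{r.idf:.6f}",
                "af_sum": f"{r.af_sum:.6f}",
                "score": f"{r.score:.6f}",
            }
            for r in records
        ],
        columns=[
            "disease_id", "disease_name", "gene_id", "gene_symbol",
            "n_abstracts", "idf", "af_sum", "score",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a reference association table (disease_id, gene_id[, disease_class])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"disease_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: reference table needs disease_id and gene_id columns")
    return df
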