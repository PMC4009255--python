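"""Abstract corpus readers, section segmentation, and sentence splitting.

Every abstract is represented as a :class:`Document` with three sections
— title, body, conclusions — because the closing message of a publication is
typically stated in the title or the final, labelled part of a structured
abstract, and downstream scoring weights those sections higher. For
unstructured abstracts the conclusions section is empty and all abstract
text lands in the body.

Sentence splitting is rule-based and deterministic: offsets are stable
across runs and environments, which the mention/association provenance
relies on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from .relext import Cooccurrence

logger = logging.getLogger(__name__)

__all__ = [
    "Section",
    "Document",
    "Sentence",
    "read_corpus",
    "write_corpus_tsv",
    "segment_abstract",
    "split_sentences",
    "document_sentences",
    "corpus_sentences",
    "bibliometrics",
]


class Section(str, Enum):
    TITLE = "TITLE"
    BODY = "BODY"
    CONCLUSIONS = "CONCLUSIONS"


#: structured-abstract labels routed to the conclusions section
CONCLUSION_LABELS = frozenset({"CONCLUSION", "CONCLUSIONS", "INTERPRETATION"})


@dataclass(frozen=True)
class Document:
    """One abstract split into title / body / conclusions."""

    pmid: str
    year: int | None
    journal: str
    title: str
    body: str
    conclusions: str = ""

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError(f"document {self.pmid}: empty title")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"document {self.pmid}: implausible year {self.year}")

    def section_text(self, section: Section) -> str:
        return {
            Section.TITLE: self.title,
            Section.BODY: self.body,
            Section.CONCLUSIONS: self.conclusions,
        }[section]


@dataclass(frozen=True)
class Sentence:
    """A sentence with its position inside one document section.

    ``char_start``/``char_end`` are 0-based half-open offsets into the
    section text, so ``section_text[char_start:char_end] == text``.
    """

    pmid: str
    section: Section
    index: int
    text: str
    char_start: int
    char_end: int

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.pmid, self.section.value, self.index)


# ---------------------------------------------------------------------------
# sentence splitting
# ---------------------------------------------------------------------------

# tokens before a period that do not end a sentence
_ABBREVIATIONS = frozenset(
    {
        "i.e", "e.g", "cf", "ca", "vs", "al", "fig", "figs", "eq", "eqs",
        "ref", "refs", "no", "nos", "approx", "resp", "dr", "prof", "mr",
        "mrs", "ms", "st", "jr", "sr", "inc", "ltd", "sp", "spp", "var",
    }
)

_BOUNDARY = re.compile(r"[.!?]+")


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True when the period at ``dot_pos`` terminates a guarded abbreviation."""
    start = dot_pos
    while start > 0 and (text[start - 1].isalnum() or text[start - 1] == "."):
        start -= 1
    token = text[start:dot_pos].lower().rstrip(".")
    if not token:
        return False
    return token in _ABBREVIATIONS or token.split(".")[-1] in _ABBREVIATIONS


def split_sentences(
    section_text: str,
    *,
    pmid: str = "",
    section: Section = Section.BODY,
) -> list[Sentence]:
    """Split one section into sentences with exact character offsets.

    Splits at runs of sentence-final punctuation followed by whitespace
    and an uppercase letter or digit, guarded by an abbreviation list so
    "i.e.", "e.g.", "Fig." and initials do not break sentences. The
    returned spans tile all non-whitespace text of the section.
    """
    sentences: list[Sentence] = []
    if not section_text or not section_text.strip():
        return sentences

    breaks: list[int] = []  # positions just after a sentence-final run
    for m in _BOUNDARY.finditer(section_text):
        end = m.end()
        if end >= len(section_text):
            break
        follow = section_text[end:]
        stripped = follow.lstrip()
        if follow == stripped:  # no whitespace after punctuation: not a boundary
            continue
        if not stripped or not (stripped[0].isupper() or stripped[0].isdigit()):
            continue
        if "." in m.group(0) and _is_abbreviation(section_text, m.start()):
            continue
        breaks.append(end)

    starts = [0] + breaks
    ends = breaks + [len(section_text)]
    index = 0
    for raw_start, raw_end in zip(starts, ends):
        chunk = section_text[raw_start:raw_end]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        start, end = raw_start + lead, raw_end - trail
        if start >= end:
            continue
        sentences.append(
            Sentence(pmid, section, index, section_text[start:end], start, end)
        )
        index += 1
    return sentences


def document_sentences(doc: Document) -> list[Sentence]:
    """All sentences of a document across the three sections."""
    out: list[Sentence] = []
    for section in Section:
        out.extend(split_sentences(doc.section_text(section), pmid=doc.pmid, section=section))
    return out


def corpus_sentences(docs: Iterable[Document]) -> list[Sentence]:
    out: list[Sentence] = []
    for doc in docs:
        out.extend(document_sentences(doc))
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_abstract(
    raw_title: str,
    raw_abstract: str,
    section_labels: Sequence[tuple[str, str]] | None = None,
) -> tuple[str, str, str]:
    """Route abstract text into (title, body, conclusions).

    ``section_labels`` is the structured-abstract decomposition as
    (label, text) pairs when the source provides one; segments labelled
    CONCLUSION(S) or INTERPRETATION go to conclusions, everything else to
    the body. Without labels the whole abstract is body.
    """
    title = raw_title.strip()
    if section_labels:
        body_parts, concl_parts = [], []
        for label, text in section_labels:
            text = text.strip()
            if not text:
                continue
            if label and label.strip().upper() in CONCLUSION_LABELS:
                concl_parts.append(text)
            else:
                body_parts.append(text)
        return title, " ".join(body_parts), " ".join(concl_parts)
    return title, raw_abstract.strip(), ""


_INLINE_LABEL = re.compile(r"(?:(?<=^)|(?<=\s))([A-Z][A-Z /&-]{2,40}):\s+")


def split_inline_labels(abstract: str) -> list[tuple[str, str]] | None:
    """Recover structured-abstract labels written inline ("METHODS: ...").

    Returns None when the text carries no such labels (unstructured
    abstract).
    """
    matches = list(_INLINE_LABEL.finditer(abstract))
    if not matches:
        return None
    segments: list[tuple[str, str]] = []
    if matches[0].start() > 0:
        segments.append(("", abstract[: matches[0].start()]))
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(abstract)
        segments.append((m.group(1).strip(), abstract[m.end(): end]))
    return segments


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["pmid", "year", "journal", "title", "body", "conclusions"]


def read_corpus(path: str | Path, format: str = "tsv") -> list[Document]:
    """Read a corpus of abstracts.

    ``format`` is one of ``tsv`` (fixture format: pmid, year, journal,
    title, body, conclusions), ``pubmed_xml`` (PubmedArticleSet) or
    ``nbib`` (MEDLINE tagged format). Records without any abstract text
    are skipped and counted in the log.
    """
    readers = {"tsv": _read_tsv, "pubmed_xml": _read_pubmed_xml, "nbib": _read_nbib}
    if format not in readers:
        raise ValueError(f"unknown corpus format {format!r}; expected one of {sorted(readers)}")
    return readers[format](Path(path))


def _read_tsv(path: Path) -> list[Document]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if missing := set(TSV_COLUMNS) - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    docs, skipped = [], 0
    for _, row in df.iterrows():
        if not (row["body"] or row["conclusions"]):
            skipped += 1
            continue
        docs.append(
            Document(
                pmid=row["pmid"],
                year=int(row["year"]) if row["year"] else None,
                journal=row["journal"],
                title=row["title"],
                body=row["body"],
                conclusions=row["conclusions"],
            )
        )
    if skipped:
        logger.info("%s: skipped %d records without abstract text", path, skipped)
    return docs


def write_corpus_tsv(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents in the fixture TSV format (round-trips with ``read_corpus``)."""

    def clean(text: str) -> str:
        return re.sub(r"[\t\r\n]+", " ", text)

    rows = [
        {
            "pmid": d.pmid,
            "year": "" if d.year is None else d.year,
            "journal": clean(d.journal),
            "title": clean(d.title),
            "body": clean(d.body),
            "conclusions": clean(d.conclusions),
        }
        for d in docs
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_pubmed_xml(path: Path) -> list[Document]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed PubMed XML: {exc}") from exc
    docs, skipped = [], 0
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//MedlineCitation/PMID", default="").strip()
        try:
            doc = _pubmed_article_to_document(article, pmid)
        except Exception as exc:
            raise ValueError(f"{path}: record PMID={pmid or '?'}: {exc}") from exc
        if doc is None:
            skipped += 1
        else:
            docs.append(doc)
    if skipped:
        logger.info("%s: skipped %d records without abstract text", path, skipped)
    return docs


def _pubmed_article_to_document(article: etree._Element, pmid: str) -> Document | None:
    art = article.find(".//MedlineCitation/Article")
    if art is None:
        return None
    title = "".join(art.find("ArticleTitle").itertext()) if art.find("ArticleTitle") is not None else ""
    abstract = art.find("Abstract")
    if abstract is None:
        return None
    labels: list[tuple[str, str]] = []
    for abstract_text in abstract.findall("AbstractText"):
        label = abstract_text.get("Label") or abstract_text.get("NlmCategory") or ""
        labels.append((label, "".join(abstract_text.itertext())))
    if not any(text.strip() for _, text in labels):
        return None
    if len(labels) == 1 and not labels[0][0]:
        inline = split_inline_labels(labels[0][1])
        if inline:
            labels = inline
    if len(labels) == 1 and not labels[0][0]:
        title, body, conclusions = segment_abstract(title, labels[0][1])
    else:
        title, body, conclusions = segment_abstract(title, "", labels)
    year_text = art.findtext(".//Journal/JournalIssue/PubDate/Year", default="")
    if not year_text:
        medline_date = art.findtext(".//Journal/JournalIssue/PubDate/MedlineDate", default="")
        m = re.search(r"(19|20)\d{2}", medline_date)
        year_text = m.group(0) if m else ""
    journal = art.findtext(".//Journal/Title", default="") or article.findtext(
        ".//MedlineCitation/MedlineJournalInfo/MedlineTA", default=""
    )
    return Document(
        pmid=pmid,
        year=int(year_text) if year_text else None,
        journal=journal.strip(),
        title=title,
        body=body,
        conclusions=conclusions,
    )


_NBIB_TAG = re.compile(r"^([A-Z]{2,4})\s*-\s(.*)$")


def _read_nbib(path: Path) -> list[Document]:
    records: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] = {}
    tag = None
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            if current:
                records.append(current)
                current, tag = {}, None
            continue
        m = _NBIB_TAG.match(line)
        if m:
            tag = m.group(1)
            current.setdefault(tag, []).append(m.group(2))
        elif line.startswith(" ") and tag:
            current[tag][-1] += " " + line.strip()
        else:
            raise ValueError(f"{path}:{lineno}: malformed nbib line: {line!r}")
    if current:
        records.append(current)

    docs, skipped = [], 0
    for rec in records:
        pmid = rec.get("PMID", [""])[0].strip()
        abstract = " ".join(rec.get("AB", [])).strip()
        if not abstract:
            skipped += 1
            continue
        title = " ".join(rec.get("TI", [])).strip()
        journal = rec.get("JT", rec.get("TA", [""]))[0].strip()
        dp = rec.get("DP", [""])[0]
        m = re.search(r"(19|20)\d{2}", dp)
        title, body, conclusions = segment_abstract(title, abstract, split_inline_labels(abstract))
        docs.append(
            Document(
                pmid=pmid,
                year=int(m.group(0)) if m else None,
                journal=journal,
                title=title,
                body=body,
                conclusions=conclusions,
            )
        )
    if skipped:
        logger.info("%s: skipped %d records without abstract text", path, skipped)
    return docs


# ---------------------------------------------------------------------------
# bibliometrics
# ---------------------------------------------------------------------------


def bibliometrics(
    corpus: Sequence[Document],
    cooccs: Sequence["Cooccurrence"] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Publication counts per year and association provenance per journal.

    Returns ``(per_year, per_journal)``: per_year has columns
    (year, n_publications, n_journals); per_journal has columns
    (journal, n_publications, n_cooccurrences, n_associations,
    n_diseases, n_genes), sorted by co-occurrence count descending.
    """
    doc_rows = pd.DataFrame(
        [{"pmid": d.pmid, "year": d.year, "journal": d.journal} for d in corpus],
        columns=["pmid", "year", "journal"],
    )
    with_year = doc_rows.dropna(subset=["year"])
    if len(with_year):
        per_year = (
            with_year.groupby("year")
            .agg(n_publications=("pmid", "size"), n_journals=("journal", "nunique"))
            .reset_index()
            .astype({"year": int})
            .sort_values("year", ignore_index=True)
        )
    else:
        per_year = pd.DataFrame(columns=["year", "n_publications", "n_journals"])

    per_journal = (
        doc_rows.groupby("journal").agg(n_publications=("pmid", "size"))
        if len(doc_rows)
        else pd.DataFrame(columns=["n_publications"])
    )
    cooc_rows = pd.DataFrame(
        [
            {"pmid": c.pmid, "disease_id": c.disease_id, "gene_id": c.gene_id}
            for c in cooccs
        ],
        columns=["pmid", "disease_id", "gene_id"],
    )
    if len(cooc_rows) and len(doc_rows):
        merged = cooc_rows.merge(doc_rows[["pmid", "journal"]], on="pmid", how="inner")
        merged["pair"] = merged["disease_id"] + "|" + merged["gene_id"]
        stats = merged.groupby("journal").agg(
            n_cooccurrences=("pair", "size"),
            n_associations=("pair", "nunique"),
            n_diseases=("disease_id", "nunique"),
            n_genes=("gene_id", "nunique"),
        )
        per_journal = per_journal.join(stats)
    else:
        for col in ("n_cooccurrences", "n_associations", "n_diseases", "n_genes"):
            per_journal[col] = 0
    per_journal = (
        per_journal.fillna(0)
        .astype(int)
        .reset_index()
        .sort_values(["n_cooccurrences", "journal"], ascending=[False, True], ignore_index=True)
    )
    return per_year, per_journal
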