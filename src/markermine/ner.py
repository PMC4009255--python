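"""Dictionary-based named entity recognition over normalized sentences.

The matcher works on the canonical normalized form of each sentence
(lowercase, diacritic-folded, punctuation replaced by spaces) so that all
surface variability handled by the lexicon's variant generation — case,
separators, Greek spelling, Roman numerals — reduces to exact matching.
Matches are restricted to token boundaries and selected greedily left to
right, always taking the longest dictionary term available at the current
position ("acute lymphoblastic leukemia" beats "leukemia"); scanning
resumes after the accepted match, so mentions of one entity class never
overlap. Each accepted mention is normalized to the concept identifier(s)
its term carries in the dictionary; a term shared by several concepts
yields a single mention flagged as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus import Document, Section, Sentence, document_sentences
from .lexicon import EntityClass, Lexicon
from .textnorm import normalize_text, tokenize

__all__ = [
    "Mention",
    "MatcherIndex",
    "compile_patterns",
    "tag_sentence",
    "tag_corpus",
    "write_mentions_tsv",
]


@dataclass(frozen=True, order=True)
class Mention:
    """A normalized entity mention located in one sentence."""

    pmid: str
    section: Section
    sentence_index: int
    char_start: int
    char_end: int
    surface: str
    entity_class: EntityClass
    concept_ids: tuple[str, ...]  # sorted, non-empty

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError("empty mention span")
        if not self.concept_ids:
            raise ValueError("mention without concept ids")

    @property
    def ambiguous(self) -> bool:
        return len(self.concept_ids) > 1

    @property
    def sentence_key(self) -> tuple[str, str, int]:
        return (self.pmid, self.section.value, self.sentence_index)


@dataclass(frozen=True)
class MatcherIndex:
    """Compiled multi-pattern index for one entity class.

    ``patterns`` maps each normalized dictionary term to the sorted tuple
    of concept ids it can denote; ``max_tokens`` bounds the lookahead of
    the scanner.
    """

    entity_class: EntityClass
    patterns: dict[str, tuple[str, ...]] = field(default_factory=dict)
    max_tokens: int = 1


def compile_patterns(lex: Lexicon, stopwords: frozenset[str] | set[str] = frozenset()) -> MatcherIndex:
    """Compile a curated lexicon into a scanning index.

    Every normalized term that is not a stop word and is at least three
    characters long becomes a pattern keyed to the union of its concept
    ids.
    """
    if not lex.entries:
        raise ValueError("cannot compile an empty lexicon")
    stop = frozenset(stopwords)
    patterns: dict[str, tuple[str, ...]] = {}
    max_tokens = 1
    for term, ids in lex.term_index().items():
        if not term or term in stop or len(term) < 3:
            continue
        patterns[term] = tuple(sorted(ids))
        max_tokens = max(max_tokens, term.count(" ") + 1)
    if not patterns:
        raise ValueError("no patterns survive stop-word filtering")
    return MatcherIndex(entity_class=lex.entity_class, patterns=patterns, max_tokens=max_tokens)


def tag_sentence(sentence: Sentence, index: MatcherIndex) -> list[Mention]:
    """Extract the leftmost-longest non-overlapping mention cover.

    The sentence is normalized with the same pipeline as the dictionary
    terms; matching happens in normalized space and spans are mapped back
    to original-sentence offsets through the normalization offset map.
    """
    norm = normalize_text(sentence.text)
    tokens = tokenize(norm.text)
    mentions: list[Mention] = []
    i = 0
    while i < len(tokens):
        matched = None
        for length in range(min(index.max_tokens, len(tokens) - i), 0, -1):
            start_off = tokens[i][1]
            last_tok, last_off = tokens[i + length - 1]
            end_off = last_off + len(last_tok)
            candidate = norm.text[start_off:end_off]
            ids = index.patterns.get(candidate)
            if ids is not None:
                matched = (length, start_off, end_off, ids)
                break
        if matched is None:
            i += 1
            continue
        length, start_off, end_off, ids = matched
        orig_start, orig_end = norm.original_span(start_off, end_off)
        mentions.append(
            Mention(
                pmid=sentence.pmid,
                section=sentence.section,
                sentence_index=sentence.index,
                char_start=orig_start,
                char_end=orig_end,
                surface=sentence.text[orig_start:orig_end],
                entity_class=index.entity_class,
                concept_ids=ids,
            )
        )
        i += length
    return mentions


def tag_corpus(
    docs: Iterable[Document],
    gene_index: MatcherIndex | None = None,
    disease_index: MatcherIndex | None = None,
) -> list[Mention]:
    """Tag all sentences of all documents with both entity classes.

    Gene and disease mentions are extracted independently, so a span may
    legitimately carry one mention of each class; within a class spans
    never overlap.
    """
    indexes = [ix for ix in (gene_index, disease_index) if ix is not None]
    if not indexes:
        raise ValueError("at least one compiled index is required")
    mentions: list[Mention] = []
    for doc in docs:
        for sentence in document_sentences(doc):
            for ix in indexes:
                mentions.extend(tag_sentence(sentence, ix))
    return mentions


def write_mentions_tsv(mentions: Sequence[Mention], path: str | Path) -> None:
    rows = [
        {
            "pmid": m.pmid,
            "section": m.section.value,
            "sentence_index": m.sentence_index,
            "char_start": m.char_start,
            "char_end": m.char_end,
            "surface": m.surface,
            "entity_class": m.entity_class.value,
            "concept_ids": ";".join(m.concept_ids),
            "ambiguous": int(m.ambiguous),
        }
        for m in mentions
    ]
    pd.DataFrame(
        rows,
        columns=[
            "pmid", "section", "sentence_index", "char_start", "char_end",
            "surface", "entity_class", "concept_ids", "ambiguous",
        ],
    ).to_csv(path, sep="\t", index=False)
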