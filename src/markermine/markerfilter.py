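"""Biomarker trigger filtering of gene and disease dictionaries.

A gene mentioned in the same sentence as a biomarker trigger term
("marker", "biomarker", "serum marker", ...) is very likely itself being
reported as a biomarker. This module finds the trigger-bearing sentences
of a corpus and restricts a dictionary to the concepts co-mentioned with
a trigger at least once, yielding the biomarker-specific gene and disease
dictionaries used by the downstream relation extraction. The trigger list
ships as an editable config file seeded with the MeSH "Biological
Markers" entry terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import Sentence
from .lexicon import Lexicon, normalize_term
from .ner import Mention
from .textnorm import normalize_text, tokenize

__all__ = ["TriggerList", "find_trigger_sentences", "filter_lexicon"]


@dataclass(frozen=True)
class TriggerList:
    """Normalized biomarker trigger terms."""

    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("trigger list is empty")
        bad = {t for t in self.terms if t != normalize_term(t)}
        if bad:
            raise ValueError(f"trigger terms not normalized: {sorted(bad)}")

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "TriggerList":
        return cls(frozenset(normalize_term(t) for t in terms if t.strip()))


def _contains_trigger(text: str, triggers: TriggerList, max_tokens: int) -> bool:
    """Token-boundary trigger search: "marker" hits "serum marker", not "remarkable"."""
    norm = normalize_text(text)
    tokens = tokenize(norm.text)
    for i in range(len(tokens)):
        for length in range(1, min(max_tokens, len(tokens) - i) + 1):
            start = tokens[i][1]
            last_tok, last_off = tokens[i + length - 1]
            if norm.text[start: last_off + len(last_tok)] in triggers.terms:
                return True
    return False


def find_trigger_sentences(
    sentences: Iterable[Sentence], triggers: TriggerList
) -> set[tuple[str, str, int]]:
    """Keys (pmid, section, index) of sentences containing a trigger term."""
    max_tokens = max(t.count(" ") + 1 for t in triggers.terms)
    return {
        s.key for s in sentences if _contains_trigger(s.text, triggers, max_tokens)
    }


def filter_lexicon(
    lex: Lexicon,
    mentions: Sequence[Mention],
    trigger_sentences: set[tuple[str, str, int]],
) -> Lexicon:
    """Restrict ``lex`` to concepts co-mentioned with a biomarker trigger.

    A single co-mention anywhere in the corpus suffices; all dictionary
    entries of a retained concept are preserved, so the filtered lexicon
    keeps full synonym coverage for the concepts it retains.
    """
    keep: set[str] = set()
    for mention in mentions:
        if mention.entity_class is not lex.entity_class:
            continue
        if mention.sentence_key in trigger_sentences:
            keep.update(cid for cid in mention.concept_ids if cid in lex.concepts)
    return lex.subset(keep)
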