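"""Tag a published abstract sentence with dictionary NER.

A small dictionary covering two entities is compiled into a matching
index; the tagger extracts the leftmost-longest matches at token
boundaries and normalizes each to its concept identifier.
"""

from markermine import Concept, EntityClass, Lexicon, TermEntry, compile_patterns, normalize_term
from markermine.corpus import Section, Sentence
from markermine.ner import tag_sentence


def lexicon(entity_class, terms):
    lex = Lexicon(entity_class=entity_class)
    for cid, term in terms:
        if cid not in lex.concepts:
            lex.add_concept(Concept(cid, term, entity_class))
        lex.add_entry(TermEntry(term, normalize_term(term), frozenset({cid})))
    return lex


genes = lexicon(EntityClass.GENE, [("gene:54474", "CK20")])
diseases = lexicon(EntityClass.DISEASE, [("disease:C1861305", "TCC")])

text = ("CK20 is an important biomarker that can be used to identify TCC "
        "in urine cytology smears.")
sentence = Sentence("17397492", Section.CONCLUSIONS, 0, text, 0, len(text))

for index in (compile_patterns(genes), compile_patterns(diseases)):
    for m in tag_sentence(sentence, index):
        print(
            f"[{m.char_start:>2}:{m.char_end:<2}] {m.surface!r} -> "
            f"{';'.join(m.concept_ids)} ({m.entity_class.value})"
        )
# Both mentions resolve to unique identifiers, so this sentence yields one
# disease-gene co-occurrence: (disease:C1861305, gene:54474).
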