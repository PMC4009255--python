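# markermine

Dictionary-based mining of **disease–biomarker associations** from
biomedical abstract corpora.

The biomedical literature reports thousands of candidate genomic
biomarkers, but the information is scattered across millions of
unstandardized abstracts. `markermine` implements a knowledge-driven
extraction workflow for researchers who want to turn an abstract corpus
into a ranked disease–biomarker knowledge base:

1. **Lexicon construction** — gene and disease dictionaries are merged
   from cross-referenced source vocabularies (NCBI Gene / HGNC / UniProt
   style exports for genes, UMLS-style exports restricted to disease
   semantic types for diseases) and curated with eight rules: minimum
   term length 3, diacritic folding, gene-symbol separator variants
   (`IL2` / `IL 2` / `IL(2)` / `IL-2`), Arabic↔Roman numeral variants,
   Greek letter name↔glyph variants, bracketed affix-label stripping,
   lowercasing, and punctuation removal. A user-editable blocklist drops
   overly general terms (DISEASE, SYNDROME, …).
2. **Named entity recognition** — each sentence is folded into the same
   canonical form as the dictionary terms and scanned with a
   leftmost-longest, token-boundary, non-overlapping matcher; every
   mention is normalized to its NCBI Gene id or UMLS CUI.
3. **Biomarker filtering** — the dictionaries are restricted to concepts
   co-mentioned in at least one sentence with a biomarker trigger term
   (seeded from the MeSH "Biological Markers" entry terms).
4. **Relation extraction and scoring** — a disease D and gene B are
   putatively associated when mentioned in the same sentence.
   Associations are ranked by a section-weighted inverse-document-
   frequency score over the corpus A of abstracts with co-occurrences:

   ```
   Score_DB   = idf(DB, A) · Σᵢ af(DB, Aᵢ)
   idf(DB, A) = log₁₀ ( |A| / |{a ∈ A : DB ∈ a}| )
   af(DB, Aᵢ) = f(DB, Aᵢ) / max { f(XY, Aᵢ) : XY ∈ Aᵢ }
   ```

   where `f(DB, Aᵢ)` counts the sentences of abstract `Aᵢ` containing
   the pair, weighted ×2 in the title or conclusions and ×1 in the body.

Everything is testable offline: a seeded fixture generator
(`markermine.fixtures`) produces synthetic lexicons and corpora with
exactly known planted mentions, pairs, and section placements.

## Worked example

Tag a published conclusions sentence with a two-entry dictionary
(`examples/02_tag_sentence.py`):

```text
[ 0:4 ] 'CK20' -> gene:54474 (GENE)
[60:63] 'TCC' -> disease:C1861305 (DISEASE)
```

Both mentions resolve to unique identifiers — CK20 to its NCBI Gene id,
TCC to its UMLS CUI — so the sentence yields the co-occurrence
(disease:C1861305, gene:54474) with section label CONCLUSIONS.

Rank associations on a synthetic corpus in which one pair is planted at
ten times the background rate (`examples/03_score_fixture_corpus.py`):

```text
200 abstracts, 450 planted pair sentences
disease            gene       n_abs    idf  af_sum   score
disease:C0900001   gene:1001     32  0.733  28.000  20.521
disease:C0900003   gene:1008      9  1.284   8.000  10.270
disease:C0900004   gene:1004      9  1.284   8.000  10.270
disease:C0900008   gene:1008      8  1.335   7.500  10.012
disease:C0900010   gene:1007     10  1.238   8.000   9.904
planted pair ('disease:C0900001', 'gene:1001') ranks #1
```

The planted pair appears in 32 abstracts: its summed normalized
frequency (af_sum 28.0) outweighs its reduced idf, putting it first with
about twice the score of the best background pair.

The other examples show lexicon merging/curation
(`examples/01_build_and_curate_lexicon.py`) and the full on-disk
pipeline with its run manifest (`examples/04_full_pipeline.py`).

## Command line

A thin CLI wraps the library:

```sh
markermine fixtures -o fix/                      # synthetic corpus + lexicons
markermine build-lexicon sources.tsv --entity-class GENE -o genes.tsv
markermine tag --corpus fix/corpus.tsv --gene-lexicon fix/lexicon_gene.tsv \
    --disease-lexicon fix/lexicon_disease.tsv -o mentions.tsv
markermine extract --mentions mentions.tsv -o cooccs.tsv
markermine score --cooccurrences cooccs.tsv -o associations.tsv
markermine run --config pipeline.yaml           # all stages + manifest
```

Corpus readers accept PubMed XML (`PubmedArticleSet`), MEDLINE nbib, and
a simple TSV fixture format (pmid, year, journal, title, body,
conclusions). Structured-abstract labels (CONCLUSION/CONCLUSIONS/
INTERPRETATION) route text to the conclusions section. For a real
MEDLINE study, the document selection this pipeline is designed for is a
PubMed query of the form
`("Biological Markers"[MeSH Terms]) AND (has abstract[text]) AND
(English[lang]) AND ("humans"[MeSH Terms])` with a publication-date
window; retrieval itself is outside the package.

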