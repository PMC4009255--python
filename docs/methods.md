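# Methods

## Overview

`markermine` extracts candidate disease–biomarker associations from a
corpus of biomedical abstracts in five stages: dictionary construction,
dictionary-based named entity recognition (NER), biomarker trigger
filtering, sentence-level co-occurrence extraction, and idf-weighted
scoring. The method is knowledge-driven throughout: there is no
statistical NER or syntactic relation extraction; precision comes from
curated dictionaries, topic-focused document selection, and the trigger
filter, and candidate associations are explicitly putative — a
co-mention is evidence, not proof, of a biomarker relationship.

## Dictionaries

A lexicon maps surface terms to concepts. Gene concepts carry NCBI Gene
integer identifiers (`gene:3934`), disease concepts UMLS CUIs
(`disease:C0022660`); genes and proteins are deliberately not
distinguished, since they largely share terminology. Disease concepts
are restricted to eight UMLS semantic types (T019, T020, T047, T048,
T050, T184, T190, T191 — congenital/acquired/anatomical abnormalities,
disease or syndrome, mental dysfunction, experimental disease models,
signs and symptoms, neoplastic processes).

**Source merging.** Source vocabularies arrive as generic TSV exports
(`source, source_id, term, xrefs[, semantic_type]`). Rows joined by
cross-references — transitively — collapse into one concept holding the
union of their terms; components are computed as connected components of
the cross-reference graph. Licensed raw formats (UMLS RRF, full NCBI
dumps) are intentionally out of scope; any vocabulary that can be
exported to the TSV shape can be merged. The concept identifier comes
from a designated primary source when present in the component (e.g.
the NCBI Gene row), otherwise from the lexicographically smallest
(source, source_id) key — a deterministic fallback for synthetic or
partial inputs.

**Curation rules.** Applied in this order per raw term:

1. bracketed prefix/suffix labels are stripped (`[X]Gastric neurosis` →
   `Gastric neurosis`);
2. terms whose stripped surface is shorter than 3 characters are
   removed — the threshold applies to the raw surface *before* variant
   generation, because the rule targets noisy 1–2 character source
   acronyms, not generated separator forms;
3. surface variants are generated (below);
4. every form is normalized: Unicode NFKD diacritic folding plus an
   explicit fold table for characters without ASCII decompositions,
   lowercasing, every punctuation character replaced by one space
   (preserving token boundaries: `hnf-3-gamma` → `hnf 3 gamma`),
   whitespace collapsed;
5. forms whose normalized text is empty, shorter than 3 characters, or
   in the blocklist are dropped;
6. duplicates are removed per (normalized form, concept).

Variant generation covers three surface phenomena. Gene-symbol acronyms
matching letters+digits spawn the four separator forms
(`IL2`, `IL 2`, `IL(2)`, `IL-2`). Standalone Arabic numeral tokens
valued 1–30 spawn Roman-numeral forms (`type 4` → `type IV`); the 1–30
cap avoids corrupting years and accession-like numbers, and both each
single numeral and the all-replaced form are generated for multi-number
terms. Spelled-out Greek letters and Greek glyphs are interconverted in
both directions (`HP1-alpha` ↔ `HP1-α`). Variant generation is
inflationary — the input term is always retained.

The blocklist replaces an external suppression tool with a user-editable
configuration file of normalized general terms (disease, syndrome,
disorder, …); it removes exact normalized matches only, never terms
that merely contain a blocked word.

**Statistics.** For a lexicon with term→concept index over distinct
normalized terms: *ambiguity* is the mean number of concepts per
distinct term and *variability* the mean number of distinct terms per
concept. Both are ≥ 1; good curation raises variability (more synonyms
per concept) without raising ambiguity.

## Corpus model

A document is an abstract split into **title**, **body**, and
**conclusions**. Conclusions are located through structured-abstract
labels only (CONCLUSION, CONCLUSIONS, INTERPRETATION — from PubMed XML
`AbstractText/@Label` attributes or inline `LABEL:` markers in
nbib/plain abstracts); unstructured abstracts are body-only. A
positional last-N-sentences heuristic was considered and rejected for
the default because it is not deterministic across writing styles;
label-based routing is exact and testable.

Sentence splitting is rule-based: split at runs of `.!?` followed by
whitespace and an uppercase letter or digit, guarded by an abbreviation
list (`i.e.`, `e.g.`, `Fig.`, `et al.`, `vs.`, …). A deterministic
splitter was chosen over a statistical model so that character offsets
— 0-based, half-open, per section — are bit-stable across environments;
sentence spans tile all non-whitespace section text.

## NER

The curated lexicon compiles into a pattern index: every normalized
term at least 3 characters long and not in a stop-word list maps to the
sorted tuple of its concept ids. A small English function-word stop list
ships as an editable config file.

Tagging normalizes the sentence with exactly the same folding pipeline
as the dictionary (with a character-level offset map back to the
original text) and scans left to right over token boundaries — in
normalized text, the single space is the only separator. At each token
position the longest matching pattern is taken and scanning resumes
after it, so mentions of one entity class never overlap; gene and
disease tagging run independently, so a span may carry one mention of
each class. Surface variability is handled entirely by dictionary
variant expansion plus normalization — matching itself is exact. An
edit-distance matcher was rejected: on 3-letter gene acronyms it would
explode ambiguity. A term shared by several concepts produces a single
mention flagged ambiguous, carrying every candidate id.

## Biomarker filtering

A sentence is a *trigger sentence* when it contains, at token
boundaries, a biomarker trigger term ("biomarker", "marker",
"serum marker", …; the shipped list is seeded from the MeSH "Biological
Markers" entry terms and user-editable — the original term set is not
published). A concept survives the filter when at least one of its
mentions falls in a trigger sentence (threshold 1: no minimum count is
stated anywhere, and the filter is a recall-oriented pre-selection);
all dictionary entries of surviving concepts are retained. The same
procedure applies to genes and diseases.

## Co-occurrence extraction and scoring

For each sentence, the distinct disease ids and distinct gene ids form
a Cartesian product of candidate pairs, deduplicated per sentence;
ambiguous mentions contribute each candidate concept once.

With A the set of abstracts containing at least one co-occurrence:

- `f(DB, Aᵢ)` — weighted count of sentences of abstract `Aᵢ` containing
  pair DB: weight 2 in title or conclusions, 1 in the body. Weighting is
  per sentence, not per section: a pair in two title sentences counts
  2 + 2. The section weight (default 2) and idf base (default 10) are
  configuration, not constants.
- `af(DB, Aᵢ) = f(DB, Aᵢ) / max{f(XY, Aᵢ)}` — normalized by the most
  frequent pair of the same abstract, so the top pair of every abstract
  has af exactly 1.
- `idf(DB, A) = log₁₀(|A| / n_abstracts(DB))` ≥ 0.
- `Score_DB = idf · Σᵢ af(DB, Aᵢ)`.

`|A|` defaults to the number of abstracts with co-occurrences and can be
overridden (e.g. to the full size of a document selection). `f` counts
co-occurring *sentences*, not mention-pair multiplicities within a
sentence, avoiding quadratic inflation when an entity is mentioned
repeatedly. Output is sorted by score descending with ties broken by
(abstract count descending, disease id, gene id) so the association
table is byte-reproducible. For the default base 10 the idf uses
`log10` directly, which keeps scores bit-identical to an independent
transcription of the formula.

The af sum accumulates over sorted values — summation order is fixed for
reproducibility; all weights are small integers, so `f` and `af` are
exact in floating point and `score = idf × af_sum` holds to < 1e-9.

## Synthetic fixtures

The generator emulates the *combinatorics* of a biomarker corpus, not
its prose: template sentences with a closed function-word vocabulary
embed planted gene and disease surfaces. Defaults, chosen once:

- section placement of planted pair sentences: 10% title, 85% body,
  5% conclusions — the distribution reported for a real biomarker
  corpus;
- per-pair sentence counts per abstract: Poisson at a configurable rate
  matrix (default 0.3);
- trigger terms included in a planted sentence with probability 0.5,
  exercising both branches of the biomarker filter;
- synthetic lexicons exhibit the curation phenomena: acronym symbols
  (`GF1`), Greek-suffixed synonyms (`GF1-alpha`), numbered disease
  names (Roman-variant cases), and one term deliberately shared between
  two gene concepts (ambiguity > 1; never planted in corpora).

The generator checks its templates against the lexicon patterns before
emitting, so planted mentions are exactly the recoverable mentions —
tests assert set equality, not overlap. Fixed seed gives byte-identical
output.

The **planted-signal design** (`planted_signal_spec`) plants one pair at
10× the background rate on a 10×10 entity grid over 200 abstracts
(rates 0.2 vs 0.02). The grid and corpus sizes keep every pair present
in only a small fraction of the co-occurring abstracts — the
document-frequency regime the idf weighting is designed for, where even
the most-reported association of a real corpus appears in on the order
of 2% of abstracts. In a tiny dense design (few entities, high rates)
the planted pair would dominate |A| and its idf would collapse toward
zero; that is a property of the score, not a defect of the
implementation.

What passing fixture tests does *not* show: robustness to real prose
(negation, coordination ellipsis, abbreviation definitions, hedging),
to noisy OCR text, or to dictionary gaps. Those failure modes require
annotated real corpora.

## Degenerate inputs and errors

Empty term → normalization error; empty lexicon → stats/compile error;
empty co-occurrence list → scoring error; empty corpus → the pipeline
writes zero-row outputs and a manifest rather than failing. Malformed
XML/nbib names the offending record. Co-occurrences spanning several
abstracts are rejected by the per-abstract frequency function.

## Known limitations

- Sentence co-occurrence over-generates: enumerated lists and
  comparative statements yield spurious pairs; syntactic filtering is
  out of scope.
- No abbreviation-definition detection or coreference; an acronym not
  in the dictionary is invisible.
- The trigger filter inherits the coverage of the trigger list.
- Corpus-scale published figures (hundreds of thousands of abstracts,
  dictionary sizes of specific 2013 vocabulary snapshots) are not
  reproducible here and are not targets of the test suite; tests run on
  worked sentences and seeded synthetic corpora (≤ 200 abstracts).
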