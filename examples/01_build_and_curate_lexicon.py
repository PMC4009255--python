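"""Build a gene lexicon from two cross-referenced source tables and curate it.

Two vocabulary exports describe the same gene (Lipocalin-2 / NGAL) under
different identifiers; cross-references collapse them into one concept.
Curation then folds case, diacritics and punctuation, drops too-short and
blocklisted terms, and generates separator/Greek/Roman variants.
"""

import pandas as pd

from markermine import EntityClass, curate, lexicon_stats, merge_sources
from markermine.lexicon import Lexicon

hgnc = pd.DataFrame(
    [("hgnc", "LCN2", "Lipocalin-2", "ncbi_gene:3934"),
     ("hgnc", "IL2", "IL2", "ncbi_gene:3558")],
    columns=["source", "source_id", "term", "xrefs"],
)
ncbi = pd.DataFrame(
    [("ncbi_gene", "3934", "NGAL", "hgnc:LCN2"),
     ("ncbi_gene", "3558", "interleukin 2", "hgnc:IL2")],
    columns=["source", "source_id", "term", "xrefs"],
)

merged = merge_sources([hgnc, ncbi], EntityClass.GENE, id_source="ncbi_gene")
print(f"{len(merged.concepts)} concepts from {len(hgnc) + len(ncbi)} source rows")

lex = Lexicon(entity_class=EntityClass.GENE, concepts=dict(merged.concepts))
for entry in curate(merged.entries, entity_class=EntityClass.GENE):
    lex.add_entry(entry)

for entry in sorted(lex.entries, key=lambda e: (min(e.concept_ids), e.normalized)):
    print(f"  {min(entry.concept_ids):<10} {entry.normalized!r:<18} ({entry.provenance.value})")

stats = lexicon_stats(lex)
print(
    f"ambiguity {stats.ambiguity:.2f} (concepts per term), "
    f"variability {stats.variability:.2f} (terms per concept)"
)
# Each gene now carries all its surface forms under one identifier, so a
# mention of any variant normalizes to the same concept downstream.
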