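"""End-to-end pipeline: lexicons -> NER -> trigger filter -> associations.

``run_pipeline`` wires the stages together under a single
:class:`PipelineConfig` and writes every intermediate and final table as
TSV plus a JSON manifest (config hash, input checksums, per-stage record
counts). Identical config and inputs produce byte-identical outputs; the
manifest makes that checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .corpus import bibliometrics, corpus_sentences, read_corpus
from .lexicon import (
    EntityClass,
    Lexicon,
    curate,
    lexicon_stats,
    merge_sources,
    read_lexicon_tsv,
    read_source_table,
    read_wordlist,
    write_lexicon_tsv,
)
from .markerfilter import TriggerList, filter_lexicon, find_trigger_sentences
from .ner import compile_patterns, tag_corpus, write_mentions_tsv
from .relext import (
    extract_cooccurrences,
    score_associations,
    specificity_profiles,
    write_associations_tsv,
    write_cooccurrences_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "default_wordlist_path"]


def default_wordlist_path(name: str) -> Path:
    """Path of a bundled config file: stopwords.txt, triggers.txt, blocklist.txt."""
    ref = resources.files("markermine.data") / name
    return Path(str(ref))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``gene_sources``/``disease_sources`` are source-vocabulary TSVs (or
    prebuilt lexicon TSVs via ``prebuilt=True``); ``corpus`` is the
    abstract corpus; the word-list paths default to the bundled files.
    ``section_weight`` is the title/conclusions multiplier for the
    within-abstract pair frequency and ``idf_base`` the logarithm base of
    the idf factor.
    """

    corpus: Path
    gene_sources: list[Path] = field(default_factory=list)
    disease_sources: list[Path] = field(default_factory=list)
    output_dir: Path = Path("markermine_out")
    corpus_format: str = "tsv"
    prebuilt: bool = False
    gene_id_source: str | None = None
    disease_id_source: str | None = None
    stopwords: Path | None = None
    triggers: Path | None = None
    blocklist: Path | None = None
    section_weight: float = 2.0
    idf_base: float = 10.0
    n_total_abstracts: int | None = None
    apply_marker_filter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.section_weight <= 0 or self.idf_base <= 0:
            raise ValueError("weights and idf base must be positive")
        for attr in ("corpus", "output_dir", "stopwords", "triggers", "blocklist"):
            value = getattr(self, attr)
            if value is not None:
                setattr(self, attr, Path(value))
        self.gene_sources = [Path(p) for p in self.gene_sources]
        self.disease_sources = [Path(p) for p in self.disease_sources]
        if self.stopwords is None:
            self.stopwords = default_wordlist_path("stopwords.txt")
        if self.triggers is None:
            self.triggers = default_wordlist_path("triggers.txt")
        if self.blocklist is None:
            self.blocklist = default_wordlist_path("blocklist.txt")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, Path):
                out[key] = str(value)
            elif isinstance(value, list):
                out[key] = [str(v) for v in value]
            else:
                out[key] = value
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_lexicon(
    config: PipelineConfig, entity_class: EntityClass, blocklist: frozenset[str]
) -> Lexicon:
    sources = (
        config.gene_sources if entity_class is EntityClass.GENE else config.disease_sources
    )
    if not sources:
        raise ValueError(f"no {entity_class.value.lower()} sources configured")
    if config.prebuilt:
        if len(sources) != 1:
            raise ValueError("prebuilt lexicons expect exactly one file per class")
        return read_lexicon_tsv(sources[0])
    id_source = (
        config.gene_id_source if entity_class is EntityClass.GENE else config.disease_id_source
    )
    tables = [read_source_table(p) for p in sources]
    merged = merge_sources(tables, entity_class, id_source=id_source)
    lex = Lexicon(entity_class=entity_class, concepts=dict(merged.concepts))
    for entry in curate(merged.entries, blocklist, entity_class):
        lex.add_entry(entry)
    return lex


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the run manifest.

    Stages: build-lexicon -> tag -> biomarker filter -> retag with the
    filtered dictionaries -> extract co-occurrences -> score -> report.
    Any stage failure aborts with the stage name in the exception.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "init"
    try:
        stage = "build-lexicon"
        blocklist = read_wordlist(config.blocklist)
        stopwords = read_wordlist(config.stopwords)
        gene_lex = _build_lexicon(config, EntityClass.GENE, blocklist)
        disease_lex = _build_lexicon(config, EntityClass.DISEASE, blocklist)
        for name, lex in (("gene", gene_lex), ("disease", disease_lex)):
            write_lexicon_tsv(lex, out / f"lexicon_{name}.tsv")
            (out / f"lexicon_{name}_stats.json").write_text(
                lexicon_stats(lex).to_json(), encoding="utf-8"
            )
        counts["gene_concepts"] = len(gene_lex.concepts)
        counts["disease_concepts"] = len(disease_lex.concepts)

        stage = "read-corpus"
        docs = read_corpus(config.corpus, config.corpus_format)
        counts["documents"] = len(docs)
        sentences = corpus_sentences(docs)
        counts["sentences"] = len(sentences)

        if not docs:
            logger.warning("empty corpus: writing zero-row outputs")
            _write_empty_outputs(out)
            manifest = _manifest(config, counts | {
                "mentions": 0, "cooccurrences": 0, "associations": 0,
            })
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
            return manifest

        stage = "tag"
        gene_index = compile_patterns(gene_lex, stopwords)
        disease_index = compile_patterns(disease_lex, stopwords)
        mentions = tag_corpus(docs, gene_index, disease_index)

        if config.apply_marker_filter:
            stage = "filter-biomarker"
            triggers = TriggerList(read_wordlist(config.triggers))
            trigger_keys = find_trigger_sentences(sentences, triggers)
            counts["trigger_sentences"] = len(trigger_keys)
            gene_lex = filter_lexicon(gene_lex, mentions, trigger_keys)
            disease_lex = filter_lexicon(disease_lex, mentions, trigger_keys)
            for name, lex in (("gene", gene_lex), ("disease", disease_lex)):
                write_lexicon_tsv(lex, out / f"lexicon_{name}_biomarker.tsv")
            counts["biomarker_gene_concepts"] = len(gene_lex.concepts)
            counts["biomarker_disease_concepts"] = len(disease_lex.concepts)
            stage = "tag"
            if gene_lex.entries and disease_lex.entries:
                gene_index = compile_patterns(gene_lex, stopwords)
                disease_index = compile_patterns(disease_lex, stopwords)
                mentions = tag_corpus(docs, gene_index, disease_index)
            else:
                mentions = []

        write_mentions_tsv(mentions, out / "mentions.tsv")
        counts["mentions"] = len(mentions)

        stage = "extract"
        cooccs = extract_cooccurrences(mentions)
        write_cooccurrences_tsv(cooccs, out / "cooccurrences.tsv")
        counts["cooccurrences"] = len(cooccs)

        stage = "score"
        if cooccs:
            records = score_associations(
                cooccs,
                n_total_abstracts=config.n_total_abstracts,
                section_weight=config.section_weight,
                idf_base=config.idf_base,
            )
        else:
            records = []
        disease_names = {c.concept_id: c.preferred_name for c in disease_lex.concepts.values()}
        gene_names = {c.concept_id: c.preferred_name for c in gene_lex.concepts.values()}
        write_associations_tsv(
            records, out / "associations.tsv",
            disease_names=disease_names, gene_names=gene_names,
        )
        counts["associations"] = len(records)

        stage = "report"
        per_year, per_journal = bibliometrics(docs, cooccs)
        per_year.to_csv(out / "publications_by_year.tsv", sep="\t", index=False)
        per_journal.to_csv(out / "journal_report.tsv", sep="\t", index=False)
        per_gene, per_disease = specificity_profiles(records)
        pd.DataFrame(
            sorted(per_gene.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["gene_id", "n_diseases"],
        ).to_csv(out / "diseases_per_gene.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(per_disease.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["disease_id", "n_genes"],
        ).to_csv(out / "genes_per_disease.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, count in sorted(counts.items()):
        logger.info("%s: %d", name, count)
    manifest = _manifest(config, counts)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest


def _write_empty_outputs(out: Path) -> None:
    from .ner import write_mentions_tsv as _wm

    _wm([], out / "mentions.tsv")
    write_cooccurrences_tsv([], out / "cooccurrences.tsv")
    write_associations_tsv([], out / "associations.tsv")
    pd.DataFrame(columns=["year", "n_publications", "n_journals"]).to_csv(
        out / "publications_by_year.tsv", sep="\t", index=False
    )


def _manifest(config: PipelineConfig, counts: dict[str, int]) -> dict:
    config_dict = config.to_dict()
    inputs = {}
    for path in [
        config.corpus, config.stopwords, config.triggers, config.blocklist,
        *config.gene_sources, *config.disease_sources,
    ]:
        path = Path(path)
        if path.exists():
            inputs[str(path)] = _sha256(path)
    return {
        "version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": inputs,
        "counts": counts,
    }
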