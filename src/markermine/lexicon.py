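"""Gene and disease dictionary construction, curation, and statistics.

A :class:`Lexicon` maps surface terms to uniquely identified concepts:
genes carry NCBI Gene integer ids (``gene:3934``), diseases carry UMLS
concept unique identifiers (``disease:C0022660``). Source vocabularies
(NCBI Gene, HGNC, UniProt, UMLS exports) are read from a generic TSV
format and merged through their cross-references, so that all synonymy
for one biological entity collapses into a single concept.

Curation implements eight rules that trade ambiguity against coverage:

1. terms shorter than three characters are dropped (acronym noise);
2. diacritics are folded to their base letters;
3. gene-symbol acronyms (letters + digits) spawn separator variants
   (``IL2`` / ``IL 2`` / ``IL(2)`` / ``IL-2``);
4. standalone Arabic numerals 1-30 spawn Roman-numeral variants
   (``type 4`` -> ``type IV``);
5. spelled-out Greek letters and Greek glyphs are interconverted
   (``HP1-alpha`` <-> ``HP1-α``);
6. bracketed prefix/suffix labels not used in natural language are
   stripped (``[X]Gastric neurosis`` -> ``Gastric neurosis``);
7. everything is lowercased;
8. punctuation is removed (replaced by spaces).

On top of the rules a user-editable blocklist removes overly general
terms (DISEASE, SYNDROME, ...) that would otherwise match everywhere.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .textnorm import normalize_text

logger = logging.getLogger(__name__)

__all__ = [
    "EntityClass",
    "Concept",
    "TermEntry",
    "Lexicon",
    "LexiconStats",
    "DISEASE_SEMANTIC_TYPES",
    "normalize_term",
    "strip_affix_labels",
    "generate_acronym_variants",
    "generate_numeral_variants",
    "generate_greek_variants",
    "generate_variants",
    "curate",
    "merge_sources",
    "lexicon_stats",
    "read_source_table",
    "read_wordlist",
    "read_lexicon_tsv",
    "write_lexicon_tsv",
]

#: UMLS semantic types admitted into the disease dictionary:
#: Congenital Abnormality, Acquired Abnormality, Disease or Syndrome,
#: Mental or Behavioral Dysfunction, Experimental Model of Disease,
#: Sign or Symptom, Anatomical Abnormality, Neoplastic Process.
DISEASE_SEMANTIC_TYPES = frozenset(
    {"T019", "T020", "T047", "T048", "T050", "T184", "T190", "T191"}
)


class EntityClass(str, Enum):
    GENE = "GENE"
    DISEASE = "DISEASE"

    @property
    def id_prefix(self) -> str:
        return "gene" if self is EntityClass.GENE else "disease"


class Provenance(str, Enum):
    SOURCE = "SOURCE"
    GENERATED_VARIANT = "GENERATED_VARIANT"


@dataclass(frozen=True)
class Concept:
    """A uniquely identified gene or disease."""

    concept_id: str
    preferred_name: str
    entity_class: EntityClass
    semantic_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        prefix = self.concept_id.split(":", 1)[0]
        if prefix != self.entity_class.id_prefix:
            raise ValueError(
                f"concept id {self.concept_id!r} inconsistent with "
                f"entity class {self.entity_class.value}"
            )
        bad = set(self.semantic_types) - DISEASE_SEMANTIC_TYPES
        if self.entity_class is EntityClass.DISEASE and bad:
            raise ValueError(f"unsupported disease semantic types: {sorted(bad)}")


@dataclass(frozen=True)
class TermEntry:
    """One surface term linked to one or more concepts."""

    surface: str
    normalized: str
    concept_ids: frozenset[str]
    provenance: Provenance = Provenance.SOURCE

    def __post_init__(self) -> None:
        if not self.concept_ids:
            raise ValueError(f"term {self.surface!r} has no concept ids")


@dataclass(frozen=True)
class LexiconStats:
    n_concepts: int
    n_terms: int
    ambiguity: float
    variability: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_concepts": self.n_concepts,
                "n_terms": self.n_terms,
                "ambiguity": self.ambiguity,
                "variability": self.variability,
            },
            indent=2,
        )


@dataclass
class Lexicon:
    """A term -> concept index for one entity class."""

    entity_class: EntityClass
    concepts: dict[str, Concept] = field(default_factory=dict)
    entries: list[TermEntry] = field(default_factory=list)

    def add_concept(self, concept: Concept) -> None:
        if concept.entity_class is not self.entity_class:
            raise ValueError("concept class does not match lexicon class")
        if concept.concept_id in self.concepts:
            raise ValueError(f"duplicate concept id {concept.concept_id}")
        self.concepts[concept.concept_id] = concept

    def add_entry(self, entry: TermEntry) -> None:
        missing = entry.concept_ids - self.concepts.keys()
        if missing:
            raise ValueError(f"entry references unknown concepts: {sorted(missing)}")
        self.entries.append(entry)

    def term_index(self) -> dict[str, frozenset[str]]:
        """Normalized term -> union of concept ids over all entries."""
        index: dict[str, set[str]] = {}
        for entry in self.entries:
            index.setdefault(entry.normalized, set()).update(entry.concept_ids)
        return {term: frozenset(ids) for term, ids in index.items()}

    def subset(self, concept_ids: Iterable[str]) -> "Lexicon":
        """The sub-lexicon for ``concept_ids``, entries retained in full."""
        keep = set(concept_ids)
        unknown = keep - self.concepts.keys()
        if unknown:
            raise KeyError(f"unknown concept ids: {sorted(unknown)}")
        sub = Lexicon(entity_class=self.entity_class)
        for cid in sorted(keep):
            sub.add_concept(self.concepts[cid])
        for entry in self.entries:
            kept_ids = entry.concept_ids & keep
            if kept_ids:
                sub.add_entry(
                    TermEntry(entry.surface, entry.normalized, frozenset(kept_ids), entry.provenance)
                )
        return sub


# ---------------------------------------------------------------------------
# curation rules
# ---------------------------------------------------------------------------


def normalize_term(term: str) -> str:
    """Fold a term to its canonical matching form (rules 2, 7, 8).

    Lowercase, diacritics folded, punctuation replaced by spaces,
    whitespace collapsed. Idempotent.
    """
    if not term:
        raise ValueError("cannot normalize an empty term")
    return normalize_text(term).text


_AFFIX_LABEL = re.compile(r"^\s*\[[^\[\]]*\]\s*|\s*\[[^\[\]]*\]\s*$")


def strip_affix_labels(term: str) -> str:
    """Remove bracketed prefix/suffix labels (rule 6).

    ``[X]Gastric neurosis`` and ``Leber Congenital Amaurosis
    [Disease/Finding]`` both reduce to the bare term.
    """
    prev = None
    while prev != term:
        prev = term
        term = _AFFIX_LABEL.sub("", term)
    return term.strip()


_ACRONYM = re.compile(r"^([A-Za-z]+)[ \-]?\(?(\d+)\)?$")


def generate_acronym_variants(symbol: str) -> set[str]:
    """Separator variants for letter+digit gene symbols (rule 3)."""
    m = _ACRONYM.match(symbol.strip())
    if not m:
        return {symbol}
    letters, digits = m.group(1), m.group(2)
    return {
        symbol,
        f"{letters}{digits}",
        f"{letters} {digits}",
        f"{letters}({digits})",
        f"{letters}-{digits}",
    }


_ROMAN = {
    1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII",
    8: "VIII", 9: "IX", 10: "X", 11: "XI", 12: "XII", 13: "XIII",
    14: "XIV", 15: "XV", 16: "XVI", 17: "XVII", 18: "XVIII", 19: "XIX",
    20: "XX", 21: "XXI", 22: "XXII", 23: "XXIII", 24: "XXIV", 25: "XXV",
    26: "XXVI", 27: "XXVII", 28: "XXVIII", 29: "XXIX", 30: "XXX",
}

_NUMBER_TOKEN = re.compile(r"(?<![0-9A-Za-z])([0-9]+)(?![0-9A-Za-z])")


def generate_numeral_variants(term: str) -> set[str]:
    """Roman-numeral variants for standalone Arabic numerals (rule 4).

    Only standalone tokens valued 1-30 convert; larger numbers (years,
    accession-like digits) are left alone.
    """
    variants = {term}
    matches = [
        m for m in _NUMBER_TOKEN.finditer(term) if int(m.group(1)) in _ROMAN
    ]
    if not matches:
        return variants
    for m in matches:  # each numeral replaced on its own
        roman = _ROMAN[int(m.group(1))]
        variants.add(term[: m.start(1)] + roman + term[m.end(1):])
    if len(matches) > 1:  # and all together
        out, last = [], 0
        for m in matches:
            out.append(term[last: m.start(1)])
            out.append(_ROMAN[int(m.group(1))])
            last = m.end(1)
        out.append(term[last:])
        variants.add("".join(out))
    return variants


_GREEK_NAMES = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "zeta": "ζ", "eta": "η", "theta": "θ", "iota": "ι", "kappa": "κ",
    "lambda": "λ", "mu": "μ", "nu": "ν", "xi": "ξ", "omicron": "ο",
    "pi": "π", "rho": "ρ", "sigma": "σ", "tau": "τ", "upsilon": "υ",
    "phi": "φ", "chi": "χ", "psi": "ψ", "omega": "ω",
}
_GLYPH_TO_NAME = {g: n for n, g in _GREEK_NAMES.items()}
_GLYPH_TO_NAME.update({g.upper(): n for n, g in _GREEK_NAMES.items()})
_GLYPH_TO_NAME["ς"] = "sigma"

_GREEK_NAME_RE = re.compile(
    r"(?<![A-Za-z])(" + "|".join(sorted(_GREEK_NAMES, key=len, reverse=True)) + r")(?![A-Za-z])",
    re.IGNORECASE,
)
_GREEK_GLYPH_RE = re.compile("[" + "".join(_GLYPH_TO_NAME) + "]")


def generate_greek_variants(term: str) -> set[str]:
    """Interconvert spelled-out Greek letters and glyphs (rule 5)."""
    variants = {term}
    if _GREEK_NAME_RE.search(term):
        variants.add(
            _GREEK_NAME_RE.sub(lambda m: _GREEK_NAMES[m.group(1).lower()], term)
        )
    if _GREEK_GLYPH_RE.search(term):
        variants.add(
            _GREEK_GLYPH_RE.sub(lambda m: _GLYPH_TO_NAME[m.group(0)], term)
        )
    return variants


def generate_variants(term: str, entity_class: EntityClass) -> set[str]:
    """All rule-based surface variants of ``term`` (term itself included)."""
    variants = {term}
    if entity_class is EntityClass.GENE:
        variants |= generate_acronym_variants(term)
    expanded = set(variants)
    for v in variants:
        expanded |= generate_numeral_variants(v)
    variants = expanded
    expanded = set(variants)
    for v in variants:
        expanded |= generate_greek_variants(v)
    return expanded


def curate(
    entries: Iterable[TermEntry],
    blocklist: frozenset[str] | set[str] = frozenset(),
    entity_class: EntityClass = EntityClass.GENE,
    *,
    expand_variants: bool = True,
) -> list[TermEntry]:
    """Apply the curation rules to a set of raw term entries.

    Bracketed affix labels are stripped first; surfaces shorter than three
    characters are removed; variants are generated; every surviving form
    is normalized; entries whose normalized form is in ``blocklist`` (or
    empties out) are removed. Output is deduplicated on
    (normalized, concept id) and deterministically ordered.
    """
    blocked = frozenset(blocklist)
    seen: dict[tuple[str, str], TermEntry] = {}
    out: list[TermEntry] = []
    for entry in entries:
        surface = strip_affix_labels(entry.surface)
        if len(surface) < 3:  # rule 1: raw surface, before variants
            continue
        forms = (
            generate_variants(surface, entity_class) if expand_variants else {surface}
        )
        # the source surface claims its normalized form before variants
        for form in [surface] + sorted(forms - {surface}):
            norm = normalize_text(form).text
            if not norm or len(norm) < 3 or norm in blocked:
                continue
            provenance = entry.provenance if form == surface else Provenance.GENERATED_VARIANT
            for cid in sorted(entry.concept_ids):
                key = (norm, cid)
                if key in seen:
                    continue
                new = TermEntry(form, norm, frozenset({cid}), provenance)
                seen[key] = new
                out.append(new)
    return out


# ---------------------------------------------------------------------------
# source merging
# ---------------------------------------------------------------------------


def merge_sources(
    tables: Sequence[pd.DataFrame],
    entity_class: EntityClass,
    *,
    id_source: str | None = None,
) -> Lexicon:
    """Integrate source vocabularies into one lexicon via cross-references.

    Each table carries columns ``source``, ``source_id``, ``term``,
    ``xrefs`` (semicolon-separated ``source:source_id`` keys, may be
    empty) and optionally ``semantic_type``. Rows connected through
    cross-references — transitively — collapse into a single concept
    carrying the union of their terms; unlinked rows become singleton
    concepts. Conflicting links simply enlarge the connected component
    (logged).

    ``id_source`` names the vocabulary whose identifier becomes the
    concept id (e.g. ``"ncbi_gene"``); components without a row from it
    fall back to the smallest (source, source_id) key.
    """
    rows = pd.concat(tables, ignore_index=True) if len(tables) > 1 else tables[0].copy()
    required = {"source", "source_id", "term"}
    if missing := required - set(rows.columns):
        raise ValueError(f"source table missing columns: {sorted(missing)}")
    rows["key"] = rows["source"].astype(str) + ":" + rows["source_id"].astype(str)

    graph = nx.Graph()
    graph.add_nodes_from(rows["key"])
    for key, xrefs in zip(rows["key"], rows.get("xrefs", pd.Series([""] * len(rows)))):
        for ref in str(xrefs or "").split(";"):
            ref = ref.strip()
            if not ref:
                continue
            if ref in graph and graph.degree(ref) > 0 and not graph.has_edge(key, ref):
                logger.debug("cross-reference %s -> %s joins existing component", key, ref)
            graph.add_edge(key, ref)

    lex = Lexicon(entity_class=entity_class)
    by_key = {k: g for k, g in rows.groupby("key", sort=False)}
    for component in sorted(nx.connected_components(graph), key=min):
        member_rows = [by_key[k] for k in sorted(component) if k in by_key]
        if not member_rows:
            continue  # component made only of dangling xref targets
        members = pd.concat(member_rows)
        primary = members[members["source"] == id_source] if id_source else members.iloc[0:0]
        anchor = primary.iloc[0] if len(primary) else members.sort_values(["source", "source_id"]).iloc[0]
        concept_id = f"{entity_class.id_prefix}:{anchor['source_id']}"
        sem_types: tuple[str, ...] = ()
        if "semantic_type" in members.columns:
            sem_types = tuple(
                sorted({t for t in members["semantic_type"].dropna().astype(str) if t})
            )
        if concept_id in lex.concepts:
            raise ValueError(f"identifier collision across components: {concept_id}")
        lex.add_concept(
            Concept(concept_id, str(anchor["term"]), entity_class, sem_types)
        )
        for term in dict.fromkeys(members["term"].astype(str)):  # preserve order, dedupe
            lex.add_entry(
                TermEntry(term, normalize_text(term).text, frozenset({concept_id}))
            )
    return lex


def lexicon_stats(lex: Lexicon) -> LexiconStats:
    """Concept/term counts plus ambiguity and variability.

    Ambiguity is the mean number of concepts per distinct normalized
    term; variability is the mean number of distinct normalized terms per
    concept. Both are 1.0 for a perfectly unambiguous one-term-per-concept
    dictionary and grow with synonymy sharing and synonym richness.
    """
    if not lex.concepts or not lex.entries:
        raise ValueError("cannot compute statistics of an empty lexicon")
    index = lex.term_index()
    ambiguity = sum(len(ids) for ids in index.values()) / len(index)
    per_concept: dict[str, set[str]] = {cid: set() for cid in lex.concepts}
    for term, ids in index.items():
        for cid in ids:
            per_concept[cid].add(term)
    concepts_with_terms = [terms for terms in per_concept.values() if terms]
    variability = sum(len(t) for t in concepts_with_terms) / len(concepts_with_terms)
    return LexiconStats(
        n_concepts=len(lex.concepts),
        n_terms=len(index),
        ambiguity=ambiguity,
        variability=variability,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_source_table(path: str | Path) -> pd.DataFrame:
    """Read a source vocabulary TSV (source, source_id, term, xrefs[, semantic_type])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"source", "source_id", "term"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_wordlist(path: str | Path, *, normalize: bool = True) -> frozenset[str]:
    """Read a one-term-per-line UTF-8 word list (stop words, triggers, blocklist)."""
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        terms.add(normalize_text(line).text if normalize else line)
    return frozenset(terms)


def write_lexicon_tsv(lex: Lexicon, path: str | Path) -> None:
    rows = []
    for entry in lex.entries:
        for cid in sorted(entry.concept_ids):
            concept = lex.concepts[cid]
            rows.append(
                {
                    "concept_id": cid,
                    "entity_class": concept.entity_class.value,
                    "preferred_name": concept.preferred_name,
                    "normalized_term": entry.normalized,
                    "surface_term": entry.surface,
                    "provenance": entry.provenance.value,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "concept_id", "entity_class", "preferred_name",
            "normalized_term", "surface_term", "provenance",
        ],
    ).sort_values(["concept_id", "normalized_term", "surface_term"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_lexicon_tsv(path: str | Path) -> Lexicon:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty lexicon file")
    classes = set(df["entity_class"])
    if len(classes) != 1:
        raise ValueError(f"{path}: mixed entity classes {sorted(classes)}")
    lex = Lexicon(entity_class=EntityClass(classes.pop()))
    for cid, group in df.groupby("concept_id", sort=True):
        lex.add_concept(
            Concept(cid, group["preferred_name"].iloc[0], lex.entity_class)
        )
    for _, row in df.iterrows():
        lex.add_entry(
            TermEntry(
                row["surface_term"],
                row["normalized_term"],
                frozenset({row["concept_id"]}),
                Provenance(row["provenance"]),
            )
        )
    return lex
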