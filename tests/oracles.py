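"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the tagger oracle
enumerates every boundary-respecting match and applies greedy
leftmost-longest selection over the enumeration; the scoring oracle
transcribes the score definition with plain dict loops; the union-find
oracle recomputes cross-reference components without graph libraries.
"""

from __future__ import annotations

import math


def brute_force_tag(normalized_sentence: str, patterns: dict) -> list[tuple[int, int, str]]:
    """All-substring enumeration + greedy leftmost-longest selection.

    Works on an already-normalized sentence (single spaces). Returns
    (start_token, end_token, pattern) triples of the selected cover.
    """
    tokens = normalized_sentence.split(" ") if normalized_sentence else []
    tokens = [t for t in tokens if t]
    matches = []
    for i in range(len(tokens)):
        for j in range(i + 1, len(tokens) + 1):
            candidate = " ".join(tokens[i:j])
            if candidate in patterns:
                matches.append((i, j, candidate))
    selected = []
    pos = 0
    while pos < len(tokens):
        here = [m for m in matches if m[0] == pos]
        if not here:
            pos += 1
            continue
        best = max(here, key=lambda m: m[1] - m[0])
        selected.append(best)
        pos = best[1]
    return selected


def brute_force_scores(
    sentence_pairs: list[tuple[str, str, int, str, str]],
    *,
    n_total_abstracts: int | None = None,
    title_conclusion_weight: float = 2.0,
) -> dict[tuple[str, str], dict]:
    """Direct transcription of the association score definition.

    ``sentence_pairs`` holds (pmid, section, sentence_index, disease,
    gene) tuples, one per pair per sentence. Returns per-pair dicts with
    n_abstracts, idf, af_sum and score.
    """
    abstracts: dict[str, set] = {}
    for pmid, section, sent_idx, disease, gene in sentence_pairs:
        abstracts.setdefault(pmid, set()).add((section, sent_idx, disease, gene))

    # f(XY, A_i): weighted sentence count of each pair in each abstract
    f: dict[str, dict[tuple[str, str], float]] = {}
    for pmid, items in abstracts.items():
        f[pmid] = {}
        for section, _sent_idx, disease, gene in items:
            w = title_conclusion_weight if section in ("TITLE", "CONCLUSIONS") else 1.0
            f[pmid][(disease, gene)] = f[pmid].get((disease, gene), 0.0) + w

    n_total = len(abstracts) if n_total_abstracts is None else n_total_abstracts
    all_pairs = {pair for per_abs in f.values() for pair in per_abs}
    out = {}
    for pair in all_pairs:
        containing = [pmid for pmid in f if pair in f[pmid]]
        idf = math.log10(n_total / len(containing))
        af_sum = 0.0
        for pmid in sorted(containing):
            af_sum += f[pmid][pair] / max(f[pmid].values())
        out[pair] = {
            "n_abstracts": len(containing),
            "idf": idf,
            "af_sum": af_sum,
            "score": idf * af_sum,
        }
    return out


def union_find_components(nodes: list, edges: list[tuple]) -> list[frozenset]:
    """Connected components by plain union-find."""
    parent = {n: n for n in nodes}
    for a, b in edges:
        parent.setdefault(a, a)
        parent.setdefault(b, b)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in parent:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]
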