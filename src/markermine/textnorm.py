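"""Canonical text normalization shared by the lexicon and the NER engine.

Dictionary terms and sentence text must be folded into exactly the same
canonical form, otherwise a curated term can never match its own mention.
The folding pipeline is:

1. diacritic folding (``à ö ç û`` -> ``a o c u``) via Unicode NFKD
   decomposition, dropping combining marks;
2. lowercasing;
3. every punctuation character replaced by a single space, so token
   boundaries survive (``hnf-3-gamma`` -> ``hnf 3 gamma``);
4. whitespace runs collapsed to single spaces, ends stripped.

:class:`NormalizedText` additionally keeps a character-level offset map so
that a match found in the normalized string can be reported as a span in
the original sentence.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

__all__ = ["NormalizedText", "normalize_text", "tokenize"]

# Explicit folds for characters whose NFKD decomposition does not yield a
# plain ASCII base letter (NFKD handles à/ö/ç/û and friends already).
_EXTRA_FOLDS = {
    "ß": "ss",
    "æ": "ae",
    "œ": "oe",
    "ø": "o",
    "đ": "d",
    "ð": "d",
    "þ": "th",
    "ł": "l",
    "ı": "i",
    "’": "'",  # still punctuation, but fold curly to straight first
    "‘": "'",
    "“": '"',
    "”": '"',
    "–": "-",
    "—": "-",
}


def _fold_char(ch: str) -> str:
    """Fold one original character to its canonical lowercase form.

    Returns a (possibly empty or multi-character) replacement string in
    which every character is either alphanumeric or a single space.
    """
    out: list[str] = []
    for part in unicodedata.normalize("NFKD", ch):
        if unicodedata.combining(part):
            continue
        for lowered in part.lower():
            for low in _EXTRA_FOLDS.get(lowered, lowered):
                if low.isalnum():
                    out.append(low)
                else:
                    # punctuation, symbols and whitespace all become a
                    # space so token boundaries are preserved
                    out.append(" ")
    return "".join(out)


@dataclass(frozen=True)
class NormalizedText:
    """A normalized string plus a map back to the original text.

    ``starts[i]``/``ends[i]`` give the half-open span in the original
    string that produced normalized character ``i``.
    """

    original: str
    text: str
    starts: tuple[int, ...]
    ends: tuple[int, ...]

    def original_span(self, norm_start: int, norm_end: int) -> tuple[int, int]:
        """Map a half-open span in the normalized text to original offsets."""
        if not (0 <= norm_start < norm_end <= len(self.text)):
            raise IndexError(f"span ({norm_start}, {norm_end}) out of range")
        return self.starts[norm_start], self.ends[norm_end - 1]


def normalize_text(text: str) -> NormalizedText:
    """Normalize ``text`` keeping the character offset map."""
    chars: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for i, ch in enumerate(text):
        for folded in _fold_char(ch):
            chars.append(folded)
            starts.append(i)
            ends.append(i + 1)

    # collapse whitespace runs; drop leading/trailing space
    out_chars: list[str] = []
    out_starts: list[int] = []
    out_ends: list[int] = []
    pending_space = False
    for ch, s, e in zip(chars, starts, ends):
        if ch == " ":
            pending_space = bool(out_chars)
            continue
        if pending_space:
            # the space inherits the gap between surrounding characters
            out_chars.append(" ")
            out_starts.append(out_ends[-1])
            out_ends.append(s)
            pending_space = False
        out_chars.append(ch)
        out_starts.append(s)
        out_ends.append(e)

    return NormalizedText(
        original=text,
        text="".join(out_chars),
        starts=tuple(out_starts),
        ends=tuple(out_ends),
    )


def tokenize(normalized: str) -> list[tuple[str, int]]:
    """Split an already-normalized string into (token, start-offset) pairs.

    In normalized text the only separator is the single space, so token
    boundaries are exactly the alphanumeric/space transitions.
    """
    tokens: list[tuple[str, int]] = []
    pos = 0
    for tok in normalized.split(" "):
        if tok:
            tokens.append((tok, pos))
        pos += len(tok) + 1
    return tokens
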