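"""Phrase matching over triage chief-complaint text.

Matching is deliberately simple — no stemming, no parsing — to mirror a
transparent keyword-search process. Text and phrases are reduced to a common
canonical token stream: normalization (see :func:`wellsauto.lexicon.normalize_text`),
synonym folding of abbreviated surface forms ("l" -> "left", "b/l" ->
"bilateral", "le" -> "lower extremity"), and hyphen splitting ("blood-tinged"
== "blood tinged"). Matches are found greedily, longest phrase first, on token
boundaries, and never overlap.

Negation scoping is OFF by default: the validated process performed none, and
its false positives from phrases "preceded by words of negation" are part of
its measured behavior. ``negation_mode="window"`` enables a minimal NegEx-style
check as an explicit extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .lexicon import Lexicon, normalize_text

__all__ = ["Match", "match_phrases", "component_flag", "NEGATION_CUES", "NEGATION_WINDOW"]

NegationMode = Literal["off", "window"]

#: Cues that flag a following phrase as negated in ``window`` mode. Multi-word
#: cues must appear as consecutive tokens.
NEGATION_CUES: frozenset[tuple[str, ...]] = frozenset(
    {
        ("no",),
        ("denies",),
        ("denied",),
        ("without",),
        ("not",),
        ("neg", "for"),
        ("negative", "for"),
    }
)

#: Number of tokens preceding a match start searched for a negation cue.
NEGATION_WINDOW = 3


@dataclass(frozen=True)
class Match:
    """One lexicon hit in a normalized text.

    ``start``/``end`` are 0-based half-open character offsets into the
    *normalized* text; the covered span is a synonym-expanded surface form of
    ``phrase``.
    """

    phrase: str
    start: int
    end: int
    source_field: str = "chief_complaint"
    negated: bool = False


def _tokenize(normalized: str) -> list[tuple[str, int, int]]:
    """Split normalized text into (token, start, end) triples."""
    tokens = []
    pos = 0
    for tok in normalized.split(" "):
        if tok:
            tokens.append((tok, pos, pos + len(tok)))
        pos += len(tok) + 1
    return tokens


def _canonical_subtokens(token: str, synonym_map: dict[str, str]) -> list[str]:
    """Expand one surface token to its canonical subtoken sequence."""
    canonical = synonym_map.get(token, token)
    parts: list[str] = []
    for piece in canonical.split(" "):
        parts.extend(p for p in piece.split("-") if p)
    return parts or [canonical]


def _phrase_key(phrase: str, synonym_map: dict[str, str]) -> tuple[str, ...]:
    key: list[str] = []
    for tok, _, _ in _tokenize(normalize_text(phrase)):
        key.extend(_canonical_subtokens(tok, synonym_map))
    return tuple(key)


def match_phrases(
    text: str,
    lexicon: Lexicon,
    synonym_map: dict[str, str] | None = None,
    negation_mode: NegationMode = "off",
    source_field: str = "chief_complaint",
) -> list[Match]:
    """Find all lexicon phrases in ``text``.

    Returns non-overlapping matches chosen greedily left-to-right, preferring
    the longest phrase at each position. Matches align to token boundaries of
    the normalized text (no hits inside words). With
    ``negation_mode="window"`` a match is flagged negated when a negation cue
    ends within the :data:`NEGATION_WINDOW` tokens before it; with ``"off"``
    no match is ever flagged.
    """
    if synonym_map is None:
        synonym_map = lexicon.synonym_map
    else:
        synonym_map = {normalize_text(k): normalize_text(v) for k, v in synonym_map.items()}
    normalized = normalize_text(text)
    if not normalized or not lexicon.phrases:
        return []

    # Canonical phrase table; colliding phrases (same canonical form, e.g.
    # "pain in le" vs "pain in lower extremity") share a key — report the
    # lexicographically first for determinism.
    table: dict[tuple[str, ...], str] = {}
    for phrase in sorted(lexicon.phrases):
        table.setdefault(_phrase_key(phrase, synonym_map), phrase)
    max_len = max(len(k) for k in table)

    tokens = _tokenize(normalized)
    # Flat canonical subtoken stream; each entry remembers its source token and
    # whether it is the first/last subtoken of that token (matches must cover
    # whole source tokens).
    stream: list[tuple[str, int, bool, bool]] = []
    for ti, (tok, _, _) in enumerate(tokens):
        subs = _canonical_subtokens(tok, synonym_map)
        for si, sub in enumerate(subs):
            stream.append((sub, ti, si == 0, si == len(subs) - 1))

    matches: list[Match] = []
    i = 0
    while i < len(stream):
        found = None
        for length in range(min(max_len, len(stream) - i), 0, -1):
            window = tuple(s[0] for s in stream[i : i + length])
            if window in table and stream[i][2] and stream[i + length - 1][3]:
                found = (length, table[window])
                break
        if found is None:
            i += 1
            continue
        length, phrase = found
        first_tok = stream[i][1]
        last_tok = stream[i + length - 1][1]
        negated = negation_mode == "window" and _is_negated(tokens, first_tok)
        matches.append(
            Match(
                phrase=phrase,
                start=tokens[first_tok][1],
                end=tokens[last_tok][2],
                source_field=source_field,
                negated=negated,
            )
        )
        i += length
    return matches


def _is_negated(tokens: list[tuple[str, int, int]], match_token_index: int) -> bool:
    window_start = max(0, match_token_index - NEGATION_WINDOW)
    preceding = [t[0] for t in tokens[window_start:match_token_index]]
    for cue in NEGATION_CUES:
        n = len(cue)
        for j in range(len(preceding) - n + 1):
            if tuple(preceding[j : j + n]) == cue:
                return True
    return False


def component_flag(matches: Iterable[Match], negation_mode: NegationMode = "off") -> bool:
    """True iff at least one non-negated match supports the component.

    With ``negation_mode="off"`` every match counts as supporting evidence.
    """
    if negation_mode == "off":
        return any(True for _ in matches)
    return any(not m.negated for m in matches)
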