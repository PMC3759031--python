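"""Phoneme inventories, lexicons, and lexical competitor structure.

A lexicon here is a list of labelled phoneme strings over a finite phoneme
inventory. Spoken-word-recognition research characterises each word by the
competitor neighbourhoods that shape its recognition dynamics: onset (cohort)
competitors, rhymes, embedded words, embeddings, and deletion/addition/
substitution (DAS) neighbours. This module reads the plain-text file formats,
validates them, and computes those neighbourhoods plus a six-variable lexical
profile per word.

File formats
------------
Inventory: one phoneme symbol per line; blank lines and ``#`` comments ignored.
Lexicon: one word per line, ``label`` followed by whitespace-separated phoneme
symbols (symbols may be multi-character, e.g. ``^``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "PhonemeInventory",
    "Word",
    "Lexicon",
    "LexicalProfile",
    "LexiconError",
    "load_inventory",
    "load_lexicon",
    "embedded_words",
    "embeds_in",
    "cohorts",
    "das_neighbors",
    "rhymes",
    "profile",
    "profiles_table",
]


class LexiconError(ValueError):
    """Raised for malformed inventories or lexicons."""


@dataclass(frozen=True)
class PhonemeInventory:
    """Ordered alphabet of distinct phoneme symbols."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise LexiconError("inventory needs at least 2 phonemes")
        seen: set[str] = set()
        for i, s in enumerate(self.symbols):
            if not s:
                raise LexiconError(f"empty phoneme symbol at position {i + 1}")
            if s in seen:
                raise LexiconError(f"duplicate phoneme symbol {s!r}")
            seen.add(s)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(self.symbols)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}


class Word(NamedTuple):
    label: str
    phonemes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.phonemes)


class Lexicon:
    """A validated list of words over one inventory.

    Iterating yields :class:`Word` entries in file order; indexing by label
    returns the corresponding entry.
    """

    def __init__(self, entries: Iterable[Word], inventory: PhonemeInventory):
        self.inventory = inventory
        self.entries: list[Word] = []
        self._by_label: dict[str, Word] = {}
        for w in entries:
            w = Word(w.label, tuple(w.phonemes))
            if len(w.phonemes) < 1:
                raise LexiconError(f"word {w.label!r} has no phonemes")
            for p in w.phonemes:
                if p not in inventory:
                    raise LexiconError(
                        f"word {w.label!r} uses unknown phoneme {p!r}"
                    )
            if w.label in self._by_label:
                raise LexiconError(f"duplicate label {w.label!r}")
            self._by_label[w.label] = w
            self.entries.append(w)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, label: object) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> Word:
        return self._by_label[label]

    def word(self, target: "Word | str") -> Word:
        """Resolve a label or Word to the lexicon's entry."""
        if isinstance(target, Word):
            if target.label not in self._by_label:
                raise KeyError(target.label)
            return self._by_label[target.label]
        return self._by_label[target]


def load_inventory(path: str | Path) -> PhonemeInventory:
    """Read a phoneme inventory file (one symbol per line, '#' comments)."""
    symbols: list[str] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in seen:
            raise LexiconError(
                f"duplicate phoneme {line!r} on line {lineno} "
                f"(first seen on line {seen[line]})"
            )
        seen[line] = lineno
        symbols.append(line)
    return PhonemeInventory(tuple(symbols))


def load_lexicon(path: str | Path, inv: PhonemeInventory) -> Lexicon:
    """Read a lexicon file: ``label p1 p2 ...`` per line, validated against inv."""
    entries: list[Word] = []
    labels: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise LexiconError(f"line {lineno}: expected 'label phonemes...'")
        label, phonemes = fields[0], tuple(fields[1:])
        for p in phonemes:
            if p not in inv:
                raise LexiconError(
                    f"line {lineno}: unknown phoneme {p!r} in word {label!r}"
                )
        if label in labels:
            raise LexiconError(f"line {lineno}: duplicate label {label!r}")
        labels.add(label)
        entries.append(Word(label, phonemes))
    return Lexicon(entries, inv)


def _is_substring(needle: Sequence[str], hay: Sequence[str]) -> bool:
    n, h = len(needle), len(hay)
    if n > h:
        return False
    return any(tuple(hay[i : i + n]) == tuple(needle) for i in range(h - n + 1))


def embedded_words(target: Word | str, lex: Lexicon) -> list[Word]:
    """Words (other than the target) occurring as contiguous substrings of it."""
    t = lex.word(target)
    return [
        v
        for v in lex
        if v.label != t.label and _is_substring(v.phonemes, t.phonemes)
    ]


def embeds_in(target: Word | str, lex: Lexicon) -> list[Word]:
    """Words the target occurs in as a contiguous substring (converse of
    :func:`embedded_words`)."""
    t = lex.word(target)
    return [
        v
        for v in lex
        if v.label != t.label and _is_substring(t.phonemes, v.phonemes)
    ]


def cohorts(target: Word | str, lex: Lexicon) -> list[Word]:
    """Onset competitors: words sharing the target's first two phonemes.

    Single-phoneme targets have no cohort (empty list, not an error).
    """
    t = lex.word(target)
    if len(t.phonemes) < 2:
        return []
    onset = t.phonemes[:2]
    return [
        v
        for v in lex
        if v.label != t.label and len(v.phonemes) >= 2 and v.phonemes[:2] == onset
    ]


def _edit_distance_is_one(a: Sequence[str], b: Sequence[str]) -> bool:
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is a plus one inserted phoneme
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return tuple(a[i:]) == tuple(b[i + 1 :])


def das_neighbors(target: Word | str, lex: Lexicon) -> list[Word]:
    """Words at phoneme edit distance exactly 1 (deletion/addition/substitution)."""
    t = lex.word(target)
    return [
        v
        for v in lex
        if v.label != t.label and _edit_distance_is_one(t.phonemes, v.phonemes)
    ]


RhymeMode = Literal["strict", "overlap"]


def rhymes(
    target: Word | str, lex: Lexicon, mode: RhymeMode = "strict"
) -> list[Word]:
    """Rhyme competitors of the target.

    mode='strict': same length, identical except at the first phoneme (the
    one-mismatch rhyme class used for competitor time courses).
    mode='overlap': the strict set plus any word exactly equal to the target
    with its first phoneme removed (the looser count used for the lexical
    profile).
    """
    t = lex.word(target)
    if len(t.phonemes) < 2:
        return []
    out = []
    tail = t.phonemes[1:]
    for v in lex:
        if v.label == t.label:
            continue
        strict = (
            len(v.phonemes) == len(t.phonemes)
            and v.phonemes[1:] == tail
            and v.phonemes[0] != t.phonemes[0]
        )
        if strict:
            out.append(v)
        elif mode == "overlap" and v.phonemes == tail:
            out.append(v)
    return out


@dataclass(frozen=True)
class LexicalProfile:
    """The six lexical variables correlated with recognition time.

    Counts are raw; ``embeddings_log`` and ``rhyme_log`` are ``log(1 + n)``
    (natural log) so that zero counts are representable.
    """

    label: str
    length: int
    embedded_count: int
    embeddings_log: float
    cohort_count: int
    das_neighbor_count: int
    rhyme_log: float


def profile(target: Word | str, lex: Lexicon) -> LexicalProfile:
    """Assemble the six-variable lexical profile of a word."""
    t = lex.word(target)
    return LexicalProfile(
        label=t.label,
        length=len(t.phonemes),
        embedded_count=len(embedded_words(t, lex)),
        embeddings_log=math.log1p(len(embeds_in(t, lex))),
        cohort_count=len(cohorts(t, lex)),
        das_neighbor_count=len(das_neighbors(t, lex)),
        rhyme_log=math.log1p(len(rhymes(t, lex, mode="overlap"))),
    )


def profiles_table(lex: Lexicon) -> pd.DataFrame:
    """One row per word, one column per lexical variable (CSV-exportable)."""
    rows = [profile(w, lex).__dict__ for w in lex]
    return pd.DataFrame(rows).set_index("label")
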