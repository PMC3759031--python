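"""Deterministic synthetic inventories and lexicons with planted structure.

Real phonological lexicons mix several competitor relations that matter for
recognition dynamics: anadrome pairs (same phonemes, reversed order — the
temporal-order discrimination case), onset-embedded pairs (a word plus the
same word extended by one phoneme, the classic confusion direction), words
with repeated phonemes (the multi-token independence case), strict rhyme
pairs, and cohort families sharing their first two phonemes. The generator
plants a requested number of each structure in an otherwise random lexicon
and returns ground-truth annotations for every planted pair, so detector code
can be validated without any external word list.

Limitations relative to real lexicons: uniform phoneme usage (no phonotactics),
no word frequency, and length distributions chosen for presentability within
the input bank rather than realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import Lexicon, PhonemeInventory, Word

__all__ = ["FixtureRecipe", "SynthesisError", "generate", "write_fixture"]


class SynthesisError(ValueError):
    """Raised when a recipe's planted structures cannot be realised."""


@dataclass(frozen=True)
class FixtureRecipe:
    """What to plant. ``n_words`` includes the planted words; the remainder
    are random fillers. Word lengths stay within ``length_range`` (and must
    not exceed the input bank the consumer plans to use, default 10)."""

    seed: int = 0
    inventory_size: int = 10
    n_words: int = 30
    length_range: tuple[int, int] = (3, 6)
    n_anadrome_pairs: int = 1
    n_embedding_pairs: int = 1
    n_repeated_phoneme_words: int = 1
    n_rhyme_pairs: int = 1
    n_cohort_families: int = 1
    cohort_family_size: int = 3

    def planted_word_count(self) -> int:
        return (
            2 * self.n_anadrome_pairs
            + 2 * self.n_embedding_pairs
            + self.n_repeated_phoneme_words
            + 2 * self.n_rhyme_pairs
            + self.n_cohort_families * self.cohort_family_size
        )

    def validate(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise SynthesisError("invalid length_range")
        if self.inventory_size < 3:
            raise SynthesisError("inventory_size must be >= 3")
        if self.planted_word_count() > self.n_words:
            raise SynthesisError(
                f"planted structures need {self.planted_word_count()} words "
                f"but n_words = {self.n_words}"
            )
        if self.n_anadrome_pairs and hi < 2:
            raise SynthesisError("anadrome pairs need length >= 2")
        if self.n_anadrome_pairs and self.inventory_size < lo:
            raise SynthesisError(
                "anadrome words need distinct phonemes: inventory too small"
            )
        if self.n_embedding_pairs and hi < 2:
            raise SynthesisError("embedding pairs need length >= 2")
        if self.n_repeated_phoneme_words and hi < 3:
            raise SynthesisError("repeated-phoneme words need length >= 3")
        if self.n_rhyme_pairs and hi < 2:
            raise SynthesisError("rhyme pairs need length >= 2")
        if self.n_cohort_families and hi < 3:
            raise SynthesisError("cohort families need length >= 3")
        if self.n_cohort_families and self.cohort_family_size < 2:
            raise SynthesisError("cohort families need size >= 2")


def _symbols(n: int) -> tuple[str, ...]:
    letters = "abcdefghijklmnopqrstuvwxyz"
    if n <= len(letters):
        return tuple(letters[:n])
    return tuple(f"p{i}" for i in range(n))


def generate(
    recipe: FixtureRecipe,
) -> tuple[PhonemeInventory, Lexicon, pd.DataFrame]:
    """Build (inventory, lexicon, annotations) from a recipe, reproducibly.

    Annotations have columns ``word_a``, ``word_b``, ``relation`` with one row
    per planted pair; relations are ``anadrome``, ``embedding`` (word_a is
    embedded in word_b), ``rhyme`` (strict), ``cohort``, and ``repeated``
    (word_b empty) for planted repeated-phoneme words.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    inv = PhonemeInventory(_symbols(recipe.inventory_size))
    syms = list(inv.symbols)
    lo, hi = recipe.length_range

    forms: dict[tuple[str, ...], str] = {}  # phoneme string -> label
    words: list[Word] = []
    annotations: list[dict] = []

    def add(phonemes: tuple[str, ...]) -> str:
        label = f"w{len(words):03d}"
        forms[phonemes] = label
        words.append(Word(label, phonemes))
        return label

    def fresh(make, what: str, tries: int = 2000):
        for _ in range(tries):
            form = make()
            if form is not None and tuple(form) not in forms:
                return tuple(form)
        raise SynthesisError(f"could not realise a fresh {what} "
                             f"(inventory or length budget too tight)")

    def rand_word(length: int) -> list[str]:
        return [syms[i] for i in rng.integers(0, len(syms), size=length)]

    for _ in range(recipe.n_anadrome_pairs):
        def make_anadrome():
            length = int(rng.integers(max(lo, 2), hi + 1))
            form = list(rng.choice(len(syms), size=length, replace=False))
            form = [syms[i] for i in form]
            if form == form[::-1] or tuple(form[::-1]) in forms:
                return None
            return form
        a = fresh(make_anadrome, "anadrome pair")
        la, lb = add(a), add(a[::-1])
        annotations.append({"word_a": la, "word_b": lb, "relation": "anadrome"})

    for _ in range(recipe.n_embedding_pairs):
        def make_base():
            length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            length = min(length, hi - 1) if hi > lo else max(lo - 1, 1)
            if length < 1:
                return None
            form = rand_word(length)
            ext = form + [syms[int(rng.integers(0, len(syms)))]]
            if tuple(ext) in forms:
                return None
            return form
        base = fresh(make_base, "embedding pair")
        ext = fresh(
            lambda: list(base) + [syms[int(rng.integers(0, len(syms)))]],
            "embedding extension",
        )
        la, lb = add(base), add(ext)
        annotations.append({"word_a": la, "word_b": lb, "relation": "embedding"})

    for _ in range(recipe.n_repeated_phoneme_words):
        def make_repeated():
            length = int(rng.integers(max(lo, 3), hi + 1))
            form = rand_word(length)
            form[-1] = form[0]  # pXp shape: first phoneme recurs at the end
            if len(set(form[1:-1]) | {form[0]}) < 2:
                return None
            return form
        form = fresh(make_repeated, "repeated-phoneme word")
        label = add(form)
        annotations.append({"word_a": label, "word_b": "", "relation": "repeated"})

    for _ in range(recipe.n_rhyme_pairs):
        def make_rhyme_base():
            length = int(rng.integers(max(lo, 2), hi + 1))
            return rand_word(length)
        base = fresh(make_rhyme_base, "rhyme pair")

        def make_rhyme_partner():
            alt = [s for s in syms if s != base[0]]
            form = list(base)
            form[0] = alt[int(rng.integers(0, len(alt)))]
            return form
        partner = fresh(make_rhyme_partner, "rhyme partner")
        la, lb = add(base), add(partner)
        annotations.append({"word_a": la, "word_b": lb, "relation": "rhyme"})

    for _ in range(recipe.n_cohort_families):
        onset = [syms[int(rng.integers(0, len(syms)))] for _ in range(2)]
        members: list[str] = []
        for _ in range(recipe.cohort_family_size):
            def make_member():
                length = int(rng.integers(max(lo, 3), hi + 1))
                form = onset + rand_word(length - 2)
                return form
            members.append(add(fresh(make_member, "cohort member")))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                annotations.append(
                    {"word_a": members[i], "word_b": members[j],
                     "relation": "cohort"}
                )

    while len(words) < recipe.n_words:
        add(fresh(lambda: rand_word(int(rng.integers(lo, hi + 1))), "filler"))

    lexicon = Lexicon(words, inv)
    ann = pd.DataFrame(annotations, columns=["word_a", "word_b", "relation"])
    return inv, lexicon, ann


def write_fixture(
    recipe: FixtureRecipe, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write inventory, lexicon, and annotations files for a recipe.

    Output is byte-identical for identical recipes (sorted, newline-
    terminated plain text), so fixtures can be regenerated anywhere.
    """
    inv, lex, ann = generate(recipe)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inv_path = out / "inventory.txt"
    lex_path = out / "lexicon.txt"
    ann_path = out / "annotations.csv"
    inv_path.write_text("".join(f"{s}\n" for s in inv.symbols))
    lex_path.write_text(
        "".join(f"{w.label} {' '.join(w.phonemes)}\n" for w in lex)
    )
    ann.to_csv(ann_path, index=False)
    return inv_path, lex_path, ann_path
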