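"""Lexicon IO and competitor-neighbourhood detectors."""

import math

import numpy as np
import pytest

from tisk.lexicon import (
    Lexicon,
    LexiconError,
    PhonemeInventory,
    Word,
    cohorts,
    das_neighbors,
    embedded_words,
    embeds_in,
    load_inventory,
    load_lexicon,
    profile,
    profiles_table,
    rhymes,
)
from tisk.synth import FixtureRecipe, generate

from conftest import TRACE14


def lex_of(*forms: str) -> Lexicon:
    """Tiny lexicon from letter strings (labels equal the strings)."""
    symbols = tuple(sorted({c for f in forms for c in f}))
    inv = PhonemeInventory(symbols if len(symbols) > 1 else symbols + ("?",))
    return Lexicon([Word(f, tuple(f)) for f in forms], inv)


def labels(words) -> set[str]:
    return {w.label for w in words}


class TestInventoryIO:
    def test_roundtrip_with_comments(self, tmp_path):
        p = tmp_path / "inv.txt"
        p.write_text("# comment\na\n\nb\n")
        inv = load_inventory(p)
        assert inv.symbols == ("a", "b")

    def test_duplicate_symbol_names_line(self, tmp_path):
        p = tmp_path / "inv.txt"
        p.write_text("a\na\n")
        with pytest.raises(LexiconError, match="'a'.*line 2"):
            load_inventory(p)

    def test_canonical_14_phoneme_inventory(self, tmp_path):
        p = tmp_path / "inv.txt"
        p.write_text("".join(f"{s}\n" for s in TRACE14))
        assert len(load_inventory(p)) == 14


class TestLexiconIO:
    def test_basic_entry(self, tmp_path):
        inv = PhonemeInventory(("d", "a", "g"))
        p = tmp_path / "lex.txt"
        p.write_text("dog d a g\n")
        lex = load_lexicon(p, inv)
        assert len(lex) == 1 and lex["dog"].phonemes == ("d", "a", "g")

    def test_unknown_phoneme_names_line(self, tmp_path):
        inv = PhonemeInventory(("d", "a", "g"))
        p = tmp_path / "lex.txt"
        p.write_text("dog d a x\n")
        with pytest.raises(LexiconError, match="line 1.*'x'"):
            load_lexicon(p, inv)

    def test_duplicate_label_rejected(self, tmp_path):
        inv = PhonemeInventory(("d", "a", "g"))
        p = tmp_path / "lex.txt"
        p.write_text("dog d a g\ndog g a d\n")
        with pytest.raises(LexiconError, match="duplicate label"):
            load_lexicon(p, inv)

    def test_multicharacter_symbols(self, tmp_path):
        inv = PhonemeInventory(("^", "S", "t"))
        p = tmp_path / "lex.txt"
        p.write_text("shut S ^ t\n")
        lex = load_lexicon(p, inv)
        assert lex["shut"].phonemes == ("S", "^", "t")

    def test_full_scale_word_count(self, tmp_path):
        # a 212-entry lexicon file loads to exactly 212 validated entries
        rng = np.random.default_rng(0)
        inv = PhonemeInventory(TRACE14)
        lines, seen = [], set()
        while len(lines) < 212:
            form = tuple(rng.choice(TRACE14, size=rng.integers(2, 8)))
            if form not in seen:
                seen.add(form)
                lines.append(f"w{len(lines)} {' '.join(form)}\n")
        p = tmp_path / "lex.txt"
        p.write_text("".join(lines))
        assert len(load_lexicon(p, inv)) == 212


class TestEmbedding:
    def test_contiguous_substrings_only(self):
        lex = lex_of("abc", "ab", "bc", "ac")
        assert labels(embedded_words("abc", lex)) == {"ab", "bc"}

    def test_single_phoneme_target_embeds_nothing(self):
        lex = lex_of("a", "ab")
        assert embedded_words("a", lex) == []

    def test_internal_embedding_detected(self):
        # a short word inside a longer carrier, off the onset
        inv = PhonemeInventory(tuple("spiker"))
        lex = Lexicon(
            [Word("spiker", tuple("spiker")), Word("pi", ("p", "i"))], inv
        )
        assert labels(embedded_words("spiker", lex)) == {"pi"}

    def test_embeds_in_counterpart(self):
        lex = lex_of("ab", "abc", "ba")
        assert labels(embeds_in("ab", lex)) == {"abc"}
        assert embeds_in("abc", lex) == []

    def test_converse_relation_exhaustive(self, random_fixture):
        _, lex, _ = random_fixture
        for w in lex:
            for v in embedded_words(w, lex):
                assert w.label in labels(embeds_in(v, lex))
            for v in embeds_in(w, lex):
                assert w.label in labels(embedded_words(v, lex))


class TestCohortsAndRhymes:
    def test_cohort_shares_first_two(self):
        lex = lex_of("dag", "dagz", "dak", "gad")
        assert labels(cohorts("dag", lex)) == {"dagz", "dak"}

    def test_single_phoneme_has_no_cohort(self):
        lex = lex_of("d", "da")
        assert cohorts("d", lex) == []

    def test_embedded_cohort_pair_is_mutual(self, embedding_lexicon):
        _, lex = embedding_lexicon
        assert "triti" in labels(cohorts("trit", lex))
        assert "trit" in labels(cohorts("triti", lex))

    def test_strict_rhyme_requires_equal_length(self):
        inv = PhonemeInventory(tuple("bspiker"))
        lex = Lexicon(
            [Word("biker", tuple("biker")), Word("spiker", tuple("spiker"))],
            inv,
        )
        assert rhymes("biker", lex, mode="strict") == []

    def test_one_mismatch_rhyme(self):
        lex = lex_of("dag", "gag")
        assert labels(rhymes("dag", lex, mode="strict")) == {"gag"}

    def test_overlap_mode_adds_tail_word(self):
        lex = lex_of("dag", "ag", "gag")
        assert labels(rhymes("dag", lex, mode="overlap")) == {"gag", "ag"}
        assert labels(rhymes("dag", lex, mode="strict")) == {"gag"}

    def test_rhymes_and_cohorts_disjoint_when_onsets_differ(self, random_fixture):
        _, lex, _ = random_fixture
        for w in lex:
            strict = labels(rhymes(w, lex, mode="strict"))
            coh = labels(cohorts(w, lex))
            # a strict rhyme differs at phoneme 1, a cohort matches it
            assert not strict & coh


class TestNeighbors:
    def test_das_kinds(self):
        lex = lex_of("ab", "b", "abc", "ba")
        assert labels(das_neighbors("ab", lex)) == {"b", "abc"}

    def test_empty_lexicon_like_case(self):
        lex = lex_of("ab")
        assert das_neighbors("ab", lex) == []

    def test_against_bruteforce_edit_distance(self):
        def lev(a, b):  # independent DP oracle
            m, n = len(a), len(b)
            D = np.zeros((m + 1, n + 1), dtype=int)
            D[:, 0] = np.arange(m + 1)
            D[0, :] = np.arange(n + 1)
            for i in range(1, m + 1):
                for j in range(1, n + 1):
                    D[i, j] = min(
                        D[i - 1, j] + 1,
                        D[i, j - 1] + 1,
                        D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                    )
            return D[m, n]

        rng = np.random.default_rng(11)
        syms = tuple("abcde")
        forms = set()
        while len(forms) < 40:
            forms.add(tuple(rng.choice(syms, size=rng.integers(1, 6))))
        inv = PhonemeInventory(syms)
        lex = Lexicon(
            [Word("".join(f) + str(i), f) for i, f in enumerate(forms)], inv
        )
        for w in lex:
            got = labels(das_neighbors(w, lex))
            want = {
                v.label
                for v in lex
                if v.label != w.label and lev(w.phonemes, v.phonemes) == 1
            }
            assert got == want


class TestProfile:
    def test_isolated_word_all_zero(self):
        inv = PhonemeInventory(tuple("abcxyz"))
        lex = Lexicon(
            [Word("abc", tuple("abc")), Word("xyz", tuple("xyz"))], inv
        )
        p = profile("abc", lex)
        assert (p.embedded_count, p.cohort_count, p.das_neighbor_count) == (0, 0, 0)
        assert p.embeddings_log == 0.0 and p.rhyme_log == 0.0
        assert p.length == 3

    def test_irreflexive_everywhere(self, random_fixture):
        _, lex, _ = random_fixture
        for w in lex:
            for fn in (embedded_words, embeds_in, cohorts, das_neighbors):
                assert w.label not in labels(fn(w, lex))
            assert w.label not in labels(rhymes(w, lex, mode="overlap"))

    def test_profile_matches_bruteforce_on_random_lexicons(self):
        rng = np.random.default_rng(3)
        syms = tuple("abcdefg")
        inv = PhonemeInventory(syms)
        for _ in range(60):
            forms = set()
            while len(forms) < 12:
                forms.add(tuple(rng.choice(syms, size=rng.integers(1, 6))))
            lex = Lexicon(
                [Word(f"w{i}", f) for i, f in enumerate(sorted(forms))], inv
            )
            for w in lex:
                p = profile(w, lex)
                others = [v for v in lex if v.label != w.label]
                sub = lambda a, b: any(  # noqa: E731
                    b[i : i + len(a)] == a for i in range(len(b) - len(a) + 1)
                )
                assert p.embedded_count == sum(
                    sub(v.phonemes, w.phonemes) for v in others
                )
                assert p.embeddings_log == math.log1p(
                    sum(sub(w.phonemes, v.phonemes) for v in others)
                )
                assert p.cohort_count == sum(
                    len(v) >= 2
                    and len(w.phonemes) >= 2
                    and v.phonemes[:2] == w.phonemes[:2]
                    for v in others
                )
                n_rhyme = sum(
                    (
                        len(v) == len(w)
                        and v.phonemes[1:] == w.phonemes[1:]
                        and v.phonemes[0] != w.phonemes[0]
                    )
                    or v.phonemes == w.phonemes[1:]
                    for v in others
                ) if len(w.phonemes) >= 2 else 0
                assert p.rhyme_log == math.log1p(n_rhyme)

    def test_profiles_table_shape(self, random_fixture):
        _, lex, _ = random_fixture
        table = profiles_table(lex)
        assert len(table) == len(lex)
        assert set(table.columns) == {
            "length",
            "embedded_count",
            "embeddings_log",
            "cohort_count",
            "das_neighbor_count",
            "rhyme_log",
        }
        assert (table[["length", "embedded_count", "cohort_count",
                       "das_neighbor_count"]] >= 0).all().all()
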