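"""Write a reproducible synthetic inventory/lexicon/annotations fixture.

The generator plants controlled competitor structure — anadrome pairs,
embedding pairs, repeated-phoneme words, strict-rhyme pairs, cohort
families — and records every planted pair, so detector code can be checked
against ground truth.
"""

import tempfile
from pathlib import Path

from tisk import FixtureRecipe, load_inventory, load_lexicon, write_fixture

recipe = FixtureRecipe(seed=42, inventory_size=12, n_words=30,
                       n_anadrome_pairs=2, n_rhyme_pairs=2)
out = Path(tempfile.mkdtemp(prefix="tisk_fixture_"))
inv_path, lex_path, ann_path = write_fixture(recipe, out)
print(f"wrote {inv_path}\n      {lex_path}\n      {ann_path}\n")

inv = load_inventory(inv_path)
lex = load_lexicon(lex_path, inv)
print(f"reloaded: {len(inv)} phonemes, {len(lex)} words")
print("first lexicon lines:")
print("\n".join(lex_path.read_text().splitlines()[:6]))
print("\nannotations:")
print(ann_path.read_text())

# Identical recipes produce byte-identical files, so fixtures never need to
# be stored — they are regenerated from the (seed, recipe) pair on demand.
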