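"""Unit and connection budgets: time-invariant vs. fully reduplicated.

Computes the closed-form cost of both architectures for the canonical sizing
assumptions (200 input slices = 2 s of echoic memory, mean word length 4) and
a slice of the scaling surface over lexicon size.
"""

from tisk import ArchitectureSpec, count_resources, scaling_surface

print(f"{'model':6s} {'words':>6s} {'phon':>5s} {'units':>10s} {'connections':>14s}")
for words, phonemes in [(212, 14), (212, 40), (20000, 40)]:
    for model in ("trace", "tisk"):
        rc = count_resources(ArchitectureSpec(model, words, phonemes, 200))
        print(f"{model:6s} {words:6d} {phonemes:5d} {rc.units:10,d} "
              f"{rc.connections:14,d}")

rc = count_resources(ArchitectureSpec("tisk", 212, 14, 200))
print("\nper-component connection breakdown (tisk, 212 words, 14 phonemes):")
for name, n in rc.connection_breakdown.items():
    print(f"  {name:14s} {n:12,d}")

print("\nconnection cost over lexicon size (200 slices, 14 phonemes):")
surface = {
    model: scaling_surface(model, [212, 1000, 5000, 20000], [200])
    for model in ("tisk", "trace")
}
for w in (212, 1000, 5000, 20000):
    t, tr = surface["tisk"].loc[w, 200], surface["trace"].loc[w, 200]
    print(f"  W={w:6d}:  tisk {t:15,d}   trace {tr:15,d}   ratio {tr / t:6.1f}x")

# Unit totals are exact; connection totals are documented estimates (see
# docs/methods.md). The decisive pattern: both models are quadratic in
# lexicon size, but only the reduplicated model multiplies that quadratic
# term by the number of time slices.
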