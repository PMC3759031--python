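"""Encode a phoneme sequence into time-invariant nphone units.

Shows the string-kernel code: which phone and ordered-diphone units a spoken
word activates, and the raw symmetry-network input each one received. The
anadrome pair dog/god demonstrates that order is preserved without
time-specific diphone units.
"""

from tisk import active_nphones, build_weights, deliver

weights = build_weights(T=10)

for word in [("d", "a", "g"), ("g", "a", "d"), ("b", "a", "b")]:
    name = "".join(word)
    active = active_nphones(word, weights)
    delivered = deliver(word, weights)
    phones = sorted("".join(u) for u in active if len(u) == 1)
    diphones = sorted("".join(u) for u in active if len(u) == 2)
    print(f"/{name}/")
    print(f"  active phones:   {phones}")
    print(f"  active diphones: {diphones}")
    supra = {u: v for u, v in delivered.items()
             if len(u) == 2 and v > weights.theta}
    print(f"  delivered input (supra-threshold, theta={weights.theta:.0f}): "
          + ", ".join(f"{''.join(u)}={v:.0f}" for u, v in sorted(supra.items())))

# Each diphone present in the sequence exceeds the threshold theta = T-1;
# anadromes of presented pairs (e.g. /ad/ for dog) stay at or below it, so
# dog and god get disjoint diphone codes. The repeated /b/ in /bab/ activates
# /bb/ but, thanks to gating, no diphone pairing /b/ with an unseen phoneme.
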