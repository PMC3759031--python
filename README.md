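# tisk — time-invariant string-kernel model of spoken word recognition

Spoken words unfold in time, and a model of spoken word recognition must
encode *order* (/dag/ is not /gad/), handle *repeated* phonemes (/dud/ has
two /d/ events), and do both for every position a word can occupy in the
input stream. The classic interactive-activation solution reduplicates every
phoneme and word detector at every time slice, which costs millions of units
and billions of connections at realistic scale. This package implements the
alternative: keep a small bank of time-specific phoneme *inputs*, but make
everything above it **time-invariant** by encoding sequences as string
kernels — the set of ordered phoneme pairs ("open diphones") a word
contains — computed by a symmetry network with gating connections.

The model has three layers:

- a T-slice input bank (one unit per phoneme per slice, at most one active
  at a time);
- an **nphone layer** of P single-phone plus P² ordered-diphone units. The
  input-to-diphone weights depend only on slice and role, not phoneme
  identity: `w_first(t) = T − t`, `w_second(t) = t − 1`. Presenting adjacent
  phonemes /a/ₜ, /b/ₜ₊₁ therefore delivers a constant total `T` to /ab/ and
  `T − 2` to /ba/ at **every** t, so a strict threshold `θ = T − 1`
  recognises /ab/ and never its anadrome. Gating connections keep repeated
  phonemes from activating spurious diphones; the resulting supra-threshold
  set is exactly `{(sᵢ, sⱼ) : i < j}`, the ordered-pair string kernel;
- a **word layer** (one unit per word) driven by its nphones with weights
  normalised by the word's nphone count, competing through lateral
  inhibition.

All units are leaky integrators,

    Aᵢ(t) = Aᵢ(t−1)(1 − decay) + Netᵢ(t)·(1 − Aᵢ(t−1))   if Netᵢ > 0
    Aᵢ(t) = Aᵢ(t−1)(1 − decay) + Netᵢ(t)·Aᵢ(t−1)         if Netᵢ ≤ 0

with `Netᵢ = Σⱼ wᵢⱼ Aⱼ(t−1)`, activations clamped to [0, 1]. Recognition is
scored three ways: absolute threshold, relative margin over the runner-up,
and sustained strict dominance for a fixed dwell (the default analysis
criterion). The package also computes the six lexical variables that predict
recognition time (length, embedded words, embeddings, DAS neighbours,
cohorts, rhymes), class-averaged competitor time courses, and closed-form
unit/connection budgets for both this architecture and the fully
reduplicated one.

## Worked example

```python
from tisk import (PhonemeInventory, Lexicon, Word, TiskNetwork,
                  RecognitionCriterion, recognize)

inv = PhonemeInventory(("d", "a", "g"))
lex = Lexicon([Word("dag", ("d", "a", "g")), Word("gad", ("g", "a", "d"))], inv)
net = TiskNetwork(inv, lex)

traj = net.run_trial("dag")
r = recognize(traj, RecognitionCriterion(kind="time"))
print(r.recognized, r.cycle)          # -> dag 15
print(round(traj.word_activation("dag")[19], 3),
      round(traj.word_activation("gad")[19], 3))   # -> 0.836 0.644
```

The two words share all three phones, so their activations tie until the
first ordered diphone (/da/) crosses threshold at the second phoneme; from
then on the word matching the presented order strictly dominates and is
recognised at cycle 15 — the anadrome is never confused with it. The
`examples/` directory holds one short script per capability (encoding,
single trials, whole-lexicon batches with RT–lexicon correlations,
competitor curves, resource budgets, fixture generation, and the protocol
for running a full externally supplied lexicon); each prints the numbers it
computes and a line on what they mean.

## Resource accounting

```python
from tisk import ArchitectureSpec, count_units
count_units(ArchitectureSpec("tisk", words=212, phonemes=14, slices=200))
# -> 3222   (= 200·14 input + 14² + 14 nphone + 212 word units)
```

Unit totals are exact closed forms. Connection totals are documented
per-component estimates (see `docs/methods.md`): the decisive scaling fact
is that both architectures are quadratic in lexicon size, but only the
reduplicated one multiplies that term by the number of time slices.

## Acceptance script

`scripts/acceptance.py` recomputes the headline unit-count figures from
scratch by running the package's counting formulas at the canonical sizing
assumptions and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/tisk/lexicon.py` — inventories, lexicons, competitor neighbourhoods
- `src/tisk/encoder.py` — symmetry network, gating, string-kernel code
- `src/tisk/dynamics.py` — leaky-integrator network and trials
- `src/tisk/recognition.py` — the three recognition criteria
- `src/tisk/experiments.py` — batches, competitor curves, RT correlations
- `src/tisk/resources.py` — unit/connection cost formulas
- `src/tisk/synth.py` — synthetic lexicons with planted structure
- `src/tisk/config.py` — run configs, CSV writers, logging
- `docs/methods.md` — model assumptions, calibration, known limitations
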