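# Methods

## Model

The model maps a temporal stream of phonemes onto a time-invariant lexical
code in three stages.

**Input bank.** T time slices × P phonemes of localist input units (default
T = 10, the minimum that fits the classic small lexicons). During a trial,
phoneme i of the word is clamped to 1 for cycles [(i−1)·d, i·d) with d =
`clamp_cycles`; at most one input unit is ever active, inputs are orthogonal
and carry no phonetic similarity. These time-specific nodes are a
computational convenience (an analogue of echoic memory), not a theoretical
commitment.

**Symmetry-network encoder.** The nphone layer holds P single-phone units
and P² ordered-diphone units. Input→diphone weights depend only on slice and
role: `w_first(t) = T − t` for the diphone's first position, `w_second(t) =
t − 1` for its second, with strict activation threshold `θ = T − 1`. The two
weight symmetries (identity-invariance within a slice; central symmetry
`w_first(t) = w_second(T − t + 1)`) make the total delivered input to a
diphone depend only on the *relative* order of its phonemes: an adjacent
pair delivers T to the matching diphone and T − 2 to its anadrome at every
alignment, and a pair at lag k delivers a matching-minus-anadrome separation
of 2k.

Repeated phonemes require gating. Two trial-scoped rules are used:

1. only the **first** token of a phoneme contributes in first position
   (later tokens' first-position connections are disabled once the phoneme
   has occurred);
2. the **most recent** token of a phoneme replaces, rather than adds to, its
   second-position contribution.

With both rules the accumulated input to diphone (p, q) is
`(T − t_first(p)) + (t_last(q) − 1)`, which strictly exceeds θ exactly when
some token of p precedes some token of q. The supra-threshold diphone set
therefore *equals* the ordered-pair string kernel {(sᵢ, sⱼ) : i < j} for
arbitrary sequences, slices and repetition patterns — this is proved by the
inequality above and verified exhaustively in the tests. Simpler one-rule
gating schemes were rejected because each admits counterexamples: gating
only first-position connections lets several pre-p tokens of q sum their
second-position contributions into a spurious /pq/ (e.g. x,y,q,q,p);
gating only second-position connections fails the motivating repeated-onset
case (b,a,b spuriously activating /b?/ diphones). Gating is implemented as
trial-scoped state, equivalent to explicit gating units; the physical
O(S²) connection count is still what the resource module bills.

**Dynamics.** Every nphone and word unit is a leaky integrator (rest 0,
clamped to [0, 1], synchronous update from the previous cycle's
activations). External drive: a phone unit receives `gain_input` while its
phoneme's input unit is clamped; a diphone receives
`gain_input · delivered/T` from the cycle its accumulated evidence exceeds θ
until the end of the stimulus. The graded (rather than flat) supra-threshold
drive follows from treating the delivered total as the unit's net input once
the threshold gate opens; it matters behaviorally, because diphones spanning
a word's full extent carry slightly more evidence and are what lets a long
word overtake words embedded inside it. Words receive
`gain_word · Σ A_nphone / |nphones(word)|` over their string-kernel support
(normalisation by the destination word's nphone count, so a fully supported
word of any length sums to the gain), plus lateral inhibition from words
sharing at least one nphone (a config switch restricts the inhibitory
neighbourhood to shared diphones). Nphone lateral inhibition is all-pairs.
There is no word→nphone feedback and no stochastic element: trajectories are
bit-deterministic.

## Parameters

| name | default | meaning |
|---|---|---|
| `T` | 10 | input-bank slices; maximum presentable word length |
| `clamp_cycles` (d) | 5 | cycles each phoneme's input unit stays clamped |
| `max_cycles` | 100 | trial length |
| `decay_nphone` / `decay_word` | 0.02 / 0.05 | leak per cycle |
| `gain_input` | 0.3 | input→nphone drive scale |
| `gain_word` | 0.4 | nphone→word gain (per-word normalised) |
| `inhibition_nphone` | −0.002 | nphone lateral inhibition |
| `inhibition_word` | −0.02 | word lateral inhibition |
| `absolute_threshold` | 0.5 | recognition criterion θ_abs |
| `margin` / `dwell` | 0.05 / 10 | relative margin; dominance dwell cycles |

The margin (0.05) and dwell (10 cycles) are the published criterion
settings. The remaining dynamics values are free parameters of this
implementation (the original supplemental parameter list is not available
here); they were calibrated **once** against qualitative targets — anadrome
pairs recognised correctly in both directions under the dwell criterion,
the canonical competitor-curve ordering, the longer member of an
onset-embedding pair being the harder one, and recognition times in the
tens of cycles with d = 5 — and then frozen. Faster gains shorten the
window in which a fully-contained competitor leads; decays set how long
sublexical evidence persists after stimulus offset.

## Recognition criteria

Absolute: first cycle any word reaches θ_abs. Relative: first cycle the
leader exceeds the runner-up by ≥ margin. Time: last cycle of the first run
of `dwell` consecutive cycles of strict dominance by one word. Exact ties
never satisfy "exceeds". Failure within `max_cycles` is a value, not an
error, and the recognised word may differ from the presented one — accuracy
is judged downstream, preserving the model's characteristic confusions.

## Experiments

`run_batch` runs one trial per word and scores every criterion on the same
trajectory; accuracy is the percentage of correct trials and mean
recognition cycles are computed over correct trials only.
`competitor_timecourse` averages word-unit activation per cycle across
correctly recognised targets for the classes cohort (first two phonemes
shared), strict rhyme (all but the first phoneme shared, same length),
embedded-in-target (contiguous substring), and the mean of all words
(including the target) as baseline; classes empty for a target are skipped.
`rt_correlations` computes Pearson r (Spearman optional) between recognition
cycles and the six lexical variables, over correct trials; zero-variance
variables yield NaN (undefined, not zero). Log-transformed counts use
natural `log(1+n)` so zero counts are representable; the base only rescales
correlations.

The "rhymes" lexical count is ambiguous between strict same-length rhymes
and any word equal to the target minus its first phoneme; both readings are
implemented (`mode="strict"` / `mode="overlap"`), with `overlap` used in the
profile and `strict` for competitor classes.

## Resource accounting

Unit counts are exact: `S·P + (P² + P) + W` for the time-invariant model and
`round((P + W)·S/3)` for the reduplicated one (phoneme and word detectors
duplicated every third slice; nearest-integer rounding is the only
convention consistent with the published unit figures, e.g. 226·200/3 →
15,067). Connection counts are per-component estimates documented in
`resources.py`; the exact published counting appendices are not available
to this implementation, so the totals land near (within a few percent of,
not equal to) the published figures for the small configurations, and the
tests assert the scaling structure instead: gating quadratic in S, both
models quadratic in W, the reduplicated model's quadratic-in-W term
multiplied by S, and the time-invariant surface strictly below the
reduplicated one over the canonical grid. When a concrete lexicon is
supplied, the feedforward and word-lateral terms are computed exactly from
its string-kernel supports.

## Synthetic lexicons

`synth.generate` plants a requested number of anadrome pairs, one-phoneme
onset-embedding pairs, repeated-phoneme (pXp) words, strict-rhyme pairs and
cohort families in an otherwise random lexicon, with ground-truth
annotations for every planted pair; a single integer seed drives all
randomness and identical recipes write byte-identical files. The generator
emulates competitor *structure*, not natural language: phoneme usage is
uniform (no phonotactics), there are no word frequencies, and 30 words over
10 phonemes is far denser than a natural lexicon — so whole-lexicon accuracy
on generated fixtures sits well below the published full-scale figures by
design, and a green batch test establishes the machinery and the planted
relations, not naturalistic accuracy levels.

## Numerical choices and degenerate inputs

Synchronous updates (all net inputs from cycle t−1) avoid order dependence;
activations are clamped to [0, 1] since the growth rule can otherwise
exceed 1 for net > 1; inhibition cannot drive a resting unit below 0 by the
second branch of the update rule. Single-word lexicons trivially dominate
(relative criterion at cycle 0); single-phoneme words have empty cohort and
rhyme sets by definition rather than raising. A dominance run interrupted by
an exact tie resets. The dwell criterion reports the last cycle of the
qualifying run.

## Known limitations

- **Embedded-word competition.** With nphone→word weights normalised by the
  destination word's nphone count, a word fully contained in the target
  reaches support fraction 1 early and can win the dwell race against its
  carrier; the calibrated defaults recover carriers against small embedded
  words but an onset-embedded word of comparable diphone richness still
  wins. This over-expresses the real model's documented confusion direction
  (the longer member of a near-identical embedding pair fails); full-scale
  accuracy figures should not be expected from this implementation without
  recalibration against the original parameter set.
- Recognition accuracy is not monotone in dwell (an easier dwell can crown
  an early-leading competitor); only the recognition *rate* is monotone.
- No word→nphone feedback, no featural/subphonemic input, no coarticulation
  analogue, no word frequency, no learning — all deliberate scope bounds of
  the architecture as implemented.
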