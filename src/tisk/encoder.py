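"""Time-specific phoneme inputs -> time-invariant nphone units.

The heart of the model: a bank of T time-specific phoneme input units feeds a
time-invariant nphone layer (P single-phone units plus P^2 ordered diphone
units) through a symmetry network. Weights depend only on the slice and the
role (first vs. second position in a diphone), never on phoneme identity:

    w_first(t)  = T - t        (from /p/_t to diphones p?)
    w_second(t) = t - 1        (from /p/_t to diphones ?p)
    theta       = T - 1        (strict diphone threshold)

Presenting adjacent phonemes [/a/_t, /b/_{t+1}] then delivers a total of
(T - t) + t = T to /ab/ at every t, and T - 2 to the anadrome /ba/, so a
threshold strictly between the two (theta = T - 1) recognises /ab/ and never
/ba/ regardless of when the pair occurs: a time-invariant open-diphone
(string-kernel) code that still separates anadromes.

Repeated phonemes need gating. Two trial-scoped gating rules make the code an
exact string kernel for arbitrary sequences:

1. first-position gating: once phoneme p has occurred, later p tokens no
   longer contribute in first position (otherwise a late repeated token would
   spuriously push every /p?/ diphone over threshold);
2. second-position refresh: a new token of q replaces — rather than adds
   to — the second-position contribution of earlier q tokens (otherwise
   several q tokens occurring *before* p could sum to a spurious /pq/).

With both rules the accumulated input to diphone (p, q) is

    (T - t_first(p)) + (t_last(q) - 1),

which exceeds theta = T - 1 exactly when some token of p precedes some token
of q, i.e. the supra-threshold diphone set equals the ordered-pair set
{(s_i, s_j) : i < j} of the presented sequence. Single-phone units activate on
any token of their phoneme (weight 1, threshold 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .lexicon import PhonemeInventory

__all__ = [
    "Nphone",
    "SymmetryWeights",
    "GatingState",
    "nphone_units",
    "word_nphones",
    "build_weights",
    "deliver",
    "active_nphones",
    "string_kernel_pairs",
]

# A single-phone nphone is a 1-tuple ('a',); an ordered diphone is ('a', 'b').
Nphone = Union[tuple[str], tuple[str, str]]


def nphone_units(inv: PhonemeInventory) -> list[Nphone]:
    """The P + P^2 nphone identities: P phones then P^2 ordered diphones."""
    phones: list[Nphone] = [(p,) for p in inv]
    diphones: list[Nphone] = [(p, q) for p in inv for q in inv]
    return phones + diphones


def word_nphones(phonemes: Sequence[str]) -> set[Nphone]:
    """String-kernel support of a word: its phones plus all ordered pairs
    (p_i, p_j) with i < j, including non-adjacent and repeated pairs."""
    out: set[Nphone] = {(p,) for p in phonemes}
    n = len(phonemes)
    for i in range(n):
        for j in range(i + 1, n):
            out.add((phonemes[i], phonemes[j]))
    return out


def string_kernel_pairs(seq: Sequence[str]) -> set[tuple[str, str]]:
    """Brute-force oracle: ordered pairs {(s_i, s_j) : i < j} of a sequence."""
    return {
        (seq[i], seq[j]) for i in range(len(seq)) for j in range(i + 1, len(seq))
    }


@dataclass(frozen=True)
class SymmetryWeights:
    """Slice-indexed weights of the symmetry network for a T-slice input bank.

    Exhibits axial symmetry (independence from phoneme identity at a slice)
    by construction, and central symmetry w_first(t) == w_second(T - t + 1).
    """

    T: int
    w_phone: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("need T >= 2 time slices to form a diphone")

    def w_first(self, t: int) -> float:
        """Weight from /p/_t to any diphone with p in first position."""
        self._check(t)
        return float(self.T - t)

    def w_second(self, t: int) -> float:
        """Weight from /p/_t to any diphone with p in second position."""
        self._check(t)
        return float(t - 1)

    @property
    def theta(self) -> float:
        """Strict diphone activation threshold."""
        return float(self.T - 1)

    def _check(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise ValueError(f"slice {t} outside [1, {self.T}]")


def build_weights(T: int, inv: PhonemeInventory | None = None) -> SymmetryWeights:
    """Construct the symmetry-network weights for a T-slice input bank.

    The inventory argument is accepted for interface symmetry but the weights
    are identical for every phoneme (that is the axial symmetry).
    """
    del inv
    return SymmetryWeights(T=T)


@dataclass
class GatingState:
    """Trial-scoped record of which phonemes occurred and when.

    ``first`` holds the slice of each phoneme's first token (fixing its
    first-position contribution); ``last`` the slice of its most recent token
    (refreshing its second-position contribution). Reset between trials.
    """

    first: dict[str, int] = field(default_factory=dict)
    last: dict[str, int] = field(default_factory=dict)
    tokens: int = 0

    @property
    def seen(self) -> set[str]:
        return set(self.first)

    def observe(self, phoneme: str, slice_t: int) -> None:
        if phoneme not in self.first:
            self.first[phoneme] = slice_t
        self.last[phoneme] = slice_t
        self.tokens += 1

    def reset(self) -> None:
        self.first.clear()
        self.last.clear()
        self.tokens = 0


def _normalize_seq(
    seq: Sequence[str] | Sequence[tuple[str, int]],
) -> list[tuple[str, int]]:
    events: list[tuple[str, int]] = []
    for i, item in enumerate(seq):
        if isinstance(item, str):
            events.append((item, i + 1))
        else:
            p, t = item
            events.append((str(p), int(t)))
    slices = [t for _, t in events]
    if any(b <= a for a, b in zip(slices, slices[1:])):
        raise ValueError("slice assignments must be strictly increasing")
    return events


def deliver(
    seq: Sequence[str] | Sequence[tuple[str, int]],
    weights: SymmetryWeights,
    gating: GatingState | None = None,
) -> dict[Nphone, float]:
    """Total feedforward input delivered to each touched nphone unit.

    ``seq`` is either a plain phoneme sequence (slices default to 1..n) or a
    sequence of (phoneme, slice) events with strictly increasing slices. The
    gating rules described in the module docstring are applied. The result
    covers every nphone unit touched by a presented phoneme (a delivered
    total of 0 is reported explicitly, e.g. for a maximally separated
    anadrome).
    """
    gating = gating if gating is not None else GatingState()
    events = _normalize_seq(seq)
    if events and events[-1][1] > weights.T:
        raise ValueError(
            f"sequence extends to slice {events[-1][1]} > T = {weights.T}"
        )
    for p, t in events:
        gating.observe(p, t)

    out: dict[Nphone, float] = {}
    for p in gating.seen:
        out[(p,)] = weights.w_phone  # any token activates the phone unit
    for p, tp in gating.first.items():
        for q, tq in gating.last.items():
            out[(p, q)] = weights.w_first(tp) + weights.w_second(tq)
    return out


def active_nphones(
    seq: Sequence[str] | Sequence[tuple[str, int]],
    weights: SymmetryWeights,
    gating: GatingState | None = None,
) -> set[Nphone]:
    """Nphone identities driven above threshold by a presented sequence.

    Diphones must strictly exceed theta = T - 1; phone units activate on any
    token. For any sequence the diphone set equals the ordered-pair string
    kernel of the sequence.
    """
    delivered = deliver(seq, weights, gating)
    active: set[Nphone] = set()
    for unit, total in delivered.items():
        if len(unit) == 1:
            active.add(unit)
        elif total > weights.theta:
            active.add(unit)
    return active
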