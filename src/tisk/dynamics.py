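"""Leaky-integrator interactive-activation dynamics over the three layers.

Connectivity: time-specific input bank -> nphone layer (symmetry-network
weights with threshold gating), lateral inhibition among nphone units,
normalized nphone -> word excitation, and lateral inhibition among words that
share sublexical units. There is no word -> nphone feedback.

Every unit is a leaky integrator updated synchronously once per cycle:

    A_i(t) = A_i(t-1) * (1 - decay) + Net_i(t) * (1 - A_i(t-1))   if Net_i > 0
    A_i(t) = A_i(t-1) * (1 - decay) + Net_i(t) * A_i(t-1)         if Net_i <= 0

with Net_i = sum_j w_ij A_j(t-1), and activations clamped to [0, 1]
(resting level 0; inhibition cannot drive a unit below rest).

How the encoder couples to the dynamics: the symmetry-network evidence for a
diphone accumulates as phoneme tokens arrive; a diphone unit contributes no
net input until its accumulated evidence strictly exceeds theta = T - 1, after
which it receives gain-scaled delivered input (gain * delivered / T) for as
long as the stimulus is present. The threshold performs the anadrome
discrimination; the graded supra-threshold drive means diphones spanning a
word's full extent (early first phoneme, late second phoneme) push slightly
harder, which is what lets a long word overtake words embedded inside it
while words differing by only one or two nphones remain confusable. Phone
units are driven whenever their phoneme's input unit is the active one.

Input schedule: phoneme i of the presented word is clamped to 1 for cycles
[(i-1)*d, i*d), so at most one input unit is active at any cycle; after the
last phoneme's clamp the network evolves freely (decay, persisting nphone ->
word support, competition) until ``max_cycles``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .encoder import (
    GatingState,
    Nphone,
    SymmetryWeights,
    build_weights,
    nphone_units,
    word_nphones,
)
from .lexicon import Lexicon, PhonemeInventory, Word

__all__ = [
    "ParameterSet",
    "NetworkState",
    "Trajectory",
    "TiskNetwork",
    "update_unit",
    "run_trial",
]


@dataclass(frozen=True)
class ParameterSet:
    """Tunable dynamics parameters (all unit-less).

    Defaults were calibrated once so that (a) anadrome pairs are recognised
    correctly in both directions under the sustained-dominance criterion,
    (b) cohort/rhyme/baseline competitor curves show the canonical ordering,
    and (c) recognition lands in the tens-of-cycles range with d = 5 cycles
    per phoneme. See docs/methods.md for the calibration rationale.
    """

    T: int = 10  # input bank slices; words longer than T cannot be presented
    clamp_cycles: int = 5  # d: cycles each phoneme's input unit stays clamped
    max_cycles: int = 100
    decay_nphone: float = 0.02
    decay_word: float = 0.05
    gain_input: float = 0.3  # input -> nphone drive per cycle
    gain_word: float = 0.4  # nphone -> word gain (normalized per word)
    inhibition_nphone: float = -0.002  # lateral, <= 0
    inhibition_word: float = -0.02  # lateral, <= 0
    word_inhibition_scope: str = "any_nphone"  # or "diphones_only"

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.clamp_cycles < 1:
            raise ValueError("clamp_cycles must be >= 1")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        for name in ("decay_nphone", "decay_word"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gain_input <= 0 or self.gain_word <= 0:
            raise ValueError("gains must be > 0")
        if self.inhibition_nphone > 0 or self.inhibition_word > 0:
            raise ValueError("inhibition strengths must be <= 0")
        if self.word_inhibition_scope not in ("any_nphone", "diphones_only"):
            raise ValueError("word_inhibition_scope must be "
                             "'any_nphone' or 'diphones_only'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)


@dataclass
class NetworkState:
    """Activations of every unit at one cycle (input clamp is implicit in the
    trial schedule and exposed as ``input_active``)."""

    cycle: int
    nphone: np.ndarray  # (P + P^2,)
    word: np.ndarray  # (W,)
    input_active: tuple[str, int] | None = None  # (phoneme, slice) clamped now


@dataclass
class Trajectory:
    """Per-cycle activation history for one presented word."""

    presented: str  # label of the presented word
    words: list[str]  # word-unit labels, fixed order
    nphones: list[Nphone]  # nphone-unit identities, fixed order
    word_history: np.ndarray  # (cycles, W)
    nphone_history: np.ndarray  # (cycles, P + P^2)

    @property
    def n_cycles(self) -> int:
        return self.word_history.shape[0]

    def word_activation(self, label: str) -> np.ndarray:
        return self.word_history[:, self.words.index(label)]


def update_unit(
    A_prev: np.ndarray | float, net: np.ndarray | float, decay: float
) -> np.ndarray | float:
    """One leaky-integrator update, clamped to [0, 1].

    Positive net drives the unit toward 1 scaled by remaining headroom;
    non-positive net scales with current activation, so a resting unit cannot
    be inhibited below rest.
    """
    A_prev = np.asarray(A_prev, dtype=float)
    net = np.asarray(net, dtype=float)
    grown = A_prev * (1.0 - decay) + np.where(net > 0, net * (1.0 - A_prev),
                                              net * A_prev)
    return np.clip(grown, 0.0, 1.0)


class TiskNetwork:
    """The assembled model: inventory + lexicon + weights + parameters."""

    def __init__(
        self,
        inventory: PhonemeInventory,
        lexicon: Lexicon,
        params: ParameterSet | None = None,
    ):
        self.inventory = inventory
        self.lexicon = lexicon
        self.params = params or ParameterSet()
        self.weights: SymmetryWeights = build_weights(self.params.T, inventory)

        self.nphones: list[Nphone] = nphone_units(inventory)
        self._nphone_index = {u: i for i, u in enumerate(self.nphones)}
        self.words: list[str] = [w.label for w in lexicon]
        self._word_sets: dict[str, set[Nphone]] = {
            w.label: word_nphones(w.phonemes) for w in lexicon
        }

        N, W = len(self.nphones), len(self.words)
        # nphone -> word excitation, normalized by the destination word's
        # nphone count so a fully supported word of any length sums to gain.
        self._feed = np.zeros((W, N))
        for wi, label in enumerate(self.words):
            support = self._word_sets[label]
            for u in support:
                self._feed[wi, self._nphone_index[u]] = 1.0 / len(support)
        # word lateral inhibition among words sharing sublexical units
        self._word_adj = np.zeros((W, W))
        diphones_only = self.params.word_inhibition_scope == "diphones_only"
        labels = self.words
        for i in range(W):
            si = self._word_sets[labels[i]]
            if diphones_only:
                si = {u for u in si if len(u) == 2}
            for j in range(i + 1, W):
                sj = self._word_sets[labels[j]]
                if diphones_only:
                    sj = {u for u in sj if len(u) == 2}
                if si & sj:
                    self._word_adj[i, j] = self._word_adj[j, i] = 1.0

    # ------------------------------------------------------------------ #

    def zero_state(self) -> NetworkState:
        return NetworkState(
            cycle=0,
            nphone=np.zeros(len(self.nphones)),
            word=np.zeros(len(self.words)),
        )

    def _net_inputs(
        self, state: NetworkState, drive: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Net inputs to (nphone, word) layers from the previous cycle."""
        p = self.params
        n_act, w_act = state.nphone, state.word
        net_n = drive + p.inhibition_nphone * (n_act.sum() - n_act)
        net_w = p.gain_word * (self._feed @ n_act) + p.inhibition_word * (
            self._word_adj @ w_act
        )
        return net_n, net_w

    def net_input(self, state: NetworkState, unit: Nphone | str,
                  drive: np.ndarray | None = None) -> float:
        """Net input to a single unit (a word label or an nphone tuple)."""
        if drive is None:
            drive = np.zeros(len(self.nphones))
        net_n, net_w = self._net_inputs(state, drive)
        if isinstance(unit, str):
            return float(net_w[self.words.index(unit)])
        return float(net_n[self._nphone_index[unit]])

    def step(
        self, state: NetworkState, drive: np.ndarray | None = None
    ) -> NetworkState:
        """Synchronous update of every unit from the previous cycle.

        ``drive`` is the external (input-layer) contribution to each nphone
        unit this cycle; omitted means no stimulus.
        """
        p = self.params
        if drive is None:
            drive = np.zeros(len(self.nphones))
        net_n, net_w = self._net_inputs(state, drive)
        return NetworkState(
            cycle=state.cycle + 1,
            nphone=update_unit(state.nphone, net_n, p.decay_nphone),
            word=update_unit(state.word, net_w, p.decay_word),
        )

    def _drive_for_cycle(
        self,
        cycle: int,
        phonemes: Sequence[str],
        gating: GatingState,
        supra: dict[Nphone, float],
    ) -> tuple[np.ndarray, tuple[str, int] | None]:
        """External drive vector for one cycle of the presentation schedule.

        Mutates ``gating``/``supra`` at phoneme onsets: the new token updates
        the symmetry-network accumulator, and any diphone whose accumulated
        evidence strictly exceeds theta enters ``supra`` with its current
        delivered total (refreshed as later tokens arrive).
        """
        p = self.params
        w = self.weights
        d = p.clamp_cycles
        input_end = len(phonemes) * d
        drive = np.zeros(len(self.nphones))
        if cycle >= input_end:
            return drive, None
        i = cycle // d
        phoneme = phonemes[i]
        if cycle % d == 0:  # token onset: accumulate evidence, open gates
            gating.observe(phoneme, i + 1)
            for a, ta in gating.first.items():
                for b, tb in gating.last.items():
                    total = w.w_first(ta) + w.w_second(tb)
                    if total > w.theta:
                        supra[(a, b)] = total
        drive[self._nphone_index[(phoneme,)]] = p.gain_input * w.w_phone
        for unit, total in supra.items():
            drive[self._nphone_index[unit]] = p.gain_input * total / p.T
        return drive, (phoneme, i + 1)

    def run_trial(self, word: Word | str | Sequence[str]) -> Trajectory:
        """Present a word and record the full activation trajectory.

        ``word`` may be a lexicon label, a Word, or a raw phoneme sequence.
        """
        if isinstance(word, Word):
            label, phonemes = word.label, word.phonemes
        elif isinstance(word, str):
            entry = self.lexicon.word(word)
            label, phonemes = entry.label, entry.phonemes
        else:
            phonemes = tuple(word)
            label = " ".join(phonemes)
        if len(phonemes) > self.params.T:
            raise ValueError(
                f"word of {len(phonemes)} phonemes exceeds T = {self.params.T}"
            )
        for ph in phonemes:
            if ph not in self.inventory:
                raise ValueError(f"unknown phoneme {ph!r}")

        gating = GatingState()
        supra: dict[Nphone, float] = {}
        state = self.zero_state()
        word_hist = np.empty((self.params.max_cycles, len(self.words)))
        nphone_hist = np.empty((self.params.max_cycles, len(self.nphones)))
        for cycle in range(self.params.max_cycles):
            drive, active = self._drive_for_cycle(cycle, phonemes, gating, supra)
            state = self.step(state, drive)
            state.input_active = active
            word_hist[cycle] = state.word
            nphone_hist[cycle] = state.nphone
        return Trajectory(
            presented=label,
            words=list(self.words),
            nphones=list(self.nphones),
            word_history=word_hist,
            nphone_history=nphone_hist,
        )


def run_trial(
    word: Word | str | Sequence[str], network: TiskNetwork
) -> Trajectory:
    """Module-level convenience wrapper around :meth:`TiskNetwork.run_trial`."""
    return network.run_trial(word)
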