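"""Closed-form unit and connection counting for TISK- and TRACE-style models.

The point of the time-invariant architecture is economy: TRACE duplicates its
phoneme and word units at every third time slice and wires lateral inhibition
among all temporally overlapping duplicates, so its cost explodes with both
trace duration and lexicon size; the time-invariant model pays for a single
nphone and word layer plus a gating apparatus that is quadratic in slices but
independent of the lexicon. This module computes both bills from closed
formulas, decoupled from any simulation.

Unit counts are exact:

    TISK  units = S*P + (P^2 + P) + W
    TRACE units = round((P + W) * S / 3)        (duplicates every 3rd slice)

Connection counts are documented per-component estimates. The per-component
decomposition is exposed so each term can be inspected independently:

TISK:
    input->nphone   S*P*(2P + 1)     each input unit reaches the P diphones
                                     with its phoneme first, P with it second,
                                     and its phone unit
    gating          (P(P-1)/2)*S^2   repeated-token gating, quadratic in S
    nphone lateral  N*(N-1), N=P^2+P directed all-pairs inhibition
    nphone->word    W*(L + L(L-1)/2) string-kernel support of an L-phoneme word
    word lateral    W*(W-1)          directed inhibition (upper bound: every
                                     pair assumed to share a sublexical unit)

TRACE (phoneme level up, A = round(S/3) alignments, phoneme centres two
alignments apart, a word spanning ~2L alignments):
    phoneme<->word  2*L*W*A          feedforward + feedback per alignment
    word lateral    W*A*(W*(4L-1)-1) inhibition among overlapping word units
    phoneme lateral P*A*(3P-1)       inhibition among overlapping phoneme units
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .encoder import word_nphones
from .lexicon import Lexicon

__all__ = [
    "ArchitectureSpec",
    "ResourceCount",
    "count_units",
    "count_connections",
    "count_resources",
    "scaling_surface",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Sizing assumptions for one model variant.

    ``mean_word_length`` is the average phonemes per word used where no
    concrete lexicon is supplied (the canonical comparison assumes 4).
    """

    model: str  # "tisk" or "trace"
    words: int
    phonemes: int
    slices: int = 200
    mean_word_length: float = 4.0

    def __post_init__(self) -> None:
        if self.model not in ("tisk", "trace"):
            raise ValueError("model must be 'tisk' or 'trace'")
        if self.words < 0:
            raise ValueError("words must be >= 0")
        if self.phonemes < 1:
            raise ValueError("phonemes must be >= 1")
        if self.slices < 2:
            raise ValueError("slices must be >= 2")
        if self.mean_word_length <= 0:
            raise ValueError("mean_word_length must be > 0")


@dataclass(frozen=True)
class ResourceCount:
    units: int
    connections: int
    unit_breakdown: dict = field(default_factory=dict)
    connection_breakdown: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.units == sum(self.unit_breakdown.values())
        assert self.connections == sum(self.connection_breakdown.values())


def _round(x: float) -> int:
    return int(math.floor(x + 0.5))


def _unit_breakdown(spec: ArchitectureSpec) -> dict[str, int]:
    W, P, S = spec.words, spec.phonemes, spec.slices
    if spec.model == "tisk":
        return {"input": S * P, "nphone": P * P + P, "word": W}
    total = _round((P + W) * S / 3)
    phoneme = _round(P * S / 3)
    return {"phoneme": phoneme, "word": total - phoneme}


def count_units(spec: ArchitectureSpec) -> int:
    """Total units of the architecture (exact; reproduces the canonical
    comparison table's unit rows)."""
    return sum(_unit_breakdown(spec).values())


def _connection_breakdown(
    spec: ArchitectureSpec, lexicon: Lexicon | None = None
) -> dict[str, int]:
    W, P, S, L = spec.words, spec.phonemes, spec.slices, spec.mean_word_length
    if spec.model == "tisk":
        N = P * P + P
        if lexicon is not None:
            sets = [word_nphones(w.phonemes) for w in lexicon]
            feed = sum(len(s) for s in sets)
            lateral = sum(
                2
                for i in range(len(sets))
                for j in range(i + 1, len(sets))
                if sets[i] & sets[j]
            )
        else:
            feed = _round(W * (L + L * (L - 1) / 2.0))
            lateral = W * (W - 1)
        return {
            "input_nphone": S * P * (2 * P + 1),
            "gating": (P * (P - 1) // 2) * S * S,
            "nphone_lateral": N * (N - 1),
            "nphone_word": feed,
            "word_lateral": lateral,
        }
    A = _round(S / 3)
    Li = _round(L)
    return {
        "phoneme_word": 2 * Li * W * A,
        "word_lateral": W * A * (W * (4 * Li - 1) - 1) if W else 0,
        "phoneme_lateral": P * A * (3 * P - 1),
    }


def count_connections(
    spec: ArchitectureSpec, lexicon: Lexicon | None = None
) -> int:
    """Total connections (documented estimate; see module docstring).

    When a concrete lexicon is supplied for the time-invariant model, the
    nphone->word and word-lateral terms are computed exactly from each word's
    string-kernel support and the actual sharing structure, instead of the
    mean-length / every-pair approximations.
    """
    return sum(_connection_breakdown(spec, lexicon).values())


def count_resources(
    spec: ArchitectureSpec, lexicon: Lexicon | None = None
) -> ResourceCount:
    """Units and connections with their per-component breakdowns."""
    ub = _unit_breakdown(spec)
    cb = _connection_breakdown(spec, lexicon)
    return ResourceCount(
        units=sum(ub.values()),
        connections=sum(cb.values()),
        unit_breakdown=ub,
        connection_breakdown=cb,
    )


def scaling_surface(
    model: str,
    word_range: Iterable[int],
    slice_range: Iterable[int],
    phonemes: int = 14,
    mean_word_length: float = 4.0,
) -> pd.DataFrame:
    """Connection cost over a (words x slices) grid.

    Rows are lexicon sizes, columns are trace durations in slices.
    """
    words = list(word_range)
    slices = list(slice_range)
    grid = np.empty((len(words), len(slices)), dtype=np.int64)
    for i, w in enumerate(words):
        for j, s in enumerate(slices):
            grid[i, j] = count_connections(
                ArchitectureSpec(model, w, phonemes, s, mean_word_length)
            )
    return pd.DataFrame(grid, index=pd.Index(words, name="words"),
                        columns=pd.Index(slices, name="slices"))
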