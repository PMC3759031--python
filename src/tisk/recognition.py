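"""Recognition criteria: mapping a word-layer trajectory to a decision.

Three operationalizations are provided:

- absolute: the first cycle any word unit reaches an absolute threshold;
- relative: the first cycle the most active word exceeds the runner-up by a
  fixed margin (default 0.05);
- time: the first cycle ending a run of ``dwell`` consecutive cycles
  (default 10) during which one word strictly exceeds all others.

Exact ties never satisfy "exceeds"; strict inequality is required. Failure to
recognise within the trajectory is a regular outcome (``recognized=None``),
not an error, and the recognised word need not be the presented one — accuracy
is judged downstream, which preserves the model's characteristic confusions
(e.g. a longer word losing to a word embedded at its onset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dynamics import Trajectory

__all__ = ["RecognitionCriterion", "RecognitionResult", "recognize"]

CriterionKind = Literal["absolute", "relative", "time"]


@dataclass(frozen=True)
class RecognitionCriterion:
    kind: CriterionKind = "time"
    absolute_threshold: float = 0.5  # theta_abs, calibration parameter
    margin: float = 0.05
    dwell: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative", "time"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if not 0.0 < self.absolute_threshold <= 1.0:
            raise ValueError("absolute_threshold must lie in (0, 1]")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.dwell < 1:
            raise ValueError("dwell must be >= 1")


@dataclass(frozen=True)
class RecognitionResult:
    presented: str
    recognized: str | None  # None when the criterion is never met
    cycle: int | None  # first cycle satisfying the criterion
    correct: bool  # recognized == presented

    @classmethod
    def failure(cls, presented: str) -> "RecognitionResult":
        return cls(presented, None, None, False)


def recognize(traj: Trajectory, crit: RecognitionCriterion) -> RecognitionResult:
    """Apply one recognition criterion to a trajectory.

    The reported cycle is the earliest cycle at which the criterion is
    satisfied; for the time criterion that is the last cycle of the first
    qualifying dwell run.
    """
    H = traj.word_history
    if H.shape[0] == 0:
        raise ValueError("empty trajectory")
    n_cycles, n_words = H.shape

    def result(cycle: int, word_idx: int) -> RecognitionResult:
        label = traj.words[word_idx]
        return RecognitionResult(
            presented=traj.presented,
            recognized=label,
            cycle=cycle,
            correct=label == traj.presented,
        )

    if crit.kind == "absolute":
        hits = H >= crit.absolute_threshold
        for c in range(n_cycles):
            if hits[c].any():
                return result(c, int(np.argmax(H[c])))
        return RecognitionResult.failure(traj.presented)

    if n_words < 2:
        # a single word trivially "exceeds all others" from cycle 0 on
        if crit.kind == "relative":
            return result(0, 0)
        return (
            result(crit.dwell - 1, 0)
            if n_cycles >= crit.dwell
            else RecognitionResult.failure(traj.presented)
        )

    order = np.argsort(H, axis=1)
    top = order[:, -1]
    lead = H[np.arange(n_cycles), top] - H[np.arange(n_cycles), order[:, -2]]

    if crit.kind == "relative":
        for c in range(n_cycles):
            if lead[c] >= crit.margin:
                return result(c, int(top[c]))
        return RecognitionResult.failure(traj.presented)

    # time criterion: strict dominance sustained for `dwell` cycles
    run, leader = 0, -1
    for c in range(n_cycles):
        if lead[c] > 0 and top[c] == leader:
            run += 1
        elif lead[c] > 0:
            leader, run = int(top[c]), 1
        else:
            leader, run = -1, 0
        if run >= crit.dwell:
            return result(c, leader)
    return RecognitionResult.failure(traj.presented)
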