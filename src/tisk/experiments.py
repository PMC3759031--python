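"""Whole-lexicon simulation suites and their summary statistics.

Three analyses mirror the standard evaluation of interactive-activation models
of spoken word recognition:

- :func:`run_batch`: one trial per word in the lexicon, every recognition
  criterion evaluated on the same trajectory; per-criterion accuracy and mean
  recognition cycles (over correct trials only).
- :func:`competitor_timecourse`: average activation over time of the target
  and its competitor classes (cohorts, strict rhymes, words embedded in the
  target) plus the mean of all words as a baseline, averaged across correctly
  recognised targets.
- :func:`rt_correlations`: correlation of recognition cycles with the six
  lexical variables of the word profile, over correct trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ParameterSet, TiskNetwork, Trajectory
from .lexicon import Lexicon, cohorts, embedded_words, profiles_table, rhymes
from .recognition import RecognitionCriterion, RecognitionResult, recognize

__all__ = [
    "BatchReport",
    "CompetitorCurves",
    "run_batch",
    "competitor_timecourse",
    "rt_correlations",
    "PROFILE_VARIABLES",
]

PROFILE_VARIABLES = (
    "length",
    "embedded_count",
    "embeddings_log",
    "cohort_count",
    "das_neighbor_count",
    "rhyme_log",
)


@dataclass
class BatchReport:
    """Per-word recognition outcomes for each criterion, plus summaries."""

    results: dict[str, dict[str, RecognitionResult]]  # criterion -> label -> result
    accuracy: dict[str, float]  # percent of the lexicon, per criterion
    mean_cycles: dict[str, float]  # over correct trials only (nan if none)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for crit, by_word in self.results.items():
            for label, r in by_word.items():
                rows.append(
                    {
                        "word": label,
                        "criterion": crit,
                        "recognized": r.recognized,
                        "cycle": r.cycle,
                        "correct": r.correct,
                    }
                )
        return pd.DataFrame(rows)


def _criterion_name(crit: RecognitionCriterion) -> str:
    return crit.kind


def run_batch(
    lex: Lexicon,
    params: ParameterSet | None = None,
    criteria: list[RecognitionCriterion] | None = None,
    network: TiskNetwork | None = None,
    keep_trajectories: bool = False,
) -> BatchReport:
    """One simulation per lexicon word, all criteria scored on each trajectory.

    Trials are independent, so the report does not depend on word order.
    Pass ``keep_trajectories=True`` to retain each trial's trajectory on the
    report (``report.trajectories``) for downstream averaging.
    """
    if network is None:
        network = TiskNetwork(lex.inventory, lex, params)
    if criteria is None:
        criteria = [
            RecognitionCriterion(kind="absolute"),
            RecognitionCriterion(kind="relative"),
            RecognitionCriterion(kind="time"),
        ]
    names = [_criterion_name(c) for c in criteria]
    if len(set(names)) != len(names):
        raise ValueError("criteria must have distinct kinds")

    results: dict[str, dict[str, RecognitionResult]] = {n: {} for n in names}
    trajectories: dict[str, Trajectory] = {}
    for w in lex:
        traj = network.run_trial(w)
        if keep_trajectories:
            trajectories[w.label] = traj
        for name, crit in zip(names, criteria):
            results[name][w.label] = recognize(traj, crit)

    accuracy = {
        n: 100.0 * sum(r.correct for r in by.values()) / len(lex)
        for n, by in results.items()
    }
    mean_cycles = {}
    for n, by in results.items():
        cycles = [r.cycle for r in by.values() if r.correct]
        mean_cycles[n] = float(np.mean(cycles)) if cycles else float("nan")
    report = BatchReport(results=results, accuracy=accuracy,
                         mean_cycles=mean_cycles)
    if keep_trajectories:
        report.trajectories = trajectories  # type: ignore[attr-defined]
    return report


COMPETITOR_CLASSES = ("target", "cohort", "rhyme", "embedded", "mean_all")


@dataclass
class CompetitorCurves:
    """Per-cycle mean activation per competitor class.

    ``curves[cls]`` is a length-``n_cycles`` array; ``n_targets[cls]`` counts
    how many targets contributed (targets with an empty class are skipped for
    that class). ``mean_all`` averages over every word including the target.
    """

    curves: dict[str, np.ndarray]
    n_targets: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curves).rename_axis("cycle")


def competitor_timecourse(
    lex: Lexicon,
    params: ParameterSet | None = None,
    network: TiskNetwork | None = None,
    criterion: RecognitionCriterion | None = None,
) -> CompetitorCurves:
    """Average competitor-class activation curves across the lexicon.

    Only correctly recognised targets (sustained-dominance criterion by
    default) enter the averages. Competitor classes per target: cohorts
    (first two phonemes shared), strict rhymes (all but the first phoneme
    shared, same length), words embedded in the target (contiguous), and the
    mean of all words as baseline.
    """
    if network is None:
        network = TiskNetwork(lex.inventory, lex, params)
    criterion = criterion or RecognitionCriterion(kind="time")

    per_class_sums: dict[str, np.ndarray | None] = {
        c: None for c in COMPETITOR_CLASSES
    }
    n_targets = {c: 0 for c in COMPETITOR_CLASSES}

    for w in lex:
        traj = network.run_trial(w)
        if not recognize(traj, criterion).correct:
            continue
        idx = {label: i for i, label in enumerate(traj.words)}
        H = traj.word_history
        members = {
            "target": [w.label],
            "cohort": [v.label for v in cohorts(w, lex)],
            "rhyme": [v.label for v in rhymes(w, lex, mode="strict")],
            "embedded": [v.label for v in embedded_words(w, lex)],
            "mean_all": list(traj.words),
        }
        for cls, labels in members.items():
            if not labels:
                continue  # class empty for this target
            curve = H[:, [idx[l] for l in labels]].mean(axis=1)
            if per_class_sums[cls] is None:
                per_class_sums[cls] = curve.copy()
            else:
                per_class_sums[cls] += curve
            n_targets[cls] += 1

    curves = {
        cls: total / n_targets[cls]
        for cls, total in per_class_sums.items()
        if total is not None
    }
    return CompetitorCurves(curves=curves,
                            n_targets={c: n_targets[c] for c in curves})


def rt_correlations(
    report: BatchReport,
    lex: Lexicon,
    criterion: str = "time",
    method: str = "pearson",
) -> pd.Series:
    """Correlate recognition cycles with the six lexical variables.

    Only correct trials enter. Variables with no variance across the correct
    trials (or constant recognition cycles) yield NaN — undefined, not zero.
    Requires at least 3 correct trials.
    """
    if criterion not in report.results:
        raise KeyError(f"criterion {criterion!r} not in report")
    by_word = report.results[criterion]
    correct = {label: r.cycle for label, r in by_word.items() if r.correct}
    if len(correct) < 3:
        raise ValueError("need at least 3 correct trials to correlate")

    table = profiles_table(lex).loc[list(correct)]
    rt = np.array([correct[label] for label in table.index], dtype=float)

    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")

    out = {}
    for var in PROFILE_VARIABLES:
        x = table[var].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(rt) == 0:
            out[var] = float("nan")
        else:
            out[var] = float(corr(rt, x)[0])
    return pd.Series(out, name=f"r({criterion})")
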