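"""Microstate sequence features: duration, occurrence, coverage, and
transition probabilities.

A label sequence decomposes into maximal runs of one class.  From the runs
of an epoch we compute, per class k:

* duration_ms[k]  — mean run length in milliseconds (0 when k never occurs);
* occurrence_hz[k] — number of runs of k per second of *labeled* time, so
  unassigned samples do not dilute the rate;
* coverage_pct[k] — percent of labeled samples spent in k;
* transition_prob[i, j] — of the runs of i that are immediately followed by
  another run (the last run of an epoch has no successor and is excluded
  from the denominator), the fraction whose successor is class j.  Rows of
  classes with no outgoing transition are NaN.

Unassigned gaps split runs and break adjacency: no transition is counted
across a gap.  Runs truncated by the epoch edges are included in duration,
occurrence and coverage (set ``drop_boundary_runs=True`` to exclude them).

Valence ratings (1-9) map onto emotion conditions as negative = {1,2,3},
neutral = {4,5}, positive = {6,7,8,9}; per-trial features are averaged per
subject x emotion, and subjects lacking any trial of some emotion are
flagged for exclusion from the repeated-measures statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import UNASSIGNED, LabelSequence, MicrostateFeatures
from .errors import InvalidInputError, UndefinedResultError

__all__ = [
    "run_segments",
    "compute_features",
    "categorize_valence",
    "average_by_condition",
    "features_to_frame",
]

EMOTIONS = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class Run:
    """One maximal run of a single class."""

    state: int
    start: int
    length: int


def run_segments(seq: LabelSequence) -> list[Run]:
    """Maximal constant runs of a label sequence, gaps excluded.

    UNASSIGNED stretches are omitted from the output and split the runs
    around them; the concatenation of runs plus gaps reconstructs the
    sequence.
    """
    labels = seq.labels
    if labels.size == 0:
        raise InvalidInputError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [labels.size])))
    return [
        Run(int(labels[s]), int(s), int(l))
        for s, l in zip(starts, lengths)
        if labels[s] != UNASSIGNED
    ]


def compute_features(
    seq: LabelSequence, drop_boundary_runs: bool = False,
    joint_transitions: bool = False,
) -> MicrostateFeatures:
    """The K-class feature vector of one label sequence.

    With K = 4 this yields the standard 24 features (4 durations, 4
    occurrences, 4 coverages, 12 off-diagonal transition probabilities).
    ``joint_transitions`` switches the transition entries from conditional
    (row-normalized) probabilities to joint frequencies over all observed
    transitions.
    """
    runs = run_segments(seq)
    if not runs:
        raise UndefinedResultError("all samples unassigned; features undefined")
    k = seq.n_states

    counted = runs
    if drop_boundary_runs:
        counted = [
            r for r in runs
            if r.start != 0 and r.start + r.length != seq.n_samples
        ]
        # degenerate epochs whose runs all touch an edge keep their runs
        counted = counted or runs

    labeled_samples = int(np.sum(seq.labels != UNASSIGNED))
    labeled_s = labeled_samples / seq.sfreq

    duration_ms = np.zeros(k)
    occurrence_hz = np.zeros(k)
    coverage_pct = np.zeros(k)
    for state in range(k):
        lens = [r.length for r in counted if r.state == state]
        if lens:
            duration_ms[state] = np.mean(lens) * 1000.0 / seq.sfreq
            occurrence_hz[state] = len(lens) / labeled_s
        coverage_pct[state] = 100.0 * sum(
            r.length for r in runs if r.state == state) / labeled_samples

    # transitions: adjacent runs only (gaps break adjacency); the final run
    # of each contiguous block has no successor
    counts = np.zeros((k, k))
    for a, b in zip(runs[:-1], runs[1:]):
        if a.start + a.length == b.start:          # no gap between them
            counts[a.state, b.state] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        if joint_transitions:
            total = counts.sum()
            trans = counts / total if total > 0 else np.full((k, k), np.nan)
        else:
            trans = np.where(row_sums > 0, counts / row_sums, np.nan)
    np.fill_diagonal(trans, 0.0)

    return MicrostateFeatures(
        duration_ms=duration_ms, occurrence_hz=occurrence_hz,
        coverage_pct=coverage_pct, transition_prob=trans, n_states=k,
        subject_id=seq.subject_id, trial_id=seq.trial_id,
        condition=seq.condition, band=seq.band,
    )


def categorize_valence(rating: int) -> str:
    """Map a 1-9 valence rating to an emotion condition.

    1-3 -> negative, 4-5 -> neutral, 6-9 -> positive.
    """
    if not isinstance(rating, (int, np.integer)) or not 1 <= rating <= 9:
        raise InvalidInputError(f"valence rating must be an integer 1-9, got {rating!r}")
    if rating <= 3:
        return "negative"
    if rating <= 5:
        return "neutral"
    return "positive"


def features_to_frame(feats: list[MicrostateFeatures]) -> pd.DataFrame:
    """Stack per-trial features into a tidy table with the fixed column
    schema ``subject, condition, trial, band, A_dur, ..., p_DC``."""
    rows = []
    for f in feats:
        row = {
            "subject": f.subject_id, "condition": f.condition,
            "trial": f.trial_id, "band": f.band,
        }
        row.update(f.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def average_by_condition(
    feats: list[MicrostateFeatures],
    emotions: tuple[str, ...] = EMOTIONS,
) -> tuple[pd.DataFrame, list[str]]:
    """Average per-trial features into one row per subject x emotion.

    The arithmetic mean of each feature is taken over a subject's trials of
    each emotion (NaN transition entries are ignored in the mean).  Returns
    the per-subject table plus the list of subjects flagged for exclusion
    because they lack at least one of the requested emotions — downstream
    repeated-measures tests need complete cases.
    """
    table = features_to_frame(feats)
    if table.empty:
        raise InvalidInputError("no features to average")
    value_cols = [c for c in table.columns
                  if c not in ("subject", "condition", "trial", "band")]
    grouped = (
        table.groupby(["subject", "condition", "band"], as_index=False)[value_cols]
        .mean()
    )
    flagged = []
    for subj, sub in grouped.groupby("subject"):
        present = set(sub["condition"])
        if not set(emotions) <= present:
            flagged.append(str(subj))
    return grouped, sorted(flagged)
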