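"""Time-varying characteristics of CAP state sequences.

For a per-frame label sequence (states 1..K) the classical dynamic
summaries are:

* **occurrence** (fractional occupancy): fraction of frames in each state;
* **entry count / entry rate**: number of maximal consecutive runs of the
  state (consecutive frames count once); also reported per minute of scan;
* **mean duration** (dwell time): average run length in frames (and
  seconds, via TR); undefined (NaN) for states never visited;
* **transition probability**: row-normalized counts of one-step
  transitions, optionally excluding self-transitions.

These satisfy the exact conservation law
``occurrence_s * T == entry_count_s * mean_duration_s`` (frames) for every
visited state s.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CapMetrics, StateSequence, ValidationError

__all__ = [
    "run_length_encode",
    "compute_state_metrics",
    "transition_probabilities",
    "metrics_table",
    "transitions_table",
]


def run_length_encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(values, run_lengths) of maximal constant runs, in order."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


def compute_state_metrics(seq: StateSequence, k: int) -> CapMetrics:
    """All dynamic summaries of one sequence against K states."""
    labels = seq.labels
    if np.any(labels > k):
        raise ValidationError(
            f"label {labels.max()} exceeds K={k} (subject {seq.subject_id})"
        )
    t = labels.size
    occurrence = np.bincount(labels - 1, minlength=k) / t
    values, lengths = run_length_encode(labels)
    entry_count = np.bincount(values - 1, minlength=k).astype(float)
    mean_duration = np.full(k, np.nan)
    for s in range(k):
        mine = lengths[values == s + 1]
        if mine.size:
            mean_duration[s] = mine.mean()
    transition = (
        transition_probabilities(seq, k) if t >= 2 else np.full((k, k), np.nan)
    )
    return CapMetrics(
        subject_id=seq.subject_id,
        band_tag=seq.band_tag,
        occurrence=occurrence,
        entry_count=entry_count,
        mean_duration_frames=mean_duration,
        transition_matrix=transition,
        n_frames=t,
        tr=seq.tr,
    )


def transition_probabilities(
    seq: StateSequence, k: int, include_self: bool = True
) -> np.ndarray:
    """Row-stochastic one-step transition matrix estimated from a sequence.

    ``C[i, j]`` counts frames where state i+1 is followed by state j+1;
    rows are normalized by their outgoing count. With
    ``include_self=False`` the diagonal is removed before normalization
    (probability of the *next different* state). Rows with no outgoing
    transitions are all-NaN.
    """
    labels = seq.labels
    if labels.size < 2:
        raise ValidationError("transition estimation needs at least 2 frames")
    if np.any(labels > k):
        raise ValidationError(f"label {labels.max()} exceeds K={k}")
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1.0)
    if not include_self:
        np.fill_diagonal(counts, 0.0)
    out = counts.sum(axis=1)
    p = np.full((k, k), np.nan)
    nz = out > 0
    p[nz] = counts[nz] / out[nz, None]
    return p


def metrics_table(metrics: list[CapMetrics]) -> pd.DataFrame:
    """Tidy table: one row per subject x band x CAP."""
    rows = []
    for m in metrics:
        for s in range(m.n_states):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "band": m.band_tag,
                    "cap": s + 1,
                    "occurrence": m.occurrence[s],
                    "entry_count": m.entry_count[s],
                    "entry_rate_per_min": m.entry_rate_per_min[s],
                    "mean_duration_frames": m.mean_duration_frames[s],
                    "mean_duration_s": m.mean_duration_seconds[s],
                }
            )
    return pd.DataFrame(rows)


def transitions_table(metrics: list[CapMetrics]) -> pd.DataFrame:
    """Long-format transition probabilities: subject, band, from, to, p."""
    rows = []
    for m in metrics:
        k = m.n_states
        for i in range(k):
            for j in range(k):
                rows.append(
                    {
                        "subject_id": m.subject_id,
                        "band": m.band_tag,
                        "from": i + 1,
                        "to": j + 1,
                        "p": m.transition_matrix[i, j],
                    }
                )
    return pd.DataFrame(rows)
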