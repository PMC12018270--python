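"""Behavioural statistics of social rebound from bout annotations.

Social rebound is quantified from scored bouts: total interaction time,
bout counts and durations, inter-bout latencies, and the within-reunion
satiation profile as 2-min-binned interaction totals. Module-to-module
transition probabilities summarise the motor sequence of interaction;
social distance comes from tracked positions; tunnel/chamber preference
indices and the USV-interaction correlation complete the rebound
read-outs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BehaviorAnnotation, ValidationError

__all__ = [
    "InteractionSummary",
    "summarize_interaction",
    "TransitionMatrix",
    "transition_matrix",
    "social_distance",
    "preference_index",
    "usv_interaction_correlation",
]


@dataclass
class InteractionSummary:
    """Interaction totals, latencies and satiation bins for one filter."""

    total_s: float
    n_bouts: int
    mean_bout_s: float
    latencies_s: np.ndarray
    binned_s: np.ndarray
    bin_s: float
    actor_filter: str


def summarize_interaction(annotation: BehaviorAnnotation,
                          actor_filter: str = "isolated",
                          bin_s: float = 120.0,
                          session_s: float | None = None) -> InteractionSummary:
    """Summarise the bouts of one actor (or ``'both'``).

    Latencies are the gaps between consecutive bouts (the pre-first-bout
    interval is not included). Binned totals apportion each bout to the
    bins it overlaps, so they exactly partition the total.
    """
    bouts = annotation.for_actor(actor_filter).sort_values("start_s")
    starts = bouts["start_s"].to_numpy(dtype=float)
    ends = bouts["end_s"].to_numpy(dtype=float)
    if session_s is None:
        session_s = float(ends.max()) if len(ends) else 0.0
    if len(ends) and (starts.min() < 0 or ends.max() > session_s + 1e-9):
        raise ValidationError(
            f"bout outside session bounds [0, {session_s}]"
        )
    durations = ends - starts
    total = float(durations.sum())
    lat = np.maximum(starts[1:] - ends[:-1], 0.0) if len(starts) > 1 else np.array([])
    n_bins = max(int(np.ceil(session_s / bin_s - 1e-9)), 1) if session_s > 0 else 0
    binned = np.zeros(n_bins)
    for s, e in zip(starts, ends):
        b0, b1 = int(s // bin_s), min(int(np.ceil(e / bin_s - 1e-9)), n_bins)
        for b in range(b0, b1):
            binned[b] += min(e, (b + 1) * bin_s) - max(s, b * bin_s)
    return InteractionSummary(
        total_s=total,
        n_bouts=int(len(bouts)),
        mean_bout_s=float(durations.mean()) if len(bouts) else 0.0,
        latencies_s=lat,
        binned_s=binned,
        bin_s=bin_s,
        actor_filter=actor_filter,
    )


@dataclass
class TransitionMatrix:
    """Row-stochastic module transition probabilities with raw counts."""

    modules: list
    probs: pd.DataFrame
    counts: pd.DataFrame
    empty_rows: list = field(default_factory=list)


def transition_matrix(annotation: BehaviorAnnotation,
                      modules=None,
                      actor_filter: str = "both") -> TransitionMatrix:
    """Module-to-module transition probabilities.

    Consecutive bout pairs are counted within each actor's time-ordered
    sequence (gaps between bouts are ignored) and pooled across actors;
    each row is normalised to sum to 1. Rows never visited are flagged in
    ``empty_rows`` and left at zero.
    """
    df = annotation.for_actor(actor_filter)
    if len(df) < 2:
        raise ValidationError("need at least 2 bouts to count transitions")
    mods = list(modules) if modules is not None else sorted(df["module"].unique())
    idx = {m: i for i, m in enumerate(mods)}
    unknown = sorted(set(df["module"]) - set(mods))
    if unknown:
        raise ValidationError(f"bout module(s) not in module list: {unknown}")
    C = np.zeros((len(mods), len(mods)), dtype=int)
    for _, grp in df.groupby("actor", sort=False):
        seq = grp.sort_values("start_s")["module"].tolist()
        for a, b in zip(seq, seq[1:]):
            C[idx[a], idx[b]] += 1
    row_sums = C.sum(axis=1)
    P = np.zeros_like(C, dtype=float)
    nz = row_sums > 0
    P[nz] = C[nz] / row_sums[nz, None]
    empty = [m for m, s in zip(mods, row_sums) if s == 0]
    return TransitionMatrix(
        modules=mods,
        probs=pd.DataFrame(P, index=mods, columns=mods),
        counts=pd.DataFrame(C, index=mods, columns=mods),
        empty_rows=empty,
    )


def social_distance(track_a, track_b) -> float:
    """Mean Euclidean distance between two tracked animals, over frames.

    Tracks are (n_frames, 2) position arrays in consistent units (cm).
    Frames with a missing coordinate in either track are excluded with a
    warning.
    """
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValidationError(
            f"tracks must share shape (n_frames, 2); got {a.shape} and {b.shape}"
        )
    ok = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
    n_missing = int((~ok).sum())
    if n_missing:
        warnings.warn(f"excluding {n_missing} frame(s) with missing positions")
    if not ok.any():
        raise ValidationError("no complete frames in the tracks")
    return float(np.linalg.norm(a[ok] - b[ok], axis=1).mean())


def preference_index(target: float, other: float) -> float:
    """Fraction of crossings (or crossing time) through the target tunnel.

    ``target / (target + other)``; works for counts or durations, and
    equally for chamber-time preference.
    """
    if target < 0 or other < 0:
        raise ValueError("crossing counts/durations must be non-negative")
    total = target + other
    if total == 0:
        raise ValueError("preference undefined: no crossings through either tunnel")
    return float(target / total)


def usv_interaction_correlation(interaction_s, usv_counts):
    """Pearson correlation between interaction time and USV syllable count.

    One value per session; needs at least 3 paired sessions and
    non-constant vectors. Returns ``(r, p)``.
    """
    x = np.asarray(interaction_s, dtype=float).ravel()
    y = np.asarray(usv_counts, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("interaction and USV vectors must have equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 paired sessions, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
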