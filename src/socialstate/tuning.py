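"""ROC/AUC tuning classification of state-modulated neurons.

Each neuron's binned activity distribution during a comparison epoch
(typically social reunion) is compared with its baseline (isolation)
distribution via the area under the ROC curve. With ties credited half a
win, the threshold-sweep AUC equals the rank-sum statistic

    AUC = (#[epoch > baseline] + 0.5 * #[epoch = baseline]) / (n * m)

over all cross pairs, so values above 0.5 indicate activation during the
epoch and below 0.5 inhibition. Significance is assessed against a
permutation null built by re-assigning the pooled 1-s bin values to the
two epoch labels (sizes preserved). A neuron is labelled

* ``reunion``  if AUC > ``auc_hi``  and AUC exceeds the ``null_pct``-th
  percentile of the shuffled AUCs,
* ``isolation`` if AUC < ``auc_lo`` and AUC falls below the symmetric
  ``(100 - null_pct)``-th percentile,
* ``none`` otherwise.

Activation strengths are AUC (reunion) and 1 - AUC (isolation).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from ._binning import bin_means
from .io import SessionTimeline, TraceMatrix, ValidationError

__all__ = [
    "TuningParams",
    "bin_epoch_values",
    "compute_auc",
    "build_null",
    "classify_neuron",
    "classify_population",
    "classify_multihour",
    "TuningClassifier",
    "match_cells",
    "ensemble_activity",
]

LABELS = ("isolation", "reunion", "none")


@dataclass
class TuningParams:
    """Thresholds and shuffle settings of the ROC classification."""

    bin_s: float = 1.0
    auc_hi: float = 0.7
    auc_lo: float = 0.3
    n_shuffles: int = 1000
    null_pct: float = 95.0
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.auc_hi < 1:
            raise ValueError(f"auc_hi must be in (0.5, 1), got {self.auc_hi}")
        if not 0 < self.auc_lo < 0.5:
            raise ValueError(f"auc_lo must be in (0, 0.5), got {self.auc_lo}")
        if self.n_shuffles < 1:
            raise ValueError(f"n_shuffles must be >= 1, got {self.n_shuffles}")
        if not 50 < self.null_pct < 100:
            raise ValueError(f"null_pct must be in (50, 100), got {self.null_pct}")
        if not self.bin_s > 0:
            raise ValueError(f"bin_s must be positive, got {self.bin_s}")


def bin_epoch_values(traces, timeline: SessionTimeline, epoch_label: str,
                     bin_s: float = 1.0):
    """Per-bin mean activity within one epoch (complete bins only).

    ``traces`` may be a :class:`TraceMatrix` (returns a neurons x bins
    array) or a tuple ``(values, fs, t0)`` for a single series.
    """
    if isinstance(traces, TraceMatrix):
        values, fs, t0 = traces.values, traces.fs, traces.t0
    else:
        values, fs, t0 = traces
    ep = timeline.epoch(epoch_label)
    means, _ = bin_means(values, fs, t0, ep.start_s, ep.end_s, bin_s)
    return means


def compute_auc(baseline_bins, epoch_bins) -> float:
    """Rank-sum AUC of epoch vs baseline bin values; ties credit 0.5."""
    b = np.asarray(baseline_bins, dtype=float).ravel()
    e = np.asarray(epoch_bins, dtype=float).ravel()
    if b.size == 0 or e.size == 0:
        raise ValueError("baseline and epoch bin lists must be non-empty")
    ranks = rankdata(np.concatenate([b, e]))
    r_e = ranks[b.size:].sum()
    return float((r_e - e.size * (e.size + 1) / 2.0) / (b.size * e.size))


def build_null(baseline_bins, epoch_bins, n_shuffles: int = 1000,
               seed=0) -> np.ndarray:
    """Permutation null of the AUC.

    Each shuffle pools all bin values, randomly re-assigns them to the two
    epochs preserving the original sizes, and recomputes the AUC. Because
    ranks are permutation-invariant, the pooled values are ranked once and
    the shuffled AUCs are computed from permuted ranks.
    """
    b = np.asarray(baseline_bins, dtype=float).ravel()
    e = np.asarray(epoch_bins, dtype=float).ravel()
    if b.size == 0 or e.size == 0:
        raise ValueError("baseline and epoch bin lists must be non-empty")
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranks = rankdata(np.concatenate([b, e]))
    perm = rng.permuted(np.tile(ranks, (int(n_shuffles), 1)), axis=1)
    r_e = perm[:, b.size:].sum(axis=1)
    return (r_e - e.size * (e.size + 1) / 2.0) / (b.size * e.size)


def classify_neuron(auc: float, null: np.ndarray,
                    params: TuningParams | None = None) -> str:
    """Dual-criterion label from the AUC and its shuffle null."""
    p = params or TuningParams()
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution must be non-empty")
    hi = np.percentile(null, p.null_pct)
    lo = np.percentile(null, 100.0 - p.null_pct)
    if auc > p.auc_hi and auc > hi:
        return "reunion"
    if auc < p.auc_lo and auc < lo:
        return "isolation"
    return "none"


class TuningClassifier(BaseEstimator):
    """Classify every neuron in a population as isolation/reunion tuned.

    Scikit-learn style estimator: construct with parameters, call
    :meth:`fit` with a :class:`TraceMatrix` and a
    :class:`SessionTimeline`, then read the fitted attributes.

    Parameters
    ----------
    baseline_label, epoch_label : str
        Timeline labels of the baseline (isolation) and comparison
        (reunion) epochs.
    bin_s : float
        ROC bin width in seconds.
    auc_hi, auc_lo : float
        AUC thresholds for reunion/isolation labels.
    n_shuffles : int
        Shuffles per neuron for the permutation null.
    null_pct : float
        Null percentile criterion (the isolation criterion uses the
        symmetric ``100 - null_pct`` percentile).
    random_state : int
        Master seed; each neuron draws from a substream keyed by a CRC of
        its neuron ID, so results do not depend on neuron order.

    Attributes
    ----------
    table_ : pandas.DataFrame
        One row per neuron: ``neuron_id``, ``auc``, ``null_low``,
        ``null_high``, ``label``, ``reunion_strength``,
        ``isolation_strength``.
    labels_ : numpy.ndarray of str
    counts_ : dict
        Number of neurons per label.
    """

    def __init__(self, baseline_label: str = "baseline",
                 epoch_label: str = "reunion", bin_s: float = 1.0,
                 auc_hi: float = 0.7, auc_lo: float = 0.3,
                 n_shuffles: int = 1000, null_pct: float = 95.0,
                 random_state: int = 0):
        self.baseline_label = baseline_label
        self.epoch_label = epoch_label
        self.bin_s = bin_s
        self.auc_hi = auc_hi
        self.auc_lo = auc_lo
        self.n_shuffles = n_shuffles
        self.null_pct = null_pct
        self.random_state = random_state

    def _params(self) -> TuningParams:
        return TuningParams(
            bin_s=self.bin_s, auc_hi=self.auc_hi, auc_lo=self.auc_lo,
            n_shuffles=self.n_shuffles, null_pct=self.null_pct,
            seed=self.random_state,
        )

    def fit(self, traces: TraceMatrix, timeline: SessionTimeline):
        p = self._params()
        if traces.n_neurons == 0:
            raise ValidationError("cannot classify an empty population (0 neurons)")
        base = bin_epoch_values(traces, timeline, self.baseline_label, p.bin_s)
        epoch = bin_epoch_values(traces, timeline, self.epoch_label, p.bin_s)
        base = np.atleast_2d(base)
        epoch = np.atleast_2d(epoch)
        n, m = base.shape[1], epoch.shape[1]

        pooled = np.concatenate([base, epoch], axis=1)
        ranks = rankdata(pooled, axis=1)
        aucs = (ranks[:, n:].sum(axis=1) - m * (m + 1) / 2.0) / (n * m)

        rows = []
        for i, nid in enumerate(traces.neuron_ids):
            rng = np.random.default_rng(
                [int(self.random_state), zlib.crc32(str(nid).encode())]
            )
            null = build_null(base[i], epoch[i], p.n_shuffles, rng)
            lo = float(np.percentile(null, 100.0 - p.null_pct))
            hi = float(np.percentile(null, p.null_pct))
            label = classify_neuron(aucs[i], null, p)
            rows.append(
                {
                    "neuron_id": nid,
                    "auc": float(aucs[i]),
                    "null_low": lo,
                    "null_high": hi,
                    "label": label,
                    "reunion_strength": float(aucs[i]),
                    "isolation_strength": float(1.0 - aucs[i]),
                }
            )
        self.table_ = pd.DataFrame(rows)
        self.labels_ = self.table_["label"].to_numpy()
        self.counts_ = {
            lab: int((self.labels_ == lab).sum()) for lab in LABELS
        }
        return self

    def tuned_ids(self) -> list[str]:
        """IDs of neurons labelled isolation or reunion."""
        t = self.table_
        return t.loc[t["label"] != "none", "neuron_id"].tolist()


def classify_population(traces: TraceMatrix, timeline: SessionTimeline,
                        params: TuningParams | None = None,
                        baseline_label: str = "baseline",
                        epoch_label: str = "reunion") -> pd.DataFrame:
    """Functional wrapper over :class:`TuningClassifier`; returns the table."""
    p = params or TuningParams()
    clf = TuningClassifier(
        baseline_label=baseline_label, epoch_label=epoch_label, bin_s=p.bin_s,
        auc_hi=p.auc_hi, auc_lo=p.auc_lo, n_shuffles=p.n_shuffles,
        null_pct=p.null_pct, random_state=p.seed,
    )
    return clf.fit(traces, timeline).table_


def classify_multihour(blocks, timelines, params: TuningParams | None = None,
                       baseline_label: str = "baseline",
                       epoch_label: str = "reunion") -> pd.DataFrame:
    """Classify per hourly block and combine across blocks.

    A neuron is tuned overall if it meets the classification criterion in
    at least one block (isolation labels take precedence over reunion when
    both occur across blocks). ``timelines`` may be one timeline shared by
    all blocks or one per block.

    Returns a table with one ``label_block<k>`` column per block plus the
    combined ``label``.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("need at least one block")
    if isinstance(timelines, SessionTimeline):
        timelines = [timelines] * len(blocks)
    timelines = list(timelines)
    if len(timelines) != len(blocks):
        raise ValueError("need one timeline per block (or a single shared one)")
    ids = blocks[0].neuron_ids
    for k, blk in enumerate(blocks[1:], start=1):
        if blk.neuron_ids != ids:
            raise ValidationError(f"block {k} neuron IDs differ from block 0")
    out = pd.DataFrame({"neuron_id": ids})
    per_block = []
    for k, (blk, tl) in enumerate(zip(blocks, timelines)):
        tab = classify_population(blk, tl, params, baseline_label, epoch_label)
        out[f"label_block{k}"] = tab["label"].to_numpy()
        per_block.append(tab["label"].to_numpy())
    per_block = np.stack(per_block, axis=1)
    combined = np.where(
        (per_block == "isolation").any(axis=1), "isolation",
        np.where((per_block == "reunion").any(axis=1), "reunion", "none"),
    )
    out["label"] = combined
    return out


def match_cells(rois_a, rois_b, threshold: float = 0.7):
    """Greedy one-to-one cross-session cell matching by footprint overlap.

    ROIs are iterables of pixel coordinates (any hashable pixel key).
    Overlap is intersection-over-union; candidate pairs are taken in
    descending overlap and accepted iff overlap > ``threshold``.

    Returns a list of ``(index_a, index_b, overlap)`` tuples.
    """
    sets_a = [frozenset(map(tuple, r)) for r in rois_a]
    sets_b = [frozenset(map(tuple, r)) for r in rois_b]
    for name, sets in (("a", sets_a), ("b", sets_b)):
        for i, s in enumerate(sets):
            if not s:
                raise ValidationError(f"ROI {i} in set {name} is empty")
    pairs = []
    for i, a in enumerate(sets_a):
        for j, b in enumerate(sets_b):
            inter = len(a & b)
            if inter:
                pairs.append((inter / len(a | b), i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, matches = set(), set(), []
    for ov, i, j in pairs:
        if ov <= threshold:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j, ov))
    return matches


def ensemble_activity(traces: TraceMatrix, member_ids, timeline: SessionTimeline,
                      epoch_label: str) -> pd.Series:
    """Per-neuron epoch-mean z-scored activity of an ensemble.

    Each member's trace is z-scored over the full session, then averaged
    over the epoch; the result is suitable for paired comparisons of the
    same ensemble across conditions.
    """
    sub = traces.select(member_ids)
    mu = sub.values.mean(axis=1, keepdims=True)
    sd = sub.values.std(axis=1, keepdims=True)
    if (sd == 0).any():
        flat = [nid for nid, s in zip(sub.neuron_ids, sd.ravel()) if s == 0]
        raise ValidationError(f"zero-variance member trace(s): {flat}")
    z = (sub.values - mu) / sd
    ep = timeline.epoch(epoch_label)
    sl = sub.epoch_samples(ep.start_s, ep.end_s)
    return pd.Series(z[:, sl].mean(axis=1), index=pd.Index(sub.neuron_ids, name="neuron_id"))
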