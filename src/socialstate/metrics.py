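"""Per-neuron activity dynamics: modulated durations, ramps, averaging.

A neuron's activity during a comparison epoch is called *activated* in a
1-s bin when the bin mean exceeds the baseline mean by more than two
baseline SDs, and *inhibited* when it falls below 30% of the baseline
mean. Total modulated duration counts such bins; persistent modulation is
the longest contiguous run. Ramping across hours of isolation is detected
by a Pearson linear-correlation test of 5-min-binned activity against
time. Per-neuron values are averaged within animals for group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._binning import bin_means
from .io import SessionTimeline, TraceMatrix, ValidationError

__all__ = [
    "BaselineStats",
    "baseline_stats",
    "modulation_masks",
    "modulated_duration",
    "persistent_duration",
    "ramp_test",
    "ramp_profile",
    "animal_average",
    "modulation_profile",
]


@dataclass
class BaselineStats:
    """Mean and SD of a trace over its baseline epoch (native samples)."""

    mean: float
    sd: float
    epoch_label: str = "baseline"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


def baseline_stats(values, fs: float, t0: float, timeline: SessionTimeline,
                   epoch_label: str = "baseline") -> BaselineStats:
    """Baseline mean/SD of one trace at native sampling resolution."""
    v = np.asarray(values, dtype=float).ravel()
    ep = timeline.epoch(epoch_label)
    eps = 1e-9
    i0 = max(int(np.ceil((ep.start_s - t0) * fs - eps)), 0)
    i1 = min(int(np.ceil((ep.end_s - t0) * fs - eps)), v.size)
    if i1 <= i0:
        raise ValueError(f"no samples in baseline epoch {epoch_label!r}")
    seg = v[i0:i1]
    return BaselineStats(float(seg.mean()), float(seg.std()), epoch_label)


def modulation_masks(values, fs: float, t0: float, timeline: SessionTimeline,
                     epoch_label: str, stats_: BaselineStats, bin_s: float = 1.0):
    """Boolean activated/inhibited series over the epoch's 1-s bins.

    Activated: bin mean > baseline mean + 2 SD. Inhibited: bin mean <
    30% of the baseline mean; this rule needs a positive baseline mean
    and raises otherwise (near-zero dF/F makes a relative threshold
    ill-posed).
    """
    if stats_.mean <= 0:
        raise ValidationError(
            f"inhibition rule undefined: baseline mean is {stats_.mean:g} <= 0"
        )
    ep = timeline.epoch(epoch_label)
    bins, _ = bin_means(values, fs, t0, ep.start_s, ep.end_s, bin_s)
    activated = bins > stats_.mean + 2.0 * stats_.sd
    inhibited = bins < 0.3 * stats_.mean
    return activated, inhibited


def modulated_duration(values, fs: float, t0: float, timeline: SessionTimeline,
                       epoch_label: str, stats_: BaselineStats,
                       bin_s: float = 1.0):
    """Total activated and inhibited seconds within the epoch."""
    activated, inhibited = modulation_masks(
        values, fs, t0, timeline, epoch_label, stats_, bin_s
    )
    return float(activated.sum() * bin_s), float(inhibited.sum() * bin_s)


def persistent_duration(significant, bin_s: float = 1.0) -> float:
    """Longest contiguous run of significant bins, in seconds."""
    s = np.asarray(significant, dtype=bool).ravel()
    if s.size == 0:
        raise ValueError("significance series must be non-empty")
    padded = np.concatenate([[0], s.view(np.int8), [0]])
    edges = np.flatnonzero(np.diff(padded))
    if edges.size == 0:
        return 0.0
    runs = edges[1::2] - edges[0::2]
    return float(runs.max() * bin_s)


def ramp_test(bin_values, bin_times=None, alpha: float = 0.05):
    """Linear-correlation ramp detection on binned activity.

    Pearson correlation of per-bin mean activity against bin time; the
    neuron is flagged ``up``/``down`` when the two-sided p-value is below
    ``alpha`` with the corresponding sign. Constant activity is defined
    as r = 0, flag ``none``.

    Returns ``(r, p, flag)``.
    """
    y = np.asarray(bin_values, dtype=float).ravel()
    if y.size < 3:
        raise ValueError(f"need >= 3 bins, got {y.size}")
    x = (np.arange(y.size, dtype=float) if bin_times is None
         else np.asarray(bin_times, dtype=float).ravel())
    if x.size != y.size:
        raise ValueError("bin_times length must match bin_values")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0, 1.0, "none"
    r, p = stats.pearsonr(x, y)
    flag = "none"
    if p < alpha:
        flag = "up" if r > 0 else "down"
    return float(r), float(p), flag


def ramp_profile(blocks, bin_s: float = 300.0, alpha: float = 0.05) -> pd.DataFrame:
    """Ramp detection across hourly imaging blocks for a whole population.

    Each block (a :class:`TraceMatrix` whose ``t0`` encodes its start on
    the session clock) is averaged in ``bin_s`` bins (5 min by default);
    the concatenated per-bin means are tested against bin time with
    :func:`ramp_test`.

    Returns a table with ``neuron_id``, ``ramp_r``, ``ramp_p``, ``ramp_flag``.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("need at least one block")
    ids = blocks[0].neuron_ids
    for k, b in enumerate(blocks[1:], start=1):
        if b.neuron_ids != ids:
            raise ValidationError(f"block {k} neuron IDs differ from block 0")
    means, times = [], []
    for b in blocks:
        m, t = bin_means(b.values, b.fs, b.t0, b.t0,
                         b.t0 + b.n_samples / b.fs, bin_s)
        means.append(np.atleast_2d(m))
        times.append(t)
    means = np.concatenate(means, axis=1)
    times = np.concatenate(times)
    rows = []
    for i, nid in enumerate(ids):
        r, p, flag = ramp_test(means[i], times, alpha)
        rows.append({"neuron_id": nid, "ramp_r": r, "ramp_p": p,
                     "ramp_flag": flag})
    return pd.DataFrame(rows)


def animal_average(per_neuron_values, animal_map) -> pd.Series:
    """Arithmetic mean of per-neuron values within each animal.

    ``per_neuron_values`` maps neuron ID to a value (mapping or Series);
    ``animal_map`` maps every neuron ID to its animal. Unmapped neurons
    raise; animals present in the map but contributing no neurons are
    simply absent from the result.
    """
    vals = pd.Series(per_neuron_values, dtype=float)
    amap = pd.Series(animal_map)
    unmapped = [str(n) for n in vals.index if n not in amap.index]
    if unmapped:
        raise ValidationError(f"neuron(s) not mapped to an animal: {unmapped}")
    out = vals.groupby(amap.reindex(vals.index)).mean()
    out.index.name = "animal"
    return out


def modulation_profile(traces: TraceMatrix, timeline: SessionTimeline,
                       baseline_label: str = "baseline",
                       epoch_label: str = "reunion",
                       bin_s: float = 1.0) -> pd.DataFrame:
    """Modulated/persistent durations for every neuron of a population.

    Neurons whose baseline mean is not positive (for which the 30%
    inhibition rule is undefined) are reported with NaN durations and
    ``valid = False`` rather than silently skipped.
    """
    rows = []
    for i, nid in enumerate(traces.neuron_ids):
        v = traces.values[i]
        st = baseline_stats(v, traces.fs, traces.t0, timeline, baseline_label)
        row = {"neuron_id": nid, "baseline_mean": st.mean, "baseline_sd": st.sd}
        try:
            act, inh = modulation_masks(
                v, traces.fs, traces.t0, timeline, epoch_label, st, bin_s
            )
        except ValidationError:
            row.update(
                activated_s=np.nan, inhibited_s=np.nan,
                persistent_activated_s=np.nan, persistent_inhibited_s=np.nan,
                valid=False,
            )
        else:
            row.update(
                activated_s=float(act.sum() * bin_s),
                inhibited_s=float(inh.sum() * bin_s),
                persistent_activated_s=persistent_duration(act, bin_s),
                persistent_inhibited_s=persistent_duration(inh, bin_s),
                valid=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
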