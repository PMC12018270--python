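"""Two-channel fibre-photometry processing.

Motion artifacts shared between the sensor and control fluorophore
channels are removed by pointwise subtraction of the control from the
sensor signal. The corrected trace is z-scored against a 30-s baseline
window immediately preceding the alignment event (e.g. reunion onset).
Event-locked responses are called significant in 1-s bins whose value
exceeds the upper bound of the baseline 95% percentile interval, and
traces from several animals are aligned at the event and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._binning import bin_means
from .io import PhotometrySession, ValidationError

__all__ = [
    "CorrectedTrace",
    "motion_correct",
    "zscore_to_baseline",
    "significance_mask",
    "align_events",
]


@dataclass
class CorrectedTrace:
    """Artifact-corrected photometry trace, optionally z-scored."""

    values: np.ndarray
    fs: float
    z: np.ndarray | None = None
    baseline_window: tuple | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


def motion_correct(session: PhotometrySession,
                   scale_control: bool = False) -> CorrectedTrace:
    """Subtract the control channel from the sensor channel.

    The default is plain pointwise subtraction. ``scale_control=True``
    instead removes the least-squares projection of the signal onto the
    control channel (a robustness option for control channels with a
    different gain), off by default.
    """
    sig, ctl = session.signal, session.control
    if sig.shape != ctl.shape:
        raise ValidationError("signal and control lengths differ")
    if scale_control:
        c = ctl - ctl.mean()
        denom = float(c @ c)
        beta = float(c @ (sig - sig.mean())) / denom if denom > 0 else 0.0
        corrected = sig - beta * ctl
    else:
        corrected = sig - ctl
    return CorrectedTrace(np.asarray(corrected, dtype=float), session.fs)


def zscore_to_baseline(corrected: CorrectedTrace, event_time: float,
                       baseline_s: float = 30.0) -> CorrectedTrace:
    """Z-score against the ``[event - baseline_s, event)`` window."""
    fs = corrected.fs
    if event_time < baseline_s:
        raise ValueError(
            f"event at {event_time} s leaves no {baseline_s}-s baseline window"
        )
    eps = 1e-9
    i0 = int(np.ceil((event_time - baseline_s) * fs - eps))
    i1 = int(np.ceil(event_time * fs - eps))
    i1 = min(i1, corrected.values.size)
    base = corrected.values[i0:i1]
    if base.size == 0:
        raise ValueError("baseline window contains no samples")
    mu, sd = float(base.mean()), float(base.std())
    if sd == 0:
        raise ValidationError("zero-variance baseline window")
    z = (corrected.values - mu) / sd
    return CorrectedTrace(corrected.values, fs, z=z,
                          baseline_window=(event_time - baseline_s, event_time))


def significance_mask(trace: CorrectedTrace, bin_s: float = 1.0,
                      upper_pct: float = 97.5):
    """Per-1-s-bin significance of enhanced activity vs baseline.

    The threshold is the ``upper_pct`` percentile (upper bound of the 95%
    interval) of the raw baseline-window z samples; the z trace is
    averaged in ``bin_s`` bins and bins above the threshold are flagged.

    Returns ``(mask, bin_times, threshold)``.
    """
    if trace.z is None or trace.baseline_window is None:
        raise ValueError("trace must be z-scored first (zscore_to_baseline)")
    n = trace.z.size
    bins, times = bin_means(trace.z, trace.fs, 0.0, 0.0, n / trace.fs, bin_s)
    w0, w1 = trace.baseline_window
    eps = 1e-9
    i0 = max(int(np.ceil(w0 * trace.fs - eps)), 0)
    i1 = min(int(np.ceil(w1 * trace.fs - eps)), n)
    if i1 <= i0:
        raise ValueError("baseline window holds no samples")
    thr = float(np.percentile(trace.z[i0:i1], upper_pct))
    return bins > thr, times, thr


def align_events(traces, event_times, window=(30.0, 60.0)):
    """Stack event-aligned windows across animals and average.

    ``traces`` is a list of :class:`CorrectedTrace` (z-scored traces are
    used when present, raw corrected values otherwise); ``event_times``
    gives one alignment time per animal; ``window`` is ``(pre_s,
    post_s)`` around the event. Windows that would extend past a session
    are an error naming the animal.

    Returns ``(aligned, rel_times, mean, sem)`` with ``aligned`` of shape
    (n_animals, n_samples); the SEM uses the population SD over animals
    (zero for a single animal).
    """
    traces = list(traces)
    event_times = list(event_times)
    if len(traces) != len(event_times):
        raise ValueError("need one event time per trace")
    if not traces:
        raise ValueError("need at least one trace")
    fs = traces[0].fs
    pre, post = window
    n_pre, n_post = int(round(pre * fs)), int(round(post * fs))
    segs = []
    for a, (tr, ev) in enumerate(zip(traces, event_times)):
        if tr.fs != fs:
            raise ValueError(f"animal {a}: sampling rate {tr.fs} != {fs}")
        v = tr.z if tr.z is not None else tr.values
        i = int(round(ev * fs))
        if i - n_pre < 0 or i + n_post > v.size:
            raise ValueError(
                f"animal {a}: window [{ev - pre}, {ev + post}) s truncated by "
                f"session bounds"
            )
        segs.append(v[i - n_pre: i + n_post])
    aligned = np.stack(segs)
    rel = (np.arange(-n_pre, n_post)) / fs
    mean = aligned.mean(axis=0)
    sem = aligned.std(axis=0, ddof=0) / np.sqrt(aligned.shape[0])
    return aligned, rel, mean, sem
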