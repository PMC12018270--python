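"""Population state-space analysis: PCA trajectories, distance, decoding.

The joint activity of state-tuned neurons is z-scored per neuron over the
session, binned, and projected onto principal components with time bins
as observations. The population's distance from its baseline (isolation)
state is the Euclidean distance, in the subspace of the fewest components
explaining 95% of variance, between each 1-s bin's score vector and the
mean baseline score. A subsampling procedure (random halves of the
population) yields a spread for that distance; the latency for the state
to return to baseline after partner removal is the first sustained
crossing below the upper bound of the baseline distance's 95% interval.
Social state is decoded from single-bin population vectors with linear
support-vector classifiers on stratified 80/20 splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from ._binning import bin_means
from .io import SessionTimeline, TraceMatrix, ValidationError

__all__ = [
    "zscore_traces",
    "StateTrajectory",
    "pca_trajectory",
    "distance_to_baseline",
    "subsample_distance",
    "ReturnEstimate",
    "return_latency",
    "PopulationTrajectory",
    "StateDecoder",
    "decode_states",
    "bin_population",
    "state_labels",
]


def zscore_traces(traces: TraceMatrix, on_constant: str = "raise"):
    """Z-score each neuron's trace over the full session.

    Zero-variance neurons make the z-score undefined; with
    ``on_constant='drop'`` they are excluded and reported in the second
    return value, with ``'raise'`` (default) they raise.

    Returns ``(z_traces, excluded_ids)``.
    """
    mu = traces.values.mean(axis=1, keepdims=True)
    sd = traces.values.std(axis=1, keepdims=True)
    flat = sd.ravel() == 0
    excluded = [nid for nid, f in zip(traces.neuron_ids, flat) if f]
    if excluded:
        if on_constant == "raise":
            raise ValidationError(f"zero-variance neuron(s): {excluded}")
        warnings.warn(f"excluding zero-variance neuron(s): {excluded}")
    keep = ~flat
    z = (traces.values[keep] - mu[keep]) / sd[keep]
    kept_ids = [nid for nid, f in zip(traces.neuron_ids, flat) if not f]
    return TraceMatrix(z, kept_ids, traces.fs, traces.t0), excluded


def bin_population(traces: TraceMatrix, bin_s: float):
    """Bins x neurons feature matrix over the full session.

    Returns ``(X, bin_start_times)``.
    """
    means, starts = bin_means(
        traces.values, traces.fs, traces.t0, traces.t0,
        traces.t0 + traces.n_samples / traces.fs, bin_s,
    )
    return means.T, starts


def state_labels(timeline: SessionTimeline, bin_times, bin_s: float) -> np.ndarray:
    """Epoch label of each bin (a bin must lie wholly inside one epoch)."""
    labels = []
    for t in np.asarray(bin_times, dtype=float):
        a, b = timeline.label_at(t + 1e-9), timeline.label_at(t + bin_s - 1e-9)
        labels.append(a if a == b and a is not None else "")
    return np.asarray(labels, dtype=object)


@dataclass
class StateTrajectory:
    """PCA trajectory of population activity.

    ``scores`` holds all-bin scores on all components (bins x PCs);
    ``explained_var`` the per-component variance fractions; ``k95`` the
    smallest number of leading components whose cumulative explained
    variance reaches 95%.
    """

    scores: np.ndarray
    explained_var: np.ndarray
    k95: int
    bin_s: float
    bin_times: np.ndarray
    pca: PCA = field(repr=False)
    neuron_ids: list = field(default_factory=list, repr=False)


def pca_trajectory(z: TraceMatrix, bin_s: float = 5.0) -> StateTrajectory:
    """Fit the population trajectory on ``bin_s``-binned z-scores.

    Time bins are observations, neurons are features. The full component
    basis is retained so 1-s bins can later be projected into the same
    space for distance analysis.
    """
    if z.n_neurons < 2:
        raise ValueError(f"need >= 2 neurons, got {z.n_neurons}")
    X, starts = bin_population(z, bin_s)
    if X.shape[0] < 3:
        raise ValueError(f"need >= 3 time bins, got {X.shape[0]}")
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    ev = pca.explained_variance_ratio_
    k95 = int(np.searchsorted(np.cumsum(ev), 0.95 - 1e-12) + 1)
    k95 = min(max(k95, 1), ev.size)
    return StateTrajectory(scores, ev, k95, bin_s, starts, pca, list(z.neuron_ids))


def distance_to_baseline(z: TraceMatrix, trajectory: StateTrajectory,
                         timeline: SessionTimeline,
                         baseline_label: str = "baseline",
                         bin_s: float = 1.0, n_components: int | None = None):
    """Per-bin Euclidean distance of the population state to baseline.

    Each ``bin_s`` bin of the z-scored population is projected onto the
    trajectory's leading ``n_components`` (default: the trajectory's k95)
    and its distance to the mean baseline-epoch score vector is returned.

    Returns ``(distance, bin_times)``.
    """
    k = trajectory.k95 if n_components is None else int(n_components)
    X, times = bin_population(z, bin_s)
    scores = trajectory.pca.transform(X)[:, :k]
    ep = timeline.epoch(baseline_label)
    in_base = (times >= ep.start_s - 1e-9) & (times + bin_s <= ep.end_s + 1e-9)
    if not in_base.any():
        raise ValueError(f"no complete {bin_s}-s bins inside {baseline_label!r}")
    base_mean = scores[in_base].mean(axis=0)
    dist = np.linalg.norm(scores - base_mean, axis=1)
    return dist, times


def subsample_distance(z: TraceMatrix, timeline: SessionTimeline,
                       baseline_label: str = "baseline",
                       n_repeats: int = 100, frac: float = 0.5,
                       seed: int = 0, bin_traj: float = 5.0,
                       bin_dist: float = 1.0):
    """Distance-to-baseline spread across random neuron subsamples.

    Each repeat draws ``frac`` of the neurons without replacement,
    refits the PCA trajectory on that half (z-scores are reused, not
    recomputed) and recomputes the distance series. Because Euclidean
    distance grows with the square root of the population size, each
    subsample's distances are rescaled by ``sqrt(n_full / n_sub)`` so the
    band is on the full-population scale. Returns the per-bin mean and SD
    across repeats plus the bin times.
    """
    if z.n_neurons < 4:
        raise ValueError(f"need >= 4 neurons for subsampling, got {z.n_neurons}")
    n_sub = max(int(np.floor(frac * z.n_neurons)), 2)
    rng = np.random.default_rng(seed)
    dists = []
    for _ in range(int(n_repeats)):
        rows = rng.choice(z.n_neurons, size=n_sub, replace=False)
        sub = TraceMatrix(z.values[rows], [z.neuron_ids[r] for r in rows],
                          z.fs, z.t0)
        traj = pca_trajectory(sub, bin_traj)
        d, times = distance_to_baseline(sub, traj, timeline, baseline_label,
                                        bin_dist)
        dists.append(d * np.sqrt(z.n_neurons / n_sub))
    dists = np.stack(dists)
    return dists.mean(axis=0), dists.std(axis=0), times


@dataclass
class ReturnEstimate:
    """Return of the population state to baseline after partner removal."""

    threshold: float
    latency_s: float  # NaN when the state never returns
    time_below_s: float
    sustain_bins: int

    @property
    def returned(self) -> bool:
        return bool(np.isfinite(self.latency_s))


def return_latency(distance, bin_times, timeline: SessionTimeline,
                   baseline_label: str, removal_time: float,
                   bin_s: float = 1.0, upper_pct: float = 97.5,
                   sustain_bins: int = 3) -> ReturnEstimate:
    """Latency for the distance series to return below the baseline bound.

    The threshold is the ``upper_pct`` percentile (upper bound of the 95%
    interval by default) of the baseline-epoch distances. The return time
    is the first post-removal bin opening a run of at least
    ``sustain_bins`` consecutive sub-threshold bins; ``latency_s`` is NaN
    when no such run exists. ``time_below_s`` totals sub-threshold time
    from the return onward.
    """
    d = np.asarray(distance, dtype=float).ravel()
    times = np.asarray(bin_times, dtype=float).ravel()
    if d.shape != times.shape:
        raise ValueError("distance and bin_times must have equal length")
    if not (times[0] <= removal_time <= times[-1] + bin_s):
        raise ValueError(f"removal_time {removal_time} outside the series")
    ep = timeline.epoch(baseline_label)
    in_base = (times >= ep.start_s - 1e-9) & (times + bin_s <= ep.end_s + 1e-9)
    if not in_base.any():
        raise ValueError(f"no bins inside baseline epoch {baseline_label!r}")
    thr = float(np.percentile(d[in_base], upper_pct))
    post = np.flatnonzero(times >= removal_time - 1e-9)
    below = d[post] <= thr
    k = max(int(sustain_bins), 1)
    run = np.convolve(below.astype(int), np.ones(k, dtype=int), mode="valid")
    hits = np.flatnonzero(run == k)
    if hits.size == 0:
        return ReturnEstimate(thr, float("nan"), 0.0, k)
    i0 = int(hits[0])
    latency = float(times[post[i0]] - removal_time)
    time_below = float(below[i0:].sum() * bin_s)
    return ReturnEstimate(thr, latency, time_below, k)


class PopulationTrajectory(BaseEstimator):
    """Estimator wrapper: z-score, fit PCA trajectory, derive distances.

    ``fit`` takes a :class:`TraceMatrix` (tuned-neuron traces);
    ``transform`` projects a (possibly different) population binning onto
    the fitted components. Fitted attributes: ``trajectory_``, ``z_``,
    ``excluded_ids_``, ``explained_var_``, ``k95_``.
    """

    def __init__(self, bin_s: float = 5.0, on_constant: str = "drop"):
        self.bin_s = bin_s
        self.on_constant = on_constant

    def fit(self, traces: TraceMatrix, y=None):
        self.z_, self.excluded_ids_ = zscore_traces(traces, self.on_constant)
        self.trajectory_ = pca_trajectory(self.z_, self.bin_s)
        self.explained_var_ = self.trajectory_.explained_var
        self.k95_ = self.trajectory_.k95
        return self

    def transform(self, traces: TraceMatrix | None = None, bin_s: float | None = None):
        z = self.z_ if traces is None else zscore_traces(traces, self.on_constant)[0]
        X, _ = bin_population(z, bin_s or self.bin_s)
        return self.trajectory_.pca.transform(X)

    def distance(self, timeline: SessionTimeline, baseline_label: str = "baseline",
                 bin_s: float = 1.0):
        return distance_to_baseline(self.z_, self.trajectory_, timeline,
                                    baseline_label, bin_s)


class StateDecoder(BaseEstimator):
    """Linear support-vector decoding of social state from population bins.

    Each repeat draws a stratified random ``train_frac`` split, fits a
    linear-kernel SVC (C = 1) on the training bins and scores accuracy on
    the held-out bins. Fitted attributes: ``accuracies_``,
    ``mean_accuracy_``, ``classifier_`` (refit on all data).
    """

    def __init__(self, train_frac: float = 0.8, n_repeats: int = 100,
                 C: float = 1.0, random_state: int = 0):
        self.train_frac = train_frac
        self.n_repeats = n_repeats
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 states to decode")
        if counts.min() < 5:
            small = classes[counts < 5].tolist()
            raise ValueError(f"state(s) with fewer than 5 bins: {small}")
        if not 0 < self.train_frac < 1:
            raise ValueError(f"train_frac must be in (0, 1), got {self.train_frac}")
        ss = np.random.SeedSequence(self.random_state)
        accs = []
        for child in ss.spawn(int(self.n_repeats)):
            split_seed = int(child.generate_state(1)[0] % (2**31))
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=self.train_frac, stratify=y,
                random_state=split_seed,
            )
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(Xtr, ytr)
            accs.append(float(clf.score(Xte, yte)))
        self.accuracies_ = np.asarray(accs)
        self.mean_accuracy_ = float(self.accuracies_.mean())
        self.classifier_ = SVC(kernel="linear", C=self.C).fit(X, y)
        self.classes_ = classes
        return self

    def predict(self, X):
        return self.classifier_.predict(np.asarray(X, dtype=float))


def decode_states(X, labels, train_frac: float = 0.8, n_repeats: int = 100,
                  seed: int = 0, C: float = 1.0) -> np.ndarray:
    """Held-out decoding accuracies over stratified random splits."""
    dec = StateDecoder(train_frac=train_frac, n_repeats=n_repeats, C=C,
                       random_state=seed)
    return dec.fit(X, labels).accuracies_
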