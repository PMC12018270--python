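"""Synthetic two-state calcium populations, photometry and ethograms.

The generator emulates the statistical structure the downstream analyses
assume, with full ground truth:

* slow-timescale state-tuned calcium activity — each neuron emits a
  homogeneous Poisson event train whose rate switches instantaneously at
  epoch boundaries, convolved with an exponential calcium kernel
  ``exp(-t / kernel_tau)`` (GCaMP6s-like, tau = 1.5 s, unit dF/F amplitude
  per event) plus additive Gaussian noise;
* isolation-tuned neurons fire at ``rate_hi`` while the animal is alone
  (baseline and re-isolation epochs) and drop to ``rate_lo`` during
  reunion; reunion-tuned neurons do the reverse; untuned neurons keep a
  constant rate; ramping neurons (multi-hour sessions) increase their rate
  linearly per hour of isolation;
* two-channel photometry with transients at event times, a shared
  slow motion artifact in both channels, and independent sensor noise;
* Markov-chain behavioural ethograms with exponential bout durations and
  inter-bout gaps.

Determinism: every generator draws from substreams derived from one master
seed and a per-unit counter (neuron index, hour, channel), so the same
configuration and seed reproduce outputs bit for bit, and adding neurons
does not perturb the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io import (
    BehaviorAnnotation,
    ConfigError,
    Epoch,
    PhotometrySession,
    SessionTimeline,
    TraceMatrix,
)

__all__ = [
    "CLASSES",
    "MODULES",
    "SynthConfig",
    "default_timeline",
    "generate_session",
    "generate_multihour",
    "generate_photometry",
    "generate_ethogram",
]

CLASSES = ("isolation", "reunion", "ramping", "untuned")

#: Scored social behavioural modules.
MODULES = ("approach", "sniff", "crawl-under", "head-to-head", "allogroom")


def default_timeline() -> SessionTimeline:
    """5-min baseline isolation, 5-min reunion, 5-min re-isolation."""
    return SessionTimeline(
        [
            Epoch("baseline", 0.0, 300.0),
            Epoch("reunion", 300.0, 600.0),
            Epoch("reisolation", 600.0, 900.0),
        ]
    )


@dataclass
class SynthConfig:
    """Configuration of a synthetic state-tuned calcium population.

    Parameters
    ----------
    n_neurons : int
        Population size.
    fractions : dict
        Proportion of neurons per tuned class (keys among ``isolation``,
        ``reunion``, ``ramping``); the remainder is untuned. Assignment is
        deterministic by index (the first ``floor(f * n)`` neurons of each
        class in the order above), so requested fractions are exact.
    rate_hi, rate_lo : float
        Poisson event rates (events/s) in the preferred and non-preferred
        state.
    kernel_tau : float
        Calcium decay time constant in seconds.
    amplitude : float
        dF/F added per event at event onset.
    noise_sd : float
        SD of additive Gaussian sensor noise (dF/F).
    ramp_slope : float
        Rate increase (events/s per hour) of ramping neurons in multi-hour
        sessions; their rate starts at ``rate_lo``.
    timeline : SessionTimeline
        Epoch structure of a single session.
    social_labels : tuple of str
        Epoch labels treated as the social (partner present) state; all
        other epochs count as isolated.
    fs : float
        Sampling rate in Hz.
    seed : int
        Master seed.
    """

    n_neurons: int = 200
    fractions: dict = field(default_factory=lambda: {"isolation": 0.2, "reunion": 0.15})
    rate_hi: float = 0.4
    rate_lo: float = 0.02
    kernel_tau: float = 1.5
    amplitude: float = 1.0
    noise_sd: float = 0.05
    ramp_slope: float = 0.05
    timeline: SessionTimeline = field(default_factory=default_timeline)
    social_labels: tuple = ("reunion",)
    fs: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 0:
            raise ConfigError(f"n_neurons must be >= 0, got {self.n_neurons}")
        bad = set(self.fractions) - set(CLASSES)
        if bad:
            raise ConfigError(f"unknown classes in fractions: {sorted(bad)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ConfigError("class fractions must be non-negative")
        if sum(self.fractions.values()) > 1 + 1e-12:
            raise ConfigError(
                f"class fractions sum to {sum(self.fractions.values()):g} > 1"
            )
        if not self.fs > 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if not self.kernel_tau > 0:
            raise ConfigError(f"kernel_tau must be positive, got {self.kernel_tau}")
        if self.rate_hi < 0 or self.rate_lo < 0:
            raise ConfigError("event rates must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for e in self.timeline:
            if not e.duration_s > 0:
                raise ConfigError(f"epoch {e.label!r} has non-positive duration")

    def class_labels(self) -> list[str]:
        """Deterministic per-neuron class assignment (exact fractions)."""
        labels = []
        for cls in ("isolation", "reunion", "ramping"):
            labels += [cls] * int(np.floor(self.fractions.get(cls, 0.0) * self.n_neurons))
        labels += ["untuned"] * (self.n_neurons - len(labels))
        return labels


def _neuron_rng(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(c) for c in counters])


def _kernel(tau: float, amplitude: float, fs: float) -> np.ndarray:
    n = max(int(np.ceil(10.0 * tau * fs)), 1)
    return amplitude * np.exp(-np.arange(n) / (tau * fs))


def _event_trace(rng, rates_per_sample, cfg: SynthConfig) -> np.ndarray:
    counts = rng.poisson(rates_per_sample / cfg.fs)
    trace = np.convolve(counts.astype(float), _kernel(cfg.kernel_tau, cfg.amplitude, cfg.fs))
    trace = trace[: rates_per_sample.size]
    if cfg.noise_sd > 0:
        trace = trace + rng.normal(0.0, cfg.noise_sd, size=trace.size)
    return trace


def _epoch_rate(cls: str, label: str, cfg: SynthConfig) -> float:
    social = label in cfg.social_labels
    if cls == "isolation":
        return cfg.rate_lo if social else cfg.rate_hi
    if cls == "reunion":
        return cfg.rate_hi if social else cfg.rate_lo
    # untuned and (within a single session) ramping neurons are constant
    return cfg.rate_hi


def generate_session(config: SynthConfig):
    """Simulate one isolation/reunion imaging session.

    Returns
    -------
    traces : TraceMatrix
    timeline : SessionTimeline
    truth : pandas.DataFrame
        One row per neuron: ``neuron_id``, ``true_class``, one
        ``rate_<label>`` column per epoch, and ``ramp_slope``.
    """
    cfg = config
    n_samples = int(round(cfg.timeline.end_s * cfg.fs))
    sample_t = np.arange(n_samples) / cfg.fs
    classes = cfg.class_labels()
    ids = [f"n{i:04d}" for i in range(cfg.n_neurons)]

    values = np.zeros((cfg.n_neurons, n_samples))
    truth_rows = []
    for i, cls in enumerate(classes):
        rates = np.zeros(n_samples)
        row = {"neuron_id": ids[i], "true_class": cls}
        for e in cfg.timeline:
            r = _epoch_rate(cls, e.label, cfg)
            rates[(sample_t >= e.start_s - 1e-9) & (sample_t < e.end_s - 1e-9)] = r
            row[f"rate_{e.label}"] = r
        row["ramp_slope"] = cfg.ramp_slope if cls == "ramping" else 0.0
        values[i] = _event_trace(_neuron_rng(cfg.seed, i), rates, cfg)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows) if truth_rows else pd.DataFrame(
        columns=["neuron_id", "true_class", "ramp_slope"]
    )
    return TraceMatrix(values, ids, cfg.fs), cfg.timeline, truth


def generate_multihour(config: SynthConfig, n_hours: int = 6, block_min: float = 15.0):
    """Simulate hourly imaging blocks across the first hours of isolation.

    One ``block_min``-minute block of pure isolation is recorded each hour
    with shared neuron identity. Ramping neurons start at ``rate_lo`` and
    gain ``ramp_slope`` events/s per hour; all other classes hold the rate
    they show in the isolated state.

    Returns
    -------
    blocks : list of TraceMatrix
        One per hour; ``t0`` encodes the block's start on the session clock.
    truth : pandas.DataFrame
        ``neuron_id``, ``true_class``, ``rate_h<h>`` per hour, ``ramp_slope``.
    """
    cfg = config
    if n_hours < 1:
        raise ConfigError(f"n_hours must be >= 1, got {n_hours}")
    if not block_min > 0:
        raise ConfigError(f"block_min must be positive, got {block_min}")
    n_samples = int(round(block_min * 60.0 * cfg.fs))
    classes = cfg.class_labels()
    ids = [f"n{i:04d}" for i in range(cfg.n_neurons)]

    truth = pd.DataFrame({"neuron_id": ids, "true_class": classes})
    truth["ramp_slope"] = [
        cfg.ramp_slope if c == "ramping" else 0.0 for c in classes
    ]
    blocks = []
    for h in range(n_hours):
        values = np.zeros((cfg.n_neurons, n_samples))
        col = np.zeros(cfg.n_neurons)
        for i, cls in enumerate(classes):
            if cls == "ramping":
                rate = cfg.rate_lo + cfg.ramp_slope * h
            elif cls == "reunion":
                rate = cfg.rate_lo
            else:  # isolation-tuned and untuned are active while alone
                rate = cfg.rate_hi
            col[i] = rate
            rates = np.full(n_samples, rate)
            values[i] = _event_trace(_neuron_rng(cfg.seed, h, i), rates, cfg)
        truth[f"rate_h{h}"] = col
        blocks.append(TraceMatrix(values, ids, cfg.fs, t0=h * 3600.0))
    return blocks, truth


def generate_photometry(
    event_times,
    artifact_amp: float = 0.5,
    seed: int = 0,
    *,
    session_s: float = 600.0,
    fs: float = 20.0,
    transient_amp: float = 2.0,
    transient_tau: float = 1.0,
    noise_sd: float = 0.1,
    artifact_tau: float = 0.5,
    return_artifact: bool = False,
):
    """Simulate a two-channel photometry session.

    The signal channel carries exponential transients of amplitude
    ``transient_amp`` at the given event times plus a shared motion
    artifact and white noise; the control channel carries the identical
    artifact realisation plus independent noise. The artifact is unit-SD
    Gaussian-smoothed noise (smoothing scale ``artifact_tau`` s) scaled by
    ``artifact_amp``. With ``return_artifact=True`` the injected artifact
    waveform is returned alongside the session as ground truth for
    correction tests.
    """
    events = sorted(float(t) for t in np.atleast_1d(np.asarray(event_times, float)))
    bad = [t for t in events if t < 0 or t >= session_s]
    if bad:
        raise ConfigError(f"event times outside session [0, {session_s}): {bad}")
    if not session_s > 0 or not fs > 0:
        raise ConfigError("session_s and fs must be positive")
    n = int(round(session_s * fs))
    rng_art = np.random.default_rng([int(seed), 0])
    rng_sig = np.random.default_rng([int(seed), 1])
    rng_ctl = np.random.default_rng([int(seed), 2])

    artifact = np.zeros(n)
    if artifact_amp != 0:
        raw = gaussian_filter1d(rng_art.standard_normal(n), sigma=artifact_tau * fs,
                                mode="reflect")
        sd = raw.std()
        if sd > 0:
            artifact = artifact_amp * raw / sd

    transients = np.zeros(n)
    if transient_amp != 0 and events:
        impulses = np.zeros(n)
        for t in events:
            impulses[int(np.floor(t * fs + 1e-9))] += transient_amp
        kern = np.exp(-np.arange(max(int(np.ceil(10 * transient_tau * fs)), 1))
                      / (transient_tau * fs))
        transients = np.convolve(impulses, kern)[:n]

    signal = transients + artifact + rng_sig.normal(0.0, noise_sd, n)
    control = artifact + rng_ctl.normal(0.0, noise_sd, n)
    session = PhotometrySession(signal, control, fs, event_times_s=events)
    return (session, artifact) if return_artifact else session


def generate_ethogram(
    transition_matrix,
    mean_bout_s: float,
    session_s: float,
    seed: int = 0,
    *,
    mean_gap_s: float = 1.0,
    modules=MODULES,
    actor: str = "isolated",
) -> BehaviorAnnotation:
    """Simulate a Markov-chain bout sequence for one actor.

    Module identities follow a first-order Markov chain with the given
    row-stochastic transition matrix; bout durations and inter-bout gaps
    are exponential with the given means. Generation stops at
    ``session_s`` (the final bout is truncated to the session bound).
    """
    P = np.asarray(transition_matrix, dtype=float)
    modules = list(modules)
    k = len(modules)
    if P.shape != (k, k):
        raise ConfigError(
            f"transition matrix shape {P.shape} does not match {k} modules"
        )
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ConfigError("transition matrix rows must be non-negative and sum to 1")
    if mean_bout_s <= 0 or mean_gap_s < 0:
        raise ConfigError("mean_bout_s must be > 0 and mean_gap_s >= 0")
    if session_s < 0:
        raise ConfigError(f"session_s must be >= 0, got {session_s}")

    rng = np.random.default_rng(int(seed))
    rows = []
    t = float(rng.exponential(mean_gap_s))
    state = int(rng.integers(k))
    while t < session_s:
        dur = rng.exponential(mean_bout_s)
        end = min(t + dur, session_s)
        if end > t:
            rows.append((actor, modules[state], t, end))
        t = end + rng.exponential(mean_gap_s) if mean_gap_s > 0 else end + 1e-6
        state = int(rng.choice(k, p=P[state]))
    return BehaviorAnnotation(rows)
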