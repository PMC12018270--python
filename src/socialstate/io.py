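"""On-disk formats and core session containers.

All times are in seconds, 0-based within a session. Intervals are half-open
``[start, end)``; sample ``i`` of a trace sampled at ``fs`` Hz covers
``[t0 + i/fs, t0 + (i+1)/fs)``. This convention removes double-counting at
epoch and bin boundaries throughout the package.

Formats
-------
* Trace matrices: CSV, UTF-8, ``.`` decimal. First column ``neuron_id``,
  remaining column headers are sample times in seconds.
* Session timelines: TSV with columns ``label``, ``start_s``, ``end_s``.
* Behaviour annotations: TSV with columns ``actor``, ``module``,
  ``start_s``, ``end_s``.
* Photometry: TSV with columns ``time_s``, ``signal``, ``control``;
  event times go to a sidecar ``<name>.events.tsv``.

Every reader is a total validator: a file it accepts maps to an object that
satisfies the type's invariants, and malformed input raises
:class:`ValidationError` naming the offending row or field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ConfigError",
    "Epoch",
    "SessionTimeline",
    "TraceMatrix",
    "BehaviorAnnotation",
    "PhotometrySession",
    "read_traces",
    "write_traces",
    "read_timeline",
    "write_timeline",
    "read_annotations",
    "write_annotations",
    "read_photometry",
    "write_photometry",
]

ACTORS = ("isolated", "partner")


class ValidationError(ValueError):
    """An on-disk file or in-memory object violates a type invariant."""


class ConfigError(ValueError):
    """A configuration value is missing, malformed or inconsistent."""


# ---------------------------------------------------------------------------
# session timeline


@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class SessionTimeline:
    """Ordered, non-overlapping labelled epochs of one session.

    Epochs are half-open intervals in seconds, e.g. a 5-min baseline
    (pre-reunion isolation) followed by a 5-min reunion and a 5-min
    re-isolation after partner removal.
    """

    def __init__(self, epochs):
        eps = [e if isinstance(e, Epoch) else Epoch(*e) for e in epochs]
        for e in eps:
            if not e.end_s > e.start_s:
                raise ValidationError(
                    f"epoch {e.label!r}: end ({e.end_s}) must exceed start ({e.start_s})"
                )
        eps = sorted(eps, key=lambda e: e.start_s)
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"epochs {a.label!r} [{a.start_s}, {a.end_s}) and "
                    f"{b.label!r} [{b.start_s}, {b.end_s}) overlap"
                )
        self.epochs: list[Epoch] = eps

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self):
        return len(self.epochs)

    def __eq__(self, other):
        return isinstance(other, SessionTimeline) and self.epochs == other.epochs

    def __repr__(self):
        inner = ", ".join(f"{e.label}[{e.start_s:g},{e.end_s:g})" for e in self.epochs)
        return f"SessionTimeline({inner})"

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]

    @property
    def end_s(self) -> float:
        return max(e.end_s for e in self.epochs)

    def epoch(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(f"unknown epoch label {label!r}; have {self.labels}")

    def label_at(self, t: float) -> str | None:
        """Label of the epoch covering time ``t``, or None between epochs."""
        for e in self.epochs:
            if e.start_s <= t < e.end_s:
                return e.label
        return None


def read_timeline(path) -> SessionTimeline:
    df = _read_table(path, sep="\t", required=("label", "start_s", "end_s"))
    return SessionTimeline(
        [Epoch(str(r.label), float(r.start_s), float(r.end_s)) for r in df.itertuples()]
    )


def write_timeline(timeline: SessionTimeline, path) -> None:
    pd.DataFrame(
        [(e.label, e.start_s, e.end_s) for e in timeline],
        columns=["label", "start_s", "end_s"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trace matrix


class TraceMatrix:
    """Neurons x samples activity matrix at a fixed sampling rate.

    Values are dF/F or deconvolved activity in arbitrary units; rows are
    neurons identified by ``neuron_ids``, columns are samples at ``fs`` Hz
    starting at ``t0`` seconds.
    """

    def __init__(self, values, neuron_ids, fs: float, t0: float = 0.0):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("trace values must be a 2-D neurons x samples array")
        if not np.all(np.isfinite(values)):
            raise ValidationError("trace values contain missing or non-finite entries")
        if not fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {fs}")
        ids = [str(i) for i in neuron_ids]
        if len(ids) != values.shape[0]:
            raise ValidationError(
                f"{len(ids)} neuron IDs for {values.shape[0]} trace rows"
            )
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dupes:
            raise ValidationError(f"duplicate neuron IDs: {dupes}")
        self.values = values
        self.neuron_ids = ids
        self.fs = float(fs)
        self.t0 = float(t0)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def row(self, neuron_id: str) -> np.ndarray:
        try:
            idx = self.neuron_ids.index(str(neuron_id))
        except ValueError:
            raise KeyError(f"unknown neuron ID {neuron_id!r}") from None
        return self.values[idx]

    def select(self, neuron_ids) -> "TraceMatrix":
        ids = [str(i) for i in neuron_ids]
        index = {nid: i for i, nid in enumerate(self.neuron_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"unknown neuron IDs: {missing}")
        rows = [index[i] for i in ids]
        return TraceMatrix(self.values[rows], ids, self.fs, self.t0)

    def epoch_samples(self, start_s: float, end_s: float) -> slice:
        """Slice of sample indices whose time lies in ``[start_s, end_s)``."""
        eps = 1e-9
        i0 = int(np.ceil((start_s - self.t0) * self.fs - eps))
        i1 = int(np.ceil((end_s - self.t0) * self.fs - eps))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), self.n_samples)
        return slice(i0, i1)


def write_traces(traces: TraceMatrix, path) -> None:
    cols = [f"{t:.10g}" for t in traces.times]
    df = pd.DataFrame(traces.values, index=pd.Index(traces.neuron_ids, name="neuron_id"),
                      columns=cols)
    df.to_csv(path, float_format="%.10g")


def read_traces(path) -> TraceMatrix:
    df = _read_table(path, sep=",", required=("neuron_id",))
    ids = df["neuron_id"].astype(str).tolist()
    dupes = sorted(set(i for i in ids if ids.count(i) > 1))
    if dupes:
        raise ValidationError(f"{path}: duplicate neuron IDs {dupes}")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric time header ({exc})") from None
    body = df.iloc[:, 1:]
    try:
        values = body.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, row in enumerate(body.itertuples(index=False)):
            for v in row:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path}: non-numeric value {v!r} in row {i + 2} "
                        f"(neuron {ids[i]!r})"
                    ) from None
        raise
    if times.size == 0:
        return TraceMatrix(values.reshape(len(ids), 0), ids, fs=1.0, t0=0.0)
    if times.size == 1:
        return TraceMatrix(values, ids, fs=1.0, t0=times[0])
    steps = np.diff(times)
    if steps.min() <= 0 or not np.allclose(steps, steps.mean(), rtol=1e-4, atol=1e-9):
        raise ValidationError(f"{path}: time header is not uniformly spaced")
    return TraceMatrix(values, ids, fs=1.0 / steps.mean(), t0=times[0])


# ---------------------------------------------------------------------------
# behaviour annotation


class BehaviorAnnotation:
    """Scored behavioural bouts: (actor, module, start_s, end_s) rows.

    Actors are the previously isolated mouse and its reintroduced partner;
    modules are scored social events (approach, sniff, crawl-under,
    head-to-head, allogroom). Bouts of one actor must not overlap.
    """

    def __init__(self, bouts):
        if isinstance(bouts, pd.DataFrame):
            df = bouts.copy()
        else:
            df = pd.DataFrame(bouts, columns=["actor", "module", "start_s", "end_s"])
        if df.empty:
            df = pd.DataFrame(columns=["actor", "module", "start_s", "end_s"])
        df["actor"] = df.get("actor", pd.Series(dtype=str)).astype(str)
        df["module"] = df.get("module", pd.Series(dtype=str)).astype(str)
        df["start_s"] = df.get("start_s", pd.Series(dtype=float)).astype(float)
        df["end_s"] = df.get("end_s", pd.Series(dtype=float)).astype(float)
        bad = df.index[df["end_s"] <= df["start_s"]].tolist()
        if bad:
            raise ValidationError(f"bout end <= start in row(s) {bad}")
        for actor, grp in df.groupby("actor", sort=False):
            g = grp.sort_values("start_s")
            overlap = g["start_s"].to_numpy()[1:] < g["end_s"].to_numpy()[:-1]
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                a, b = g.index[i], g.index[i + 1]
                raise ValidationError(
                    f"overlapping bouts for actor {actor!r}: rows {a} and {b}"
                )
        self.bouts = df.sort_values(["start_s", "end_s"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self):
        return len(self.bouts)

    @property
    def modules(self) -> list[str]:
        return sorted(self.bouts["module"].unique())

    def for_actor(self, actor: str) -> pd.DataFrame:
        if actor in ("both", "all", None):
            return self.bouts
        return self.bouts[self.bouts["actor"] == actor].reset_index(drop=True)


def read_annotations(path) -> BehaviorAnnotation:
    df = _read_table(path, sep="\t", required=("actor", "module", "start_s", "end_s"))
    return BehaviorAnnotation(df)


def write_annotations(ann: BehaviorAnnotation, path) -> None:
    ann.bouts.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# photometry


class PhotometrySession:
    """Two-channel photometry recording with event times.

    ``signal`` carries the sensor fluorescence, ``control`` a
    motion/haemodynamic control fluorophore recorded simultaneously; both
    share motion artifacts, which downstream correction removes by
    subtraction.
    """

    def __init__(self, signal, control, fs: float, event_times_s=()):
        signal = np.asarray(signal, dtype=float)
        control = np.asarray(control, dtype=float)
        if signal.ndim != 1 or control.ndim != 1:
            raise ValidationError("photometry channels must be 1-D series")
        if signal.shape != control.shape:
            raise ValidationError(
                f"channel length mismatch: signal {signal.size}, control {control.size}"
            )
        if not fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {fs}")
        self.signal = signal
        self.control = control
        self.fs = float(fs)
        self.event_times_s = [float(t) for t in event_times_s]

    @property
    def n_samples(self) -> int:
        return self.signal.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _events_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".events.tsv")


def write_photometry(session: PhotometrySession, path) -> None:
    pd.DataFrame(
        {"time_s": session.times, "signal": session.signal, "control": session.control}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame({"event_time_s": session.event_times_s}).to_csv(
        _events_path(path), sep="\t", index=False, float_format="%.10g"
    )


def read_photometry(path) -> PhotometrySession:
    df = _read_table(path, sep="\t", required=("time_s", "signal", "control"))
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError(f"{path}: need at least 2 samples to infer rate")
    steps = np.diff(t)
    if steps.min() <= 0 or not np.allclose(steps, steps.mean(), rtol=1e-4, atol=1e-9):
        raise ValidationError(f"{path}: time column is not uniformly spaced")
    events: list[float] = []
    ep = _events_path(path)
    if ep.exists():
        events = pd.read_csv(ep, sep="\t")["event_time_s"].astype(float).tolist()
    return PhotometrySession(
        df["signal"].to_numpy(float),
        df["control"].to_numpy(float),
        fs=1.0 / steps.mean(),
        event_times_s=events,
    )


# ---------------------------------------------------------------------------
# helpers


def _read_table(path, sep: str, required) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed table ({exc})") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    import yaml

    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top-level configuration must be a mapping")
    return cfg
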