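"""End-to-end pipeline: simulate/load -> classify -> metrics -> state.

Driven by a plain-dict configuration (YAML/JSON on disk) with either a
``synthesis`` block (generator parameters) or an ``inputs`` block naming
trace/timeline files. Results are returned as a bundle and, when
``out_dir`` is set, written as TSV/JSON together with a log recording the
seed, the package version and a hash of the configuration, so a run is
reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    ConfigError,
    SessionTimeline,
    load_config,
    read_timeline,
    read_traces,
    write_timeline,
    write_traces,
)
from .metrics import modulation_profile
from .simulate import SynthConfig, generate_session
from .state import (
    PopulationTrajectory,
    bin_population,
    decode_states,
    return_latency,
    state_labels,
)
from .tuning import TuningClassifier

STAGES = ("simulate", "classify", "metrics", "state")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_inputs(cfg: dict):
    if "synthesis" in cfg:
        synth = dict(cfg["synthesis"])
        if "timeline" in synth:
            synth["timeline"] = SessionTimeline(synth["timeline"])
        synth.setdefault("seed", cfg.get("seed", 0))
        sc = SynthConfig(**synth)
        traces, timeline, truth = generate_session(sc)
        return traces, timeline, truth
    if "inputs" not in cfg:
        raise ConfigError("config needs a 'synthesis' or an 'inputs' block")
    inputs = cfg["inputs"]
    for key in ("traces", "timeline"):
        if key not in inputs:
            raise ConfigError(f"missing required input field 'inputs.{key}'")
    return read_traces(inputs["traces"]), read_timeline(inputs["timeline"]), None


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured stages and return a results bundle.

    ``config`` is a dict or a path to a YAML/JSON file. Recognised keys:
    ``seed``, ``stages``, ``synthesis`` | ``inputs``, ``baseline_label``,
    ``epoch_label``, ``classify`` (TuningClassifier kwargs), ``state``
    (bin/subsample/decoder settings), ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(config)
    out_dir = out_dir or cfg.get("out_dir")
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage name(s): {unknown}; valid: {list(STAGES)}")
    baseline_label = cfg.get("baseline_label", "baseline")
    epoch_label = cfg.get("epoch_label", "reunion")

    traces, timeline, truth = _load_inputs(cfg)
    results: dict = {
        "traces": traces,
        "timeline": timeline,
        "ground_truth": truth,
        "log": {
            "seed": seed,
            "config_hash": _config_hash(cfg),
            "version": __version__,
            "stages": stages,
            "n_neurons": traces.n_neurons,
        },
    }

    if "classify" in stages:
        ckw = dict(cfg.get("classify", {}))
        ckw.setdefault("random_state", seed)
        clf = TuningClassifier(baseline_label=baseline_label,
                               epoch_label=epoch_label, **ckw)
        clf.fit(traces, timeline)
        results["tuning"] = clf.table_
        results["log"]["label_counts"] = clf.counts_

    if "metrics" in stages:
        results["modulation"] = modulation_profile(
            traces, timeline, baseline_label, epoch_label,
            bin_s=float(cfg.get("metrics", {}).get("bin_s", 1.0)),
        )

    if "state" in stages:
        skw = dict(cfg.get("state", {}))
        tuned = results.get("tuning")
        if tuned is not None:
            ids = tuned.loc[tuned["label"] != "none", "neuron_id"].tolist()
        else:
            ids = traces.neuron_ids
        if len(ids) < 4:  # too few tuned neurons for a subspace: use all
            ids = traces.neuron_ids
            results["log"]["state_neurons"] = "all (too few tuned)"
        else:
            results["log"]["state_neurons"] = f"{len(ids)} tuned"
        pop = PopulationTrajectory(bin_s=float(skw.get("bin_traj", 5.0)))
        pop.fit(traces.select(ids))
        dist, dtimes = pop.distance(timeline, baseline_label,
                                    bin_s=float(skw.get("bin_dist", 1.0)))
        results["trajectory"] = pop.trajectory_
        results["distance"] = pd.DataFrame({"time_s": dtimes, "distance": dist})
        # return-to-baseline latency after the last social epoch, if any
        social = [e for e in timeline if e.label == epoch_label]
        if social and social[-1].end_s < timeline.end_s:
            est = return_latency(dist, dtimes, timeline, baseline_label,
                                 removal_time=social[-1].end_s)
            results["return"] = est
        X, btimes = bin_population(pop.z_, float(skw.get("bin_dist", 1.0)))
        labels = state_labels(timeline, btimes, float(skw.get("bin_dist", 1.0)))
        keep = labels != ""
        if np.unique(labels[keep]).size >= 2:
            accs = decode_states(
                X[keep], labels[keep],
                train_frac=float(skw.get("train_frac", 0.8)),
                n_repeats=int(skw.get("n_repeats", 20)), seed=seed,
            )
            results["decoding_accuracy"] = accs

    if out_dir is not None:
        _write_bundle(results, Path(out_dir))
    return results


def _write_bundle(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_traces(results["traces"], out_dir / "traces.csv")
    write_timeline(results["timeline"], out_dir / "timeline.tsv")
    if results.get("ground_truth") is not None:
        results["ground_truth"].to_csv(out_dir / "ground_truth.tsv", sep="\t",
                                       index=False)
    if "tuning" in results:
        results["tuning"].to_csv(out_dir / "tuning.tsv", sep="\t", index=False)
    if "modulation" in results:
        results["modulation"].to_csv(out_dir / "modulation.tsv", sep="\t",
                                     index=False)
    if "distance" in results:
        results["distance"].to_csv(out_dir / "distance.tsv", sep="\t", index=False)
    if "trajectory" in results:
        traj = results["trajectory"]
        pd.DataFrame(
            traj.scores[:, : max(traj.k95, 3)],
            columns=[f"pc{i + 1}" for i in range(max(traj.k95, 3))],
        ).assign(time_s=traj.bin_times).to_csv(
            out_dir / "trajectory_scores.tsv", sep="\t", index=False
        )
    summary: dict = dict(results["log"])
    if "return" in results:
        summary["return"] = asdict(results["return"])
    if "decoding_accuracy" in results:
        summary["decoding_accuracy_mean"] = float(
            np.mean(results["decoding_accuracy"])
        )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
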