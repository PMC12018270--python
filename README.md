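# socialstate

Analysis pipeline for studying **social homeostasis** in neural and
behavioural data: how a neural population (e.g. in the medial preoptic
nucleus of the hypothalamus) tracks social isolation and reunion, and how
the behavioural rebound after isolation — the burst of social interaction
that satiates over a reunion — is quantified.

It is written for systems-neuroscience users who already have extracted
calcium traces (dF/F or deconvolved activity from a miniscope pipeline),
scored behavioural bouts, tracked positions and/or two-channel fibre
photometry, and want a tested, reproducible implementation of the
downstream statistics, together with a synthetic-data generator with known
ground truth for calibrating every stage.

## What it computes

**Single-neuron tuning (ROC/AUC with a permutation null).** For each
neuron, activity is averaged in 1-s bins and the reunion-epoch bin
distribution is compared with the baseline (isolation) distribution via
the area under the ROC curve. With ties credited half a win, the
threshold-sweep AUC equals the rank-sum statistic

```
AUC = (#[epoch > baseline] + 0.5 · #[epoch = baseline]) / (n · m)
```

A neuron is *reunion-tuned* when AUC > 0.7 **and** exceeds the 95th
percentile of 1,000 shuffled AUCs (bin values re-assigned across the two
epoch labels), and *isolation-tuned* when AUC < 0.3 and falls below the
symmetric 5th percentile. Activation strengths are AUC and 1 − AUC.
Multi-hour recordings label a neuron tuned if it meets the criterion in at
least one hourly block, and footprints are matched across sessions at
an intersection-over-union overlap above 70%.

**Activity dynamics.** Total and longest-contiguous (persistent) durations
of significant modulation (bins above baseline mean + 2 SD, or below 30%
of the baseline mean); ramp-up/-down detection across hours of isolation
by Pearson correlation of 5-min-binned activity against time (p < 0.05);
per-animal averaging of per-neuron values.

**Population state.** Z-scored activity of the tuned neurons is projected
onto principal components (time bins as observations); the state's
Euclidean distance to the mean baseline score, in the fewest components
explaining 95% of variance, tracks the isolation/reunion trajectory, with
a mean ± SD band from 100 random 50% neuron subsamples. The latency to
return to baseline after partner removal is the first sustained crossing
below the upper bound of the baseline distance's 95% interval. Linear
support-vector classifiers on 80/20 stratified splits decode the social
state from single-bin population vectors.

**Photometry.** Control-channel subtraction for motion correction,
z-scoring against a 30-s pre-event baseline, per-1-s-bin significance
against the baseline 95% interval, and event-aligned averaging across
animals.

**Behaviour.** Interaction totals, bout counts/durations, inter-bout
latencies, 2-min satiation bins, module-transition probability matrices,
frame-averaged social distance, tunnel/chamber preference indices and the
USV–interaction correlation.

**Synthetic data.** Poisson event trains with state-dependent rates
convolved with an exponential calcium kernel (plus noise), multi-hour
ramping populations, two-channel photometry with a shared motion artifact,
and Markov-chain ethograms — all deterministic given a seed and paired
with ground truth.

## Worked example

```python
from socialstate import (SynthConfig, generate_session, TuningParams,
                         classify_population, zscore_traces, pca_trajectory,
                         distance_to_baseline, return_latency)

cfg = SynthConfig(n_neurons=100,
                  fractions={"isolation": 0.2, "reunion": 0.15}, seed=42)
traces, timeline, truth = generate_session(cfg)

table = classify_population(traces, timeline, TuningParams(seed=42))
print(table["label"].value_counts().to_dict())
# {'none': 65, 'isolation': 20, 'reunion': 15}

print(table.head(3).round(3).to_string(index=False))
# neuron_id   auc  null_low  null_high     label  reunion_strength  isolation_strength
#     n0000 0.051     0.462      0.539 isolation             0.051               0.949
#     n0001 0.107     0.463      0.537 isolation             0.107               0.893
#     n0002 0.059     0.463      0.539 isolation             0.059               0.941

ids = table.loc[table.label != "none", "neuron_id"].tolist()
z, _ = zscore_traces(traces.select(ids))
traj = pca_trajectory(z, bin_s=5.0)
d, t = distance_to_baseline(z, traj, timeline, "baseline")
est = return_latency(d, t, timeline, "baseline", removal_time=600.0)
print(est.latency_s, round(est.threshold, 2))
# 1.0 5.48
```

The 100-neuron session contains 20 isolation-tuned and 15 reunion-tuned
neurons by construction; the classifier recovers all 35 (AUC of 0.051
means the neuron is far more active during baseline isolation than during
reunion, hence isolation strength 0.949). The population state sits ~5.5
distance units from baseline during reunion and returns below the baseline
bound 1 s after partner removal — the generator switches rates
instantaneously, so a near-immediate return is expected.

The same stages are available from the shell:

```
socialstate simulate --n-neurons 200 --seed 1 --out-dir run1
socialstate classify --traces run1/traces.csv --timeline run1/timeline.tsv \
    --seed 1 --out run1/tuning.tsv
socialstate pipeline --config config.yaml --out-dir run2
```

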