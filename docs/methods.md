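# Methods notes

This note documents the models, conventions and numerical choices behind
`socialstate`, the assumptions of the synthetic-data generator, and the
limitations of both.

## Time conventions

All times are seconds, 0-based within a session. Intervals are half-open
`[start, end)`: sample `i` of a trace at `fs` Hz covers
`[t0 + i/fs, t0 + (i+1)/fs)`, and bin `j` of width `b` within an epoch
starting at `s` covers `[s + j·b, s + (j+1)·b)`. A trailing partial bin is
always dropped. This removes double counting at every epoch and bin
boundary, at the cost of discarding at most one bin of data per epoch.

## Tuning classification

The per-neuron statistic is the ROC AUC between the baseline-epoch and
comparison-epoch distributions of 1-s bin means, computed in rank-sum form
with ties credited 0.5 — identical to the full threshold-sweep ROC
integral, and checked against an exhaustive pairwise oracle and against
scikit-learn's ROC implementation in the test suite. AUC values enter the
label rule symmetrically: reunion-tuned needs AUC > 0.7 *and* above the
95th percentile of the shuffle null; isolation-tuned needs AUC < 0.3 and
below the 5th percentile. The symmetric lower-percentile rule for
inhibited neurons is a design choice (the inhibited-side criterion admits
more than one reading); with the dual criterion the AUC threshold, not the
null percentile, is binding in practice, so the choice has little effect.

The null is built by pooling all bin values and re-assigning them to the
two epochs with sizes preserved. Because ranks are invariant under
permutation, the pooled data are ranked once and shuffles permute the rank
vector, which makes 1,000 shuffles per neuron cheap (a 500-neuron,
1,000-shuffle run takes a few seconds). Within-epoch autocorrelation of
calcium signals is deliberately ignored by the shuffle, as in the field's
standard recipe; the practical consequence is that the null percentile
criterion alone would be anti-conservative for slow signals, which is
exactly why the hard AUC thresholds matter. Under the generator's null
(identical rates in both epochs) the fraction of neurons labelled tuned is
~0% against a 6% bound.

Percentiles use numpy's default linear interpolation between order
statistics. Unequal epoch lengths are allowed (the AUC is defined for
n ≠ m).

Reproducibility vs neuron order: each neuron's shuffle stream derives from
`(master_seed, crc32(neuron_id))`, so the classification of a neuron does
not depend on how the population is ordered on disk. The generator, by
contrast, derives per-neuron streams from the neuron *index* so that
enlarging a simulated population leaves the first neurons unchanged.

Multi-hour sessions classify each hourly block separately and call a
neuron tuned overall if any block meets the criterion; this matches the
"at least one hour" convention and makes the overall label monotone in
the number of blocks. Cross-session cell matching uses
intersection-over-union of pixel footprints with greedy one-to-one
assignment, accepting pairs strictly above the 0.7 threshold; "overlap"
relative to the union is the strictest of the plausible definitions and
therefore the least likely to produce false matches.

## Activity-duration metrics

Baseline mean and SD are taken over the raw samples of the baseline
epoch; the modulation thresholds (mean + 2 SD for activation, 30% of the
mean for inhibition) are applied to 1-s bin means, matching the ROC bin
convention. The relative (30%) inhibition rule requires a positive
baseline mean; traces failing that are reported as invalid rather than
silently skipped, because a near-zero dF/F baseline makes a relative
threshold meaningless. Persistent modulation is the longest run of
significant bins (exact run-length scan). Ramp detection correlates
5-min-binned activity against bin time (Pearson, two-sided p via the
t-transform); constant input is defined as r = 0, no flag. No
multiple-testing correction is applied across neurons, deliberately. With
α = 0.05 the false-flag rate among truly constant neurons is the nominal
5% (measured 5.1% over 60,000 simulated constant-rate neurons), so
downstream counts of "ramping" neurons should be interpreted net of that
base rate.

## Population state

Traces are z-scored per neuron over the whole session; zero-variance
neurons are excluded and reported. The PCA treats time bins (5 s for the
trajectory) as observations and neurons as features, and the test suite
pins the scores to an explicit covariance eigendecomposition up to
component sign. Distance to baseline projects 1-s bins onto the smallest
set of leading components with ≥ 95% cumulative explained variance and
takes the Euclidean distance to the mean baseline-epoch score.

Subsampling repeats the PCA + distance computation on random halves of
the population (z-scores are reused, not recomputed, so the band isolates
sampling variability of the *population*, not of the normalisation).
Because Euclidean distance grows as √n_neurons, each subsample's
distances are rescaled by √(n_full/n_sub); without this the
half-population band would sit √2 below the full-population series.

Return-to-baseline latency thresholds the distance series at the 97.5th
percentile of the baseline-epoch distances (the upper bound of the
percentile-form 95% interval — the CI construction is a package choice)
and requires 3 consecutive sub-threshold 1-s bins, so a single noisy bin
cannot count as a return; both the percentile and the run length are
configurable. A series that never returns yields NaN latency.

Decoding uses `sklearn.svm.SVC(kernel="linear", C=1)` on single 1-s-bin
population vectors with stratified random 80/20 splits; accuracy is the
held-out mean over repeats, each repeat on a seed spawned from the master
seed. On linearly separable synthetic states the accuracy is ≥ 0.99 and
on permuted labels it is 0.50 within ±0.05, which is the calibration the
package guarantees.

## Photometry

Motion correction is plain pointwise subtraction of the control channel;
a least-squares-scaled subtraction is available behind
`scale_control=True` for control channels with a different gain, off by
default. Z-scoring uses the mean/SD of the 30-s window ending at the
alignment event. Significance bars threshold 1-s bin means of z at the
97.5th percentile of the *raw* baseline-window samples; since a bin mean
of k samples has smaller spread than a single sample, this is
conservative for null data (measured null flag rate ≪ 2.5%), which is the
intended direction for a display of "enhanced activity". Event alignment
averages across animals with the population-SD standard error (zero for a
single animal by convention).

## Behavioural statistics

Interaction totals are plain sums of bout durations under the actor
filter (no union-merging; overlapping same-actor bouts are rejected by
the annotation type). Inter-bout latency excludes the interval before the
first bout. Satiation bins (2 min) apportion each bout to the bins it
overlaps, so binned totals partition the total exactly. Transition counts
are taken within each actor's time-ordered bout sequence, ignoring gaps,
and pooled across actors; rows never visited are flagged rather than
normalised. Preference indices are `target/(target+other)` for counts or
durations. The USV correlation is a plain Pearson r over sessions
(minimum 3, non-constant).

## Synthetic-data generator

Each neuron is a homogeneous Poisson event train whose rate switches
instantaneously at epoch boundaries, convolved with an exponential kernel
`exp(-t/τ)` with τ = 1.5 s and 1 dF/F per event (GCaMP6s-like scale;
single-event kinetics are a plausible placeholder, not fitted values),
plus white Gaussian noise (SD 0.05 dF/F by default). Default conditions:
200 neurons at 10 Hz over a 5-min baseline / 5-min reunion / 5-min
re-isolation session; tuned classes at 20% isolation / 15% reunion;
preferred-state rate 0.4 events/s against 0.02 events/s (a 20× effect);
class assignment is deterministic by index so requested fractions are
exact. Multi-hour sessions record a 15-min block each hour for 6 h;
ramping neurons start at the low rate and gain 0.05 events/s per hour.
Photometry sessions carry exponential transients (amplitude 2, τ = 1 s)
on a shared unit-SD smoothed-noise motion artifact with independent white
noise per channel at 20 Hz. Ethograms are first-order Markov chains over
five modules with exponential bout durations and gaps.

What the generator does *not* emulate — and hence what passing tests do
not establish about real recordings: sub-Poisson or bursty event
statistics, slow drifts and photobleaching, correlated population noise,
gradual (rather than instantaneous) state transitions, behavioural
state-activity coupling, crosstalk between behaviour scoring and neural
epochs, and non-exponential bout-duration distributions. Calibration
results (type-I rates, recovery sensitivities) transfer to real data only
insofar as these assumptions hold approximately.

## Problem sizes

The shipped calibration runs use 500 neurons × 1,000 shuffles for null
calibration, 200 neurons for recovery, 60,000 simulated neurons for the
one-off ramp type-I measurement quoted above, 500 replicate sessions for
photometry null calibration, and ~13,000-bout ethograms for transition
recovery; these sizes put Monte-Carlo noise well below the tolerances
asserted while keeping a full test run in well under a minute.

## Known limitations

* The ROC shuffle ignores bin autocorrelation (by design, matching the
  standard recipe); the null percentile bound alone should not be used
  without the hard AUC thresholds.
* `classify_multihour` assumes each block has its own baseline/comparison
  structure; it does not model slow drift in tuning across hours beyond
  the per-block labels.
* The PCA trajectory assumes stationarity of the neuron covariance within
  a session; pooling across animals must be done by the caller (z-scoring
  per neuron makes pooling scale-free but not noise-matched).
* Photometry correction assumes the artifact enters both channels with
  equal gain unless `scale_control=True`.
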