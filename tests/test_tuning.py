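from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialstate import (
    SessionTimeline,
    SynthConfig,
    TraceMatrix,
    TuningParams,
    ValidationError,
    bin_epoch_values,
    build_null,
    classify_multihour,
    classify_neuron,
    classify_population,
    compute_auc,
    ensemble_activity,
    generate_session,
    match_cells,
)


def auc_pairwise_oracle(baseline, epoch):
    """Exhaustive (wins + 0.5 ties) / (n m) reference statistic."""
    wins = ties = 0
    for b in baseline:
        for e in epoch:
            if e > b:
                wins += 1
            elif e == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(baseline) * len(epoch))


class TestComputeAuc:
    @pytest.mark.parametrize(
        "base, epoch, expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 0.5),  # full ties -> symmetry
            ([0, 0, 0], [1, 1, 1], 1.0),  # complete separation
            ([1, 2, 3], [2, 3, 4], 7 / 9),  # mixed wins and ties
        ],
    )
    def test_known_values(self, base, epoch, expected):
        assert compute_auc(base, epoch) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([], [1.0])

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n, m = rng.integers(1, 51, size=2)
            b = np.round(rng.normal(size=n), 1)  # rounding forces ties
            e = np.round(rng.normal(size=m), 1)
            assert compute_auc(b, e) == pytest.approx(
                auc_pairwise_oracle(b, e), abs=1e-12
            )

    def test_matches_sklearn_rank_auc(self, rng):
        # independent route: the ROC integral as computed by sklearn
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            n, m = rng.integers(2, 40, size=2)
            b = np.round(rng.normal(size=n), 1)
            e = np.round(rng.normal(size=m), 1)
            y = np.r_[np.zeros(n), np.ones(m)]
            assert compute_auc(b, e) == pytest.approx(
                roc_auc_score(y, np.r_[b, e]), abs=1e-12
            )

    @given(
        b=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
        e=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=200)
    def test_label_swap_antisymmetry(self, b, e):
        assert compute_auc(b, e) + compute_auc(e, b) == pytest.approx(1.0)

    @given(
        b=st.lists(st.integers(-5, 5), min_size=1, max_size=15),
        e=st.lists(st.integers(-5, 5), min_size=1, max_size=15),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_transform_invariance(self, b, e):
        f = lambda x: np.exp(np.asarray(x, float)) + np.asarray(x, float) ** 3
        assert compute_auc(b, e) == pytest.approx(compute_auc(f(b), f(e)))


class TestBinEpochValues:
    tl = SessionTimeline([("baseline", 0, 300), ("reunion", 300, 600)])

    def test_constant_trace(self):
        vals = np.full(6000, 3.5)
        bins = bin_epoch_values((vals, 10.0, 0.0), self.tl, "baseline", 1.0)
        assert bins.shape == (300,)
        assert np.all(bins == 3.5)

    def test_bin_count_and_partial_bin_dropped(self):
        tl = SessionTimeline([("short", 0, 7.5)])
        bins = bin_epoch_values((np.arange(75.0), 10.0, 0.0), tl, "short", 2.0)
        assert bins.shape == (3,)  # 7.5 s -> three complete 2-s bins

    def test_ramp_gives_increasing_bins(self):
        vals = np.linspace(0, 1, 6000)
        bins = bin_epoch_values((vals, 10.0, 0.0), self.tl, "reunion", 1.0)
        assert np.all(np.diff(bins) > 0)

    def test_unknown_epoch(self):
        with pytest.raises(KeyError):
            bin_epoch_values((np.zeros(6000), 10.0, 0.0), self.tl, "nope", 1.0)


class TestBuildNull:
    def test_constant_data_gives_half(self):
        null = build_null(np.ones(10), np.ones(12), n_shuffles=50, seed=0)
        assert np.all(null == 0.5)

    def test_deterministic(self):
        b, e = [0.1, 0.9], [0.4, 0.7]
        assert np.array_equal(
            build_null(b, e, 100, seed=7), build_null(b, e, 100, seed=7)
        )

    def test_matches_exact_enumeration_on_tiny_input(self):
        # 2 + 2 distinct values: the null support is the AUCs of all
        # C(4,2) = 6 assignments, each equally likely
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        exact = []
        for idx in combinations(range(4), 2):
            base = vals[list(idx)]
            epoch = vals[[i for i in range(4) if i not in idx]]
            exact.append(compute_auc(base, epoch))
        exact_support, exact_freq = np.unique(exact, return_counts=True)
        null = build_null(vals[:2], vals[2:], n_shuffles=6000, seed=3)
        support, counts = np.unique(null, return_counts=True)
        assert np.allclose(support, exact_support)
        np.testing.assert_allclose(
            counts / null.size, exact_freq / 6, atol=0.03
        )


class TestClassifyNeuron:
    def test_dual_criterion(self):
        null = np.linspace(0.38, 0.62, 1001)  # 95th pct = 0.608
        assert classify_neuron(0.75, null) == "reunion"
        assert classify_neuron(0.50, null) == "none"
        assert classify_neuron(0.25, null) == "isolation"
        # AUC threshold met but null criterion not
        wide_null = np.linspace(0.2, 0.8, 1001)  # 95th pct = 0.77
        assert classify_neuron(0.72, wide_null) == "none"

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TuningParams(auc_hi=0.4)
        with pytest.raises(ValueError):
            TuningParams(n_shuffles=0)


class TestClassifyPopulation:
    def test_recovers_ground_truth_strong_effect(self, strong_session):
        _, traces, timeline, truth = strong_session
        table = classify_population(
            traces, timeline, TuningParams(n_shuffles=200, seed=1)
        )
        merged = table.merge(truth, on="neuron_id")
        tuned = merged[merged.true_class.isin(["isolation", "reunion"])]
        assert (tuned.label == tuned.true_class).mean() >= 0.9
        untuned = merged[merged.true_class == "untuned"]
        assert (untuned.label == "none").mean() >= 0.95

    def test_strengths_complementary(self, strong_session):
        _, traces, timeline, _ = strong_session
        table = classify_population(
            traces, timeline, TuningParams(n_shuffles=20, seed=1)
        )
        np.testing.assert_allclose(
            table.reunion_strength + table.isolation_strength, 1.0
        )
        assert table.auc.between(0, 1).all()

    def test_permutation_equivariant_in_neuron_order(self):
        cfg = SynthConfig(n_neurons=12, seed=21)
        traces, timeline, _ = generate_session(cfg)
        perm = np.random.default_rng(0).permutation(12)
        shuffled = TraceMatrix(
            traces.values[perm], [traces.neuron_ids[i] for i in perm],
            traces.fs, traces.t0,
        )
        p = TuningParams(n_shuffles=100, seed=4)
        a = classify_population(traces, timeline, p).set_index("neuron_id")
        b = classify_population(shuffled, timeline, p).set_index("neuron_id")
        assert a.loc[b.index].label.tolist() == b.label.tolist()


class TestClassifyMultihour:
    def _blocks(self):
        untuned = SynthConfig(n_neurons=10, fractions={}, seed=1)
        tuned = SynthConfig(n_neurons=10, fractions={"isolation": 0.3}, seed=2)
        b0, tl, _ = generate_session(untuned)
        b1, _, _ = generate_session(SynthConfig(n_neurons=10, fractions={}, seed=3))
        b2, _, truth = generate_session(tuned)
        return [b0, b1, b2], tl, truth

    def test_tuned_in_one_block_is_tuned_overall(self):
        blocks, tl, truth = self._blocks()
        out = classify_multihour(blocks, tl, TuningParams(n_shuffles=100, seed=5))
        iso = truth.loc[truth.true_class == "isolation", "neuron_id"]
        sub = out.set_index("neuron_id").loc[iso]
        assert (sub.label_block2 == "isolation").all()
        assert (sub.label == "isolation").all()

    def test_never_significant_is_none(self):
        blocks, tl, truth = self._blocks()
        out = classify_multihour(blocks, tl, TuningParams(n_shuffles=100, seed=5))
        never = out[[c for c in out if c.startswith("label_block")]].eq("none").all(axis=1)
        assert (out.loc[never, "label"] == "none").all()

    def test_identical_blocks_identical_labels(self):
        blocks, tl, _ = self._blocks()
        out = classify_multihour([blocks[2], blocks[2]], tl,
                                 TuningParams(n_shuffles=100, seed=5))
        assert out.label_block0.tolist() == out.label_block1.tolist()

    def test_mismatched_ids_rejected(self):
        blocks, tl, _ = self._blocks()
        other = TraceMatrix(blocks[0].values, [f"x{i}" for i in range(10)],
                            blocks[0].fs)
        with pytest.raises(ValidationError, match="IDs differ"):
            classify_multihour([blocks[0], other], tl)


class TestMatchCells:
    def test_identity_and_disjoint(self):
        a = [{(0, 0), (0, 1), (1, 0)}]
        b_same = [{(0, 0), (0, 1), (1, 0)}]
        b_far = [{(9, 9), (9, 8)}]
        assert match_cells(a, b_same) == [(0, 0, 1.0)]
        assert match_cells(a, b_far) == []

    def test_overlap_threshold(self):
        base = {(0, i) for i in range(6)}
        a = [base | {(1, 0)}]  # 7 px
        b = [base | {(2, 0)}]  # 7 px, intersection 6, union 8 -> 0.75
        assert match_cells(a, b, threshold=0.7) == [(0, 0, 0.75)]
        assert match_cells(a, b, threshold=0.75) == []  # strict inequality

    def test_greedy_one_to_one(self):
        a = [{(0, 0), (0, 1)}, {(0, 0), (0, 1), (0, 2)}]
        b = [{(0, 0), (0, 1)}]
        matches = match_cells(a, b, threshold=0.5)
        assert matches == [(0, 0, 1.0)]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            match_cells([set()], [{(0, 0)}])


class TestEnsembleActivity:
    def test_single_neuron_equals_epoch_mean_zscore(self, strong_session):
        _, traces, timeline, _ = strong_session
        nid = traces.neuron_ids[0]
        out = ensemble_activity(traces, [nid], timeline, "reunion")
        v = traces.row(nid)
        z = (v - v.mean()) / v.std()
        ep = timeline.epoch("reunion")
        sl = traces.epoch_samples(ep.start_s, ep.end_s)
        assert out[nid] == pytest.approx(z[sl].mean())

    def test_isolation_ensemble_suppressed_during_reunion(self, strong_session):
        _, traces, timeline, truth = strong_session
        iso = truth.loc[truth.true_class == "isolation", "neuron_id"].tolist()
        reun = ensemble_activity(traces, iso, timeline, "reunion")
        base = ensemble_activity(traces, iso, timeline, "baseline")
        assert ((reun < base).mean()) >= 0.9

    def test_unknown_member(self, strong_session):
        _, traces, timeline, _ = strong_session
        with pytest.raises(KeyError):
            ensemble_activity(traces, ["ghost"], timeline, "reunion")
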