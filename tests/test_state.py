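import numpy as np
import pytest

from socialstate import (
    SessionTimeline,
    StateDecoder,
    TraceMatrix,
    ValidationError,
    bin_population,
    decode_states,
    distance_to_baseline,
    pca_trajectory,
    return_latency,
    state_labels,
    subsample_distance,
    zscore_traces,
)

TL = SessionTimeline([("baseline", 0, 300), ("reunion", 300, 600),
                      ("reisolation", 600, 900)])


def make_z(values, fs=1.0):
    ids = [f"n{i}" for i in range(values.shape[0])]
    z, _ = zscore_traces(TraceMatrix(values, ids, fs))
    return z


def pca_eig_oracle(X):
    """Scores/variances from an explicit covariance eigendecomposition."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return Xc @ V[:, order], w[order]


class TestZscore:
    def test_rows_standardised(self, rng):
        z, excluded = zscore_traces(
            TraceMatrix(rng.normal(2, 3, size=(6, 500)),
                        [f"n{i}" for i in range(6)], 10.0)
        )
        assert excluded == []
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1), 1, atol=1e-12)

    def test_constant_neuron_reported(self, rng):
        vals = rng.normal(size=(3, 100))
        vals[1] = 5.0
        tm = TraceMatrix(vals, ["a", "flat", "c"], 10.0)
        with pytest.raises(ValidationError, match="flat"):
            zscore_traces(tm)
        with pytest.warns(UserWarning, match="flat"):
            z, excluded = zscore_traces(tm, on_constant="drop")
        assert excluded == ["flat"]
        assert z.neuron_ids == ["a", "c"]

    def test_affine_invariance(self, rng):
        vals = rng.normal(size=(4, 200))
        z1, _ = zscore_traces(TraceMatrix(vals, list("abcd"), 10.0))
        z2, _ = zscore_traces(TraceMatrix(3.5 * vals - 1.2, list("abcd"), 10.0))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)


class TestPcaTrajectory:
    def test_matches_eigendecomposition_oracle(self, rng):
        vals = rng.normal(size=(3, 4))  # 3 neurons x 4 samples -> 4 bins
        z = make_z(vals)
        traj = pca_trajectory(z, bin_s=1.0)
        X, _ = bin_population(z, 1.0)
        scores, eigvals = pca_eig_oracle(X)
        for k in range(scores.shape[1]):
            s = np.sign(scores[0, k]) * np.sign(traj.scores[0, k]) or 1.0
            np.testing.assert_allclose(traj.scores[:, k], s * scores[:, k],
                                       atol=1e-10)
        total = eigvals.sum()
        np.testing.assert_allclose(traj.explained_var, eigvals / total, atol=1e-10)

    def test_rank_one_data(self, rng):
        vals = np.zeros((3, 100))
        vals[0] = rng.normal(size=100)
        vals[1] = 2 * vals[0]
        vals[2] = -vals[0]
        traj = pca_trajectory(make_z(vals), bin_s=1.0)
        assert traj.explained_var[0] == pytest.approx(1.0)
        assert traj.k95 == 1

    def test_rotation_invariance_of_spectrum(self, rng):
        X = rng.normal(size=(30, 5))
        from scipy.stats import ortho_group

        R = ortho_group.rvs(5, random_state=1)
        ids = list("abcde")
        t1 = pca_trajectory(TraceMatrix(X.T, ids, 1.0), bin_s=1.0)
        t2 = pca_trajectory(TraceMatrix((X @ R).T, ids, 1.0), bin_s=1.0)
        np.testing.assert_allclose(t1.explained_var, t2.explained_var, atol=1e-10)

    def test_too_small_inputs(self, rng):
        with pytest.raises(ValueError, match=">= 2 neurons"):
            pca_trajectory(make_z(rng.normal(size=(1, 50))))


class TestDistance:
    def test_distance_nonnegative_and_aligned(self):
        vals = np.tile(np.linspace(-1, 1, 900), (4, 1))
        vals += np.random.default_rng(1).normal(0, 1e-6, vals.shape)
        z = make_z(vals)
        traj = pca_trajectory(z, bin_s=5.0)
        d, times = distance_to_baseline(z, traj, TL, "baseline", 1.0)
        assert d.shape == times.shape
        assert (d >= 0).all()

    def test_displacement_norm(self, rng):
        # bins displaced by v in retained PC space are at distance ||v||
        vals = rng.normal(size=(5, 900))
        z = make_z(vals)
        traj = pca_trajectory(z, bin_s=1.0)
        d, times = distance_to_baseline(z, traj, TL, "baseline", 1.0)
        X, _ = bin_population(z, 1.0)
        scores = traj.pca.transform(X)[:, :traj.k95]
        base = scores[(times >= 0) & (times + 1 <= 300)].mean(axis=0)
        np.testing.assert_allclose(d, np.linalg.norm(scores - base, axis=1),
                                   atol=1e-10)

    def test_state_shift_detected(self, strong_session):
        _, traces, timeline, truth = strong_session
        tuned = truth.loc[truth.true_class != "untuned", "neuron_id"].tolist()
        z, _ = zscore_traces(traces.select(tuned))
        traj = pca_trajectory(z, bin_s=5.0)
        d, times = distance_to_baseline(z, traj, timeline, "baseline", 1.0)
        in_base = (times >= 0) & (times + 1 <= 300)
        in_reun = (times >= 300) & (times + 1 <= 600)
        assert np.median(d[in_reun]) > np.percentile(d[in_base], 97.5)


class TestSubsample:
    def test_single_repeat_sd_zero(self, strong_session):
        _, traces, timeline, _ = strong_session
        z, _ = zscore_traces(traces.select(traces.neuron_ids[:8]))
        _, sd, _ = subsample_distance(z, timeline, n_repeats=1, seed=0)
        assert np.all(sd == 0)

    def test_deterministic(self, strong_session):
        _, traces, timeline, _ = strong_session
        z, _ = zscore_traces(traces.select(traces.neuron_ids[:10]))
        a = subsample_distance(z, timeline, n_repeats=5, seed=42)
        b = subsample_distance(z, timeline, n_repeats=5, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_duplicated_population_close_to_full(self, strong_session):
        _, traces, timeline, truth = strong_session
        tuned = truth.loc[truth.true_class != "untuned", "neuron_id"].tolist()
        z, _ = zscore_traces(traces.select(tuned))
        dup = TraceMatrix(np.vstack([z.values, z.values]),
                          [f"{i}a" for i in tuned] + [f"{i}b" for i in tuned],
                          z.fs, z.t0)
        traj = pca_trajectory(dup, bin_s=5.0)
        full, times = distance_to_baseline(dup, traj, timeline, "baseline", 1.0)
        mean, _, _ = subsample_distance(dup, timeline, n_repeats=30, seed=1)
        scale = np.median(full[full > 0])
        assert np.median(np.abs(mean - full)) / scale < 0.05

    def test_too_few_neurons(self, rng):
        z = make_z(rng.normal(size=(3, 900)))
        with pytest.raises(ValueError, match=">= 4"):
            subsample_distance(z, TL)


class TestReturnLatency:
    def _series(self, cross_at, thr_base=1.0, n=900):
        times = np.arange(n, dtype=float)
        d = np.zeros(n)
        d[:300] = 0.5  # baseline: all below
        d[300:] = 5.0
        d[int(cross_at):] = 0.5
        return d, times

    def test_constructed_crossing_recovered(self):
        d, times = self._series(720)
        est = return_latency(d, times, TL, "baseline", removal_time=600.0)
        assert est.latency_s == pytest.approx(120.0, abs=1.0)
        assert est.returned

    def test_drop_at_removal_gives_zero(self):
        d, times = self._series(600)
        est = return_latency(d, times, TL, "baseline", removal_time=600.0)
        assert est.latency_s == 0.0
        assert est.time_below_s == pytest.approx(300.0, abs=1.0)

    def test_never_returning_is_sentinel(self):
        d, times = self._series(600)
        d[600:] = 99.0
        est = return_latency(d, times, TL, "baseline", removal_time=600.0)
        assert not est.returned
        assert np.isnan(est.latency_s)
        assert est.time_below_s == 0.0

    def test_sustain_skips_single_bin_dips(self):
        d, times = self._series(700)
        d[650] = 0.0  # isolated single-bin dip must not count as a return
        est = return_latency(d, times, TL, "baseline", removal_time=600.0,
                             sustain_bins=3)
        assert est.latency_s == pytest.approx(100.0, abs=1.0)

    def test_random_crossings_recovered_within_one_bin(self, rng):
        for _ in range(50):
            cross = int(rng.integers(610, 890))
            d, times = self._series(cross)
            est = return_latency(d, times, TL, "baseline", removal_time=600.0)
            assert est.latency_s == pytest.approx(cross - 600.0, abs=1.0)


class TestDecoding:
    def test_separable_states(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 10)), rng.normal(6, 1, (60, 10))])
        y = np.array(["iso"] * 60 + ["reun"] * 60)
        accs = decode_states(X, y, n_repeats=20, seed=0)
        assert accs.mean() >= 0.99

    def test_identical_distributions_near_chance(self, rng):
        X = rng.normal(size=(240, 10))
        y = np.array(["a", "b"] * 120)
        accs = decode_states(X, y, n_repeats=50, seed=0)
        assert abs(accs.mean() - 0.5) < 0.08

    def test_too_few_bins_per_state(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="fewer than 5"):
            decode_states(X, y)

    def test_estimator_api(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(5, 1, (30, 4))])
        y = np.array([0] * 30 + [1] * 30)
        dec = StateDecoder(n_repeats=5, random_state=1).fit(X, y)
        assert dec.get_params()["n_repeats"] == 5
        assert (dec.predict(rng.normal(5, 1, (5, 4))) == 1).all()


def test_state_labels_assigns_whole_bins():
    times = np.array([0.0, 299.0, 300.0, 599.0, 600.0])
    labels = state_labels(TL, times, 1.0)
    assert labels.tolist() == ["baseline", "baseline", "reunion", "reunion",
                               "reisolation"]
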