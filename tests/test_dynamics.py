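"""Dynamic FNC: taper, windowed correlation, state clustering, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfnckit.cohort import (default_cohort_config, markov_from_occupancy,
                            sample_state_sequence, simulate_cohort,
                            simulate_subject)
from dfnckit.dynamics import (StateModel, WindowSpec, build_taper,
                              cluster_states, pool_windows, select_k,
                              subject_state_fnc, temporal_metrics,
                              window_count, window_truth_labels, windowed_fnc)
from dfnckit.sfnc import ComponentTimecourses, fisher_z


def brute_force_metrics(seq, k):
    """Independent run-length scanner used as the metrics oracle."""
    seq = list(seq)
    frac = [seq.count(s) / len(seq) for s in range(k)]
    runs = []
    cur_state, cur_len = seq[0], 1
    for a in seq[1:]:
        if a == cur_state:
            cur_len += 1
        else:
            runs.append((cur_state, cur_len))
            cur_state, cur_len = a, 1
    runs.append((cur_state, cur_len))
    dwell = []
    for s in range(k):
        lens = [ln for st_, ln in runs if st_ == s]
        dwell.append(sum(lens) / len(lens) if lens else 0.0)
    transitions = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    return frac, dwell, transitions, runs


class TestTaper:
    @pytest.mark.parametrize("spec", [WindowSpec(22, 3.0, 1),
                                      WindowSpec(10, 1.5, 2),
                                      WindowSpec(33, 5.0, 1)])
    def test_normalised_and_symmetric(self, spec):
        w = build_taper(spec)
        assert w.size == spec.length
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, w[::-1], atol=1e-15)

    def test_flat_limit_is_uniform(self):
        w = build_taper(WindowSpec(22, 1e6, 1))
        assert np.abs(w - 1 / 22).max() < 1e-3

    def test_matches_direct_convolution_oracle(self):
        # independent elementwise convolution at the same +/- 4 sigma support
        length, sigma = 22, 3.0
        half = int(np.ceil(4 * sigma))
        g = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        g /= g.sum()
        full_len = length + 2 * half
        oracle = np.zeros(full_len)
        for i in range(length):  # rect index
            for j in range(2 * half + 1):
                oracle[i + j] += g[j]
        start = (full_len - length) // 2
        oracle = oracle[start:start + length]
        oracle /= oracle.sum()
        w = build_taper(WindowSpec(length, sigma, 1))
        assert (w[length // 2] / w[0]) == pytest.approx(
            oracle[length // 2] / oracle[0], abs=1e-10)
        np.testing.assert_allclose(w, oracle, atol=1e-12)


class TestWindowedFnc:
    @given(t=st.integers(30, 400), length=st.integers(3, 29),
           step=st.integers(1, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_count_formula(self, t, length, step):
        spec = WindowSpec(length, 2.0, step)
        n = window_count(t, spec)
        assert n == len(range(0, t - length + 1, step))

    def test_default_study_geometry_gives_209_windows(self):
        assert window_count(230, WindowSpec(22, 3.0, 1)) == 209

    def test_flat_taper_equals_plain_pearson(self, rng):
        data = rng.standard_normal((4, 60))
        tc = ComponentTimecourses("s", data, tr=2.0)
        spec = WindowSpec(20, 3.0, 2)
        flat = np.full(20, 1 / 20)
        wf = windowed_fnc(tc, spec, fisher=False, taper=flat)
        iu = np.triu_indices(4, k=1)
        for wi, s in enumerate(wf.window_starts):
            plain = np.corrcoef(data[:, s:s + 20])[iu]
            np.testing.assert_allclose(wf.values[wi], plain, atol=1e-10)

    def test_deep_run_windows_match_state_z(self, default_cohort):
        # alternating 60-TR runs; windows fully inside a run, averaged
        # over many runs, estimate the active state's z matrix.
        # (overlapping windows are heavily correlated, so a long
        # simulation is needed for a +/-0.1 entrywise check)
        covs = default_cohort.state_covariances
        block = 60
        n_blocks = 200
        seq = np.tile(np.repeat([0, 1], block), n_blocks // 2)
        tc = simulate_subject(covs, seq, seed=15)
        spec = WindowSpec()
        wf = windowed_fnc(tc, spec)
        iu = np.triu_indices(21, k=1)
        starts = wf.window_starts
        inside = (starts % block) <= block - spec.length
        run_state = (starts // block) % 2
        for state in (0, 1):
            sel = inside & (run_state == state)
            mean_z = wf.values[sel].mean(axis=0)
            true_z = fisher_z(covs.matrices[state][iu])
            assert np.abs(mean_z - true_z).max() < 0.1

    def test_zero_variance_window_flagged(self, rng):
        data = rng.standard_normal((3, 60))
        data[0, 10:40] = 2.5  # flat stretch inside some windows
        tc = ComponentTimecourses("s", data, tr=2.0)
        with pytest.warns(UserWarning, match="zero weighted variance"):
            wf = windowed_fnc(tc, WindowSpec(12, 3.0, 1))
        # affected edges are zeroed, others finite
        assert np.all(np.isfinite(wf.values))


class TestClusterStates:
    def test_k1_centroid_is_componentwise_median(self, rng):
        from dfnckit.dynamics import WindowedFnc

        vals = rng.standard_normal((50, 8))
        wf = WindowedFnc("s", vals, np.arange(50), WindowSpec(5, 1.0, 1), 5)
        model = cluster_states([wf], 1, n_init=2, seed=0)
        np.testing.assert_allclose(model.centroids[0],
                                   np.median(vals, axis=0), atol=1e-12)

    def test_duplicated_windows_same_centroids(self, rng):
        from dfnckit.dynamics import WindowedFnc

        vals = rng.standard_normal((60, 5)) + np.repeat(
            np.array([[0.0], [4.0]]), 30, axis=0)
        wf1 = WindowedFnc("a", vals, np.arange(60), WindowSpec(5, 1.0, 1), 4)
        wf2 = WindowedFnc("b", vals.copy(), np.arange(60),
                          WindowSpec(5, 1.0, 1), 4)
        single = cluster_states([wf1], 2, n_init=5, seed=3)
        doubled = cluster_states([wf1, wf2], 2, n_init=5, seed=3)
        np.testing.assert_allclose(np.sort(single.centroids, axis=0),
                                   np.sort(doubled.centroids, axis=0),
                                   atol=1e-10)

    def test_states_ordered_by_occurrence(self, rng):
        from dfnckit.dynamics import WindowedFnc

        vals = np.vstack([np.zeros((70, 3)), np.full((30, 3), 5.0)])
        wf = WindowedFnc("s", vals, np.arange(100), WindowSpec(5, 1.0, 1), 3)
        model = cluster_states([wf], 2, n_init=3, seed=0)
        assert model.occurrence[0] >= model.occurrence[1]
        assert model.occurrence.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(model.centroids[0], 0.0, atol=1e-9)

    def test_occupancy_consistency(self, small_cohort):
        wfs = [windowed_fnc(tc, WindowSpec(20, 3.0, 2))
               for tc in small_cohort.subjects]
        model = cluster_states(wfs, 3, n_init=3, seed=1)
        metrics = temporal_metrics(model.assignments, 3)
        weights = np.array([wf.n_windows for wf in wfs], float)
        weights /= weights.sum()
        frac_cols = [f"frac_{s + 1}" for s in range(3)]
        pooled = (metrics.loc[[w.subject_id for w in wfs], frac_cols]
                  .to_numpy() * weights[:, None]).sum(axis=0)
        np.testing.assert_allclose(pooled, model.occurrence, atol=1e-12)

    def test_invalid_k(self, rng):
        from dfnckit.dynamics import WindowedFnc

        wf = WindowedFnc("s", rng.standard_normal((10, 4)), np.arange(10),
                         WindowSpec(5, 1.0, 1), 4)
        with pytest.raises(ValueError, match="k must"):
            cluster_states([wf], 11)

    def test_exemplar_subsampling_agrees_on_separated_data(self, rng):
        from dfnckit.dynamics import WindowedFnc

        vals = np.vstack([rng.normal(0, 0.2, (60, 4)),
                          rng.normal(5, 0.2, (40, 4))])
        wf = WindowedFnc("s", vals, np.arange(100), WindowSpec(5, 1.0, 1), 4)
        a = cluster_states([wf], 2, n_init=5, seed=0)
        b = cluster_states([wf], 2, n_init=5, seed=0,
                           exemplar_subsampling=True)
        np.testing.assert_allclose(a.centroids, b.centroids, atol=0.1)


class TestSelectK:
    def test_three_separated_clusters(self, rng):
        x = np.vstack([rng.normal(loc, 0.3, (80, 4))
                       for loc in (0.0, 5.0, 10.0)])
        k_sil, diag = select_k(x, (2, 6), seed=0, criterion="silhouette")
        k_gap, _ = select_k(x, (2, 6), seed=0, criterion="gap")
        assert k_sil == 3
        assert k_gap == 3
        assert diag.loc[diag["silhouette"].idxmax(), "k"] == 3

    def test_single_blob_gap_rule_selects_one(self, rng):
        x = rng.standard_normal((150, 4))
        k, _ = select_k(x, range(1, 5), seed=0, criterion="gap")
        assert k == 1

    def test_deterministic_diagnostics(self, rng):
        x = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(4, 1, (60, 3))])
        _, d1 = select_k(x, (2, 4), seed=5)
        _, d2 = select_k(x, (2, 4), seed=5)
        np.testing.assert_array_equal(d1.to_numpy(), d2.to_numpy())

    def test_k_range_exceeding_windows_rejected(self, rng):
        with pytest.raises(ValueError, match="k_range"):
            select_k(rng.standard_normal((5, 3)), (2, 9))


class TestTemporalMetrics:
    def test_hand_enumerated_sequence(self):
        m = temporal_metrics({"s": np.array([0, 0, 1, 1, 1, 0])}, 2)
        assert m.loc["s", "frac_1"] == pytest.approx(0.5)
        assert m.loc["s", "frac_2"] == pytest.approx(0.5)
        assert m.loc["s", "dwell_1"] == pytest.approx(1.5)
        assert m.loc["s", "dwell_2"] == pytest.approx(3.0)
        assert m.loc["s", "transitions"] == 2

    def test_constant_sequence(self):
        m = temporal_metrics({"s": np.zeros(209, int)}, 4)
        assert m.loc["s", "frac_1"] == 1.0
        assert m.loc["s", "dwell_1"] == 209
        assert m.loc["s", "transitions"] == 0
        assert m.loc["s", "dwell_2"] == 0.0  # absent-state convention

    def test_absent_state_missing_convention(self):
        m = temporal_metrics({"s": np.zeros(10, int)}, 2,
                             absent_state="missing")
        assert np.isnan(m.loc["s", "dwell_2"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        k = 4
        for _ in range(300):
            seq = rng.integers(0, k, size=rng.integers(1, 80))
            m = temporal_metrics({"s": seq}, k)
            frac, dwell, transitions, runs = brute_force_metrics(seq, k)
            for s in range(k):
                assert m.loc["s", f"frac_{s + 1}"] == frac[s]
                assert m.loc["s", f"dwell_{s + 1}"] == dwell[s]
            assert m.loc["s", "transitions"] == transitions
            # conservation: run-length totals account for every window
            assert sum(ln for _, ln in runs) == seq.size
            assert sum(frac) == pytest.approx(1.0, abs=1e-12)

    def test_seconds_view_factor(self):
        m = temporal_metrics({"s": np.zeros(10, int)}, 1,
                             WindowSpec(22, 3.0, 2), tr=2.0)
        assert m.attrs["dwell_seconds_factor"] == 4.0


class TestSubjectStateFnc:
    def _model_for(self, wfs, assignments):
        return StateModel(
            k=2, centroids=np.zeros((2, wfs[0].values.shape[1])),
            assignments=assignments, occurrence=np.array([0.5, 0.5]),
            metric="cityblock", seed=0, inertia=0.0,
        )

    def test_single_state_subject(self, rng):
        from dfnckit.dynamics import WindowedFnc

        vals = rng.standard_normal((30, 6))
        wf = WindowedFnc("s", vals, np.arange(30), WindowSpec(5, 1.0, 1), 4)
        model = self._model_for([wf], {"s": np.zeros(30, int)})
        out = subject_state_fnc([wf], model)
        np.testing.assert_allclose(out[0, 0], vals.mean(axis=0))
        assert np.all(np.isnan(out[0, 1]))

    def test_window_order_invariance(self, rng):
        from dfnckit.dynamics import WindowedFnc

        vals = rng.standard_normal((40, 5))
        a = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        wf1 = WindowedFnc("s", vals, np.arange(40), WindowSpec(5, 1.0, 1), 4)
        wf2 = WindowedFnc("s", vals[perm], np.arange(40),
                          WindowSpec(5, 1.0, 1), 4)
        out1 = subject_state_fnc([wf1], self._model_for([wf1], {"s": a}))
        out2 = subject_state_fnc([wf2], self._model_for([wf2], {"s": a[perm]}))
        np.testing.assert_allclose(out1, out2, atol=1e-12)


class TestGroupRecoveryProperty:
    def test_state1_group_difference_has_planted_sign(self):
        # recovered State-1 fractional windows split in the planted
        # direction across a small seed ensemble
        hits = 0
        n_seeds = 5
        for seed in range(1, n_seeds + 1):
            cohort = simulate_cohort(default_cohort_config(
                seed=seed, separation="high"))
            spec = WindowSpec()
            wfs = [windowed_fnc(tc, spec) for tc in cohort.subjects]
            model = cluster_states(wfs, 4, n_init=5, seed=seed)
            metrics = temporal_metrics(model.assignments, 4, spec)
            g = cohort.groups.loc[metrics.index]
            diff = (metrics.loc[g == "COPD", "frac_1"].mean()
                    - metrics.loc[g == "HC", "frac_1"].mean())
            hits += int(diff > 0)
        assert hits >= int(0.9 * n_seeds)

    def test_window_truth_labels_majority(self):
        seq = np.array([0] * 15 + [1] * 15)
        labels = window_truth_labels(seq, WindowSpec(10, 2.0, 1))
        assert labels[0] == 0 and labels[-1] == 1
        assert labels[9] == 0  # 6 zeros vs 4 ones
        assert labels[10] == 0  # 5-5 tie resolves to the lower state index
        assert labels[11] == 1  # 4 zeros vs 6 ones
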