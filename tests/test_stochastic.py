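"""Semi-stochastic analysis: response windows, condition grids, iteration
sufficiency, duration thresholds and unit clustering."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from optopulse import stimuli, synth
from optopulse.stochastic import (
    cluster_units,
    condition_metrics,
    duration_threshold,
    iteration_sufficiency,
    sta_window,
)
from tests.conftest import constant_p_params


@pytest.fixture(scope="module")
def schedule_rec(small_protocol):
    par = synth.NeuronParams(q50=20.0, slope=5.0, spont_rate=5.0)
    return synth.simulate_schedule(par, small_protocol, seed=17)


class TestStaWindow:
    def test_window_captures_evoked_spikes(self, small_protocol):
        par = synth.NeuronParams(q50=-100.0, latency_mu=2.2, latency_sd=0.1,
                                 spont_rate=0.0, adapt_depletion=0.0,
                                 block_rate=1e9, latency_drive_mu=0.0,
                                 latency_drive_sd=0.0)
        rec = synth.simulate_schedule(par, small_protocol, seed=3)
        offset = sta_window(rec, small_protocol, width=3.0)
        # evoked latencies are N(2.2, 0.1): the 3 ms window starting at the
        # returned offset must cover >= 99% of that mass
        lo, hi = offset, offset + 3.0
        from scipy.stats import norm

        covered = norm.cdf(hi, 2.2, 0.1) - norm.cdf(lo, 2.2, 0.1)
        assert covered >= 0.99

    def test_spont_only_falls_back_with_warning(self, small_protocol):
        par = synth.NeuronParams(q50=1e6, spont_rate=0.5)
        rec = synth.simulate_schedule(par, small_protocol, seed=4)
        with pytest.warns(UserWarning):
            offset = sta_window(rec, small_protocol)
        assert offset == 1.0


class TestConditionMetrics:
    def test_combo_mode_has_35_keys(self, schedule_rec, small_protocol):
        grid = condition_metrics(schedule_rec, small_protocol, mode="combo")
        assert len(grid.keys) == 35
        assert grid.n_presentations.sum() == 35 * 10 * small_protocol.n_iterations

    def test_isi_mode_has_245_keys(self, schedule_rec, default_protocol):
        par = synth.NeuronParams()
        rec = synth.simulate_schedule(par, default_protocol, seed=18)
        grid = condition_metrics(rec, default_protocol, mode="isi")
        assert len(grid.keys) == 245

    def test_spikes_monotone_in_duration_at_fixed_rate(self, small_protocol):
        par = constant_p_params(0.5, 0.8, 35.0, spont_rate=0.0)
        par = synth.NeuronParams(q50=par.q50, slope=5.0, adapt_depletion=0.0,
                                 block_rate=1e9, spont_rate=0.0)
        rec = synth.simulate_schedule(par, small_protocol, seed=19)
        grid = condition_metrics(rec, small_protocol, mode="combo")
        vals = {(k.rate, k.duration): v for k, v in zip(grid.keys, grid.spikes_per_pulse)}
        durs = sorted({k.duration for k in grid.keys})
        series = [vals[(10.0, d)] for d in durs]
        # allow small binomial wiggle at 60 presentations per condition
        assert all(b >= a - 0.15 for a, b in zip(series, series[1:]))


class TestIterationSufficiency:
    def test_deterministic_unit_stabilizes_immediately(self, small_protocol,
                                                       deterministic_params):
        rec = synth.simulate_schedule(deterministic_params, small_protocol, seed=5)
        n, ok = iteration_sufficiency(rec, small_protocol)
        assert ok and n == 2

    def test_zero_tolerance_on_noisy_data_flags(self, schedule_rec, small_protocol):
        n, ok = iteration_sufficiency(schedule_rec, small_protocol, tolerance=0.0)
        assert not ok and n == small_protocol.n_iterations

    def test_moderate_tolerance_stabilizes_before_full_data(self, small_protocol):
        par = constant_p_params(0.8, 1.6, 35.0, spont_rate=2.0)
        rec = synth.simulate_schedule(par, small_protocol, seed=6)
        n, ok = iteration_sufficiency(rec, small_protocol, tolerance=0.25)
        assert ok and n <= small_protocol.n_iterations


class TestDurationThreshold:
    def _grid(self, rates, durs, values):
        keys, spp = [], []
        for r in rates:
            for d in durs:
                keys.append(stimuli.ConditionKey(mode="combo", rate=r, duration=d))
                spp.append(values[(r, d)])
        from optopulse.stochastic import ConditionGrid

        return ConditionGrid(mode="combo", unit_id="u", keys=keys,
                             spikes_per_pulse=np.array(spp),
                             fsl=np.full(len(keys), np.nan),
                             fsl_jitter=np.full(len(keys), np.nan),
                             n_presentations=np.full(len(keys), 10))

    def test_silent_unit_has_no_thresholds(self):
        grid = self._grid([10.0, 100.0], [0.2, 0.8, 2.4],
                          {(r, d): 0.0 for r in (10.0, 100.0) for d in (0.2, 0.8, 2.4)})
        thresholds, slope = duration_threshold(grid)
        assert all(t is None for t in thresholds.values())
        assert slope is None

    def test_exact_linear_thresholds_reproduce_regression_slope(self):
        # construct spikes/pulse = duration - offset(rate), so the 0.1
        # crossing sits at known durations {0.4, 0.6, 0.8} for the 3 rates
        rates = [10.0, 100.0, 179.0]
        target = {10.0: 0.4, 100.0: 0.6, 179.0: 0.8}
        durs = [0.2, 0.4, 0.6, 0.8, 1.2]
        values = {(r, d): max(0.0, 0.1 + (d - target[r])) for r in rates for d in durs}
        grid = self._grid(rates, durs, values)
        thresholds, slope = duration_threshold(grid, criterion=0.1)
        for r in rates:
            assert thresholds[r] == pytest.approx(target[r], abs=1e-9)
        x = np.array(rates)
        y = np.array([target[r] for r in rates])
        assert slope == pytest.approx(np.polyfit(x, y, 1)[0])

    def test_thresholds_increase_with_rate_for_adapting_unit(self, default_protocol):
        par = synth.NeuronParams(q50=26.0, slope=6.0, adapt_depletion=0.35,
                                 tau_rec=40.0, spont_rate=0.0)
        rec = synth.simulate_schedule(par, default_protocol, seed=20)
        grid = condition_metrics(rec, default_protocol, mode="combo")
        thresholds, slope = duration_threshold(grid)
        t10, t313 = thresholds[10.0], thresholds[313.0]
        assert t10 is not None and t313 is not None and t313 > t10
        assert slope is not None and slope > 0


class TestClusterUnits:
    def test_well_separated_clusters_recovered_exactly(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.1] * 35, [0.5] * 35, [0.9] * 35])
        labels_true = np.repeat([0, 1, 2], [4, 5, 3])
        X = centers[labels_true] + rng.normal(0, 0.02, (12, 35))
        out = cluster_units(X, seed=1)
        assert adjusted_rand_score(labels_true, out.labels) == 1.0
        assert out.variance_explained[0] > 0.9

    def test_variance_explained_non_increasing_and_bounded(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 35))
        out = cluster_units(X, n_components=4, seed=2, k=3)
        assert np.all(np.diff(out.variance_explained) <= 1e-12)
        assert out.variance_explained.sum() <= 1.0 + 1e-9

    def test_identical_units_flagged_unstable(self):
        X = np.ones((6, 35))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = cluster_units(X, seed=3, k=3)
        assert out.meta["unstable"]
        assert np.allclose(out.variance_explained, 0.0)

    def test_label_permutation_leaves_ari_unchanged(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(c, 0.05, (4, 10)) for c in (0.0, 1.0, 2.0)])
        truth = np.repeat([0, 1, 2], 4)
        out = cluster_units(X, seed=4)
        ari = adjusted_rand_score(truth, out.labels)
        permuted = (out.labels + 1) % 3
        assert adjusted_rand_score(truth, permuted) == pytest.approx(ari)

    def test_more_clusters_than_units_rejected(self):
        with pytest.raises(ValueError):
            cluster_units(np.zeros((2, 5)), k=3, seed=0)

    def test_end_to_end_cluster_recovery_from_simulated_cohort(self, default_protocol):
        """PCA + k-means on per-condition spike counts recovers the three
        generator clusters of a well-separated synthetic cohort."""
        spec = synth.default_cluster_spec()
        for c in spec:  # shrink within-cluster spread to separate clearly
            c["jitter"] = {k: v * 0.2 for k, v in c["jitter"].items()}
        params = synth.sample_population(12, cluster_spec=spec, seed=21)
        recs = [synth.simulate_schedule(p, default_protocol, seed=100 + i,
                                        unit_id=f"u{i}")
                for i, p in enumerate(params)]
        grids = [condition_metrics(r, default_protocol, mode="combo") for r in recs]
        X = np.vstack([g.spikes_per_pulse for g in grids])
        out = cluster_units(X, seed=5)
        truth = [p.cluster_id for p in params]
        assert adjusted_rand_score(truth, out.labels) == 1.0
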