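"""Rate-level analysis: level conversion, adapted rates, classification,
d' thresholds and dynamic range."""

import numpy as np
import pytest

from optopulse import rlf as rlf_mod
from optopulse import stimuli, synth
from optopulse.rlf import (
    RateLevelFunction,
    adapted_rate,
    classify_rlf,
    db_to_power,
    dprime,
    dprime_threshold,
    dynamic_range,
    level_db,
)
from tests.conftest import constant_p_params


def make_rlf(levels, mean_rates, spont_mean=5.0, sd=1.0, n_trials=20, seed=0):
    rng = np.random.default_rng(seed)
    trial_rates = [rng.normal(m, sd, n_trials) for m in mean_rates]
    spont = rng.normal(spont_mean, sd, n_trials)
    return RateLevelFunction(levels=np.asarray(levels, float),
                             trial_rates=trial_rates, spont_rates=spont)


class TestLevelDb:
    def test_reference_is_zero(self):
        assert level_db(12.0, 12.0) == pytest.approx(0.0)

    def test_doubling_is_3db(self):
        assert level_db(2.0, 1.0) == pytest.approx(3.0103, abs=1e-4)

    def test_round_trip(self):
        for a in (0.5, 5.0, 35.0):
            assert db_to_power(level_db(a, 12.0), 12.0) == pytest.approx(a)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            level_db(0.0, 1.0)


class TestAdaptedRate:
    def _rec(self, times_per_trial, train):
        return synth.SpikeRecording(unit_id="u", trials={
            t: np.asarray(v, float) for t, v in enumerate(times_per_trial)},
            stimulus=train)

    def test_stationary_rate(self, train_100pps):
        times = np.arange(0.5, 400.0, 10.0)  # 100 spikes/s
        rec = self._rec([times] * 3, train_100pps)
        assert adapted_rate(rec) == pytest.approx(100.0)

    def test_onset_only_response_is_zero(self, train_100pps):
        rec = self._rec([np.linspace(1, 90, 30)], train_100pps)
        assert adapted_rate(rec) == 0.0

    def test_short_train_rejected(self):
        tr = stimuli.make_pulse_train(100.0, 1.6, train_len=200.0)
        rec = self._rec([[10.0]], tr)
        with pytest.raises(ValueError):
            adapted_rate(rec)

    def test_matches_full_train_rate_for_stationary_generator(self, train_100pps):
        par = constant_p_params(0.8, 1.6, 35.0)
        rec = synth.simulate_sgn(par, train_100pps, n_trials=50, seed=2)
        from optopulse.metrics import discharge_rate

        full = discharge_rate(rec, 0.0, 400.0)
        assert adapted_rate(rec) == pytest.approx(full, rel=0.1)


class TestClassifyRlf:
    def test_non_responding(self):
        r = make_rlf([0, 2, 4, 6], [5, 6, 7, 10], spont_mean=5.0, sd=0.5)
        assert classify_rlf(r) == "non-responding"

    def test_saturating_slope_rule(self):
        # slope 2 spikes/dB between the two highest levels
        r = make_rlf([0, 2, 4, 6], [5, 40, 76, 80], spont_mean=5.0, sd=0.5)
        assert classify_rlf(r) == "saturating"

    def test_non_saturating(self):
        r = make_rlf([0, 2, 4, 6], [5, 25, 45, 65], spont_mean=5.0, sd=0.5)
        assert classify_rlf(r) == "non-saturating"


class TestDprime:
    def test_pooled_variance_formula(self):
        rng = np.random.default_rng(1)
        driven = rng.normal(10, 3, 2000)
        ref = rng.normal(5, 4, 2000)
        # (10-5)/sqrt((9+16)/2) = 1.414
        assert dprime(driven, ref) == pytest.approx(1.4142, abs=0.1)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        driven = rng.normal(8, 2, 200)
        ref = rng.normal(5, 2, 200)
        d0 = dprime(driven, ref)
        d1 = dprime(3 * driven + 7, 3 * ref + 7)
        assert d1 == pytest.approx(d0)


class TestDprimeThreshold:
    def test_flat_rlf_has_no_threshold(self):
        r = make_rlf([0, 2, 4, 6], [5, 5, 5, 5], spont_mean=5.0, sd=2.0)
        assert dprime_threshold(r) is None

    def test_no_subthreshold_level_rejected(self):
        r = make_rlf([0, 2, 4, 6], [50, 60, 70, 80], spont_mean=5.0, sd=2.0)
        with pytest.raises(ValueError):
            dprime_threshold(r)

    def test_threshold_matches_dense_grid_oracle(self):
        # deterministic d'-level function: linear in level, crosses 1 at 3.5 dB
        levels = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        sd = 4.0
        spont_mean = 10.0
        # d'(L) = (mu(L) - spont)/sd with equal variances; mu = spont + sd*(L - 3.5)/3.5...
        # choose mu so that d' = L / 3.5
        mus = spont_mean + sd * levels / 3.5
        n = 4000  # large n: sample moments ~ population moments
        rng = np.random.default_rng(3)
        trial_rates = [rng.normal(m, sd, n) for m in mus]
        spont = rng.normal(spont_mean, sd, n)
        r = RateLevelFunction(levels=levels, trial_rates=trial_rates, spont_rates=spont)
        thr = dprime_threshold(r, step_db=0.2)
        # dense-grid oracle on the generating model: lowest level with d' >= 1
        grid = np.arange(0, 8, 0.001)
        oracle = grid[np.argmax(grid / 3.5 >= 1.0)]
        assert thr == pytest.approx(oracle, abs=0.4)

    def test_threshold_monotone_in_driven_rates(self):
        levels = [0, 2, 4, 6, 8]
        base = [5.0, 6.0, 9.0, 14.0, 20.0]
        low = make_rlf(levels, base, sd=2.0, seed=4)
        # raising all driven rates (same noise realization) cannot raise the threshold
        high = RateLevelFunction(levels=np.asarray(levels, float),
                                 trial_rates=[r + 1.0 for r in low.trial_rates],
                                 spont_rates=low.spont_rates)
        t_low = dprime_threshold(low)
        t_high = dprime_threshold(high)
        if t_low is not None and t_high is not None:
            assert t_high <= t_low


class TestDynamicRange:
    def test_noiseless_logistic_recovers_95_point(self):
        floor, span, mid, slope = 5.0, 80.0, 4.0, 0.8
        levels = np.linspace(0, 10, 9)
        rates = floor + span / (1 + np.exp(-(levels - mid) / slope))
        r = RateLevelFunction(levels=levels,
                              trial_rates=[np.full(5, v) for v in rates],
                              spont_rates=np.full(5, floor))
        r.class_label = "saturating"
        dr, driven = dynamic_range(r, criterion=0.95, threshold_db=2.0)
        # closed-form level where the logistic reaches 0.95*(floor+span)
        target = 0.95 * (floor + span)
        frac = (target - floor) / span
        upper = mid + slope * np.log(frac / (1 - frac))
        assert dr == pytest.approx(upper - 2.0, abs=0.05)

    def test_non_saturating_uses_max_level(self):
        levels = [0, 2, 4, 6, 8]
        r = make_rlf(levels, [5, 15, 30, 45, 60], sd=0.5)
        r.class_label = "non-saturating"
        dr, driven = dynamic_range(r, threshold_db=2.0)
        assert dr == pytest.approx(6.0)
        assert driven >= 0.0

    def test_non_responding_rejected(self):
        r = make_rlf([0, 2, 4, 6], [5, 5, 5, 6], spont_mean=5.0, sd=0.5)
        with pytest.raises(ValueError):
            dynamic_range(r, threshold_db=1.0)


class TestParameterRecovery:
    def test_threshold_recovery_on_simulated_population(self):
        """Simulated RLFs recover the generating model's d' threshold to
        within 0.4 dB (median over units)."""
        a0 = 12.0  # oABR-threshold flux used as the dB reference
        levels_db = np.array([-6.0, -3.0, 0.0, 2.0, 4.0, 6.0])
        fluxes = db_to_power(levels_db, a0)
        duration = 1.6
        errors = []
        rng = np.random.default_rng(42)
        for _ in range(12):
            par = synth.NeuronParams(
                q50=float(rng.uniform(15, 30)), slope=4.0,
                adapt_depletion=0.0, block_rate=1e9, spont_rate=20.0,
            )
            train_by_level = [
                stimuli.make_pulse_train(100.0, duration, intensity=f)
                for f in fluxes
            ]
            trial_rates = []
            for tr in train_by_level:
                rec = synth.simulate_sgn(par, tr, n_trials=20,
                                         seed=int(rng.integers(2**31)))
                trial_rates.append(rlf_mod.adapted_rates_per_trial(rec))
            dark = stimuli.make_pulse_train(100.0, duration, intensity=1e-6)
            rec0 = synth.simulate_sgn(par, dark, n_trials=20,
                                      seed=int(rng.integers(2**31)))
            spont = rlf_mod.adapted_rates_per_trial(rec0)
            r = RateLevelFunction(levels=levels_db, trial_rates=trial_rates,
                                  spont_rates=spont)
            try:
                thr = dprime_threshold(r)
            except ValueError:
                continue
            if thr is None:
                continue
            # oracle: d' of the generating model on a dense level grid,
            # using exact per-trial count distributions (Binomial over 30
            # plateau pulses) vs the Poisson-like spontaneous reference
            grid = np.arange(levels_db[0], levels_db[-1], 0.001)
            mu0, var0 = spont.mean(), spont.var(ddof=1)
            d_or = []
            for g in grid:
                p = par.pulse_probability(duration, db_to_power(g, a0))
                # 30 plateau pulses / 0.3 s; superposed spont in the window
                mu = p * 30 / 0.3 + 20.0
                var = 30 * p * (1 - p) / 0.3**2 + 20.0 / 0.3
                d_or.append((mu - mu0) / np.sqrt((var + var0) / 2))
            d_or = np.asarray(d_or)
            if not np.any(d_or >= 1.0) or d_or[0] >= 1.0:
                continue
            oracle = grid[np.argmax(d_or >= 1.0)]
            errors.append(abs(thr - oracle))
        assert len(errors) >= 6
        assert np.median(errors) <= 0.4
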