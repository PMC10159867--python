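"""Intensity coding: rate-level functions, d' thresholds and dynamic range.

Levels are expressed in dB re the evoked-potential threshold intensity:
level = 10*log10(A/A0) with A the radiant flux (mW) and A0 the flux at the
brainstem-response threshold.  Discharge rates enter as adapted (plateau)
rates measured between 100 and 400 ms of the train, one value per trial,
so detection-theoretic statistics have trial-to-trial variance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synth import SpikeRecording

__all__ = [
    "RateLevelFunction",
    "level_db",
    "db_to_power",
    "adapted_rate",
    "adapted_rates_per_trial",
    "classify_rlf",
    "dprime",
    "dprime_threshold",
    "dynamic_range",
    "ADAPTED_WINDOW_MS",
    "DPRIME_STEP_DB",
]

ADAPTED_WINDOW_MS = (100.0, 400.0)
DPRIME_STEP_DB = 0.2
RESPONDING_MARGIN = 10.0  # spikes/s above spont at top level
SATURATION_SLOPE = 3.0  # spikes/s per dB between the two highest levels


@dataclass
class RateLevelFunction:
    """Adapted discharge rate vs stimulus level for one unit/pulse duration.

    ``trial_rates[i]`` holds the per-trial adapted rates at ``levels[i]``;
    ``spont_rates`` are the per-trial rates of the spontaneous reference
    (lowest sub-threshold intensity, or dark windows).
    """

    levels: np.ndarray  # dB, sorted ascending
    trial_rates: list  # list of np.ndarray, per level
    spont_rates: np.ndarray
    pulse_duration: float | None = None
    unit_id: str | None = None
    class_label: str | None = None
    threshold_db: float | None = None
    dynamic_range_db: float | None = None
    driven_rate: float | None = None
    fit_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.trial_rates = [np.asarray(r, dtype=float) for r in self.trial_rates]
        self.spont_rates = np.asarray(self.spont_rates, dtype=float)
        if self.levels.size != len(self.trial_rates):
            raise ValueError("one trial-rate vector per level is required")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")

    @property
    def mean_rates(self) -> np.ndarray:
        return np.array([r.mean() for r in self.trial_rates])

    @property
    def spont_mean(self) -> float:
        return float(self.spont_rates.mean())

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)


def level_db(a_mw: float, a0_mw: float) -> float:
    """Stimulus level in dB re the evoked-potential threshold flux."""
    a_mw = np.asarray(a_mw, dtype=float)
    if np.any(a_mw <= 0) or a0_mw <= 0:
        raise ValueError("radiant flux values must be positive")
    return 10.0 * np.log10(a_mw / a0_mw)


def db_to_power(level: float, a0_mw: float) -> float:
    """Inverse of :func:`level_db`."""
    return a0_mw * 10.0 ** (np.asarray(level, dtype=float) / 10.0)


def adapted_rates_per_trial(
    rec: SpikeRecording, window: tuple[float, float] = ADAPTED_WINDOW_MS
) -> np.ndarray:
    """Per-trial adapted (plateau) discharge rate in spikes/s."""
    t0, t1 = window
    stim = rec.stimulus
    if stim is not None and getattr(stim, "train_len", t1) < t1:
        raise ValueError("train shorter than the adapted-rate window")
    dur_s = (t1 - t0) / 1000.0
    return np.array([
        (np.searchsorted(rec.trials[t], t1) - np.searchsorted(rec.trials[t], t0)) / dur_s
        for t in sorted(rec.trials)
    ])


def adapted_rate(rec: SpikeRecording, window: tuple[float, float] = ADAPTED_WINDOW_MS) -> float:
    """Mean adapted rate across trials (spikes/s)."""
    return float(adapted_rates_per_trial(rec, window).mean())


def classify_rlf(rlf: RateLevelFunction) -> str:
    """Label the RLF: non-responding, saturating or non-saturating.

    Responding requires the top-level rate to exceed the spontaneous rate
    by 10 spikes/s; responding RLFs saturate when the slope between the two
    highest levels is <= 3 spikes/s per dB.
    """
    if rlf.n_levels < 2:
        raise ValueError("at least two levels are required")
    rates = rlf.mean_rates
    if rates[-1] < rlf.spont_mean + RESPONDING_MARGIN:
        return "non-responding"
    slope = (rates[-1] - rates[-2]) / (rlf.levels[-1] - rlf.levels[-2])
    return "saturating" if slope <= SATURATION_SLOPE else "non-saturating"


def dprime(driven: np.ndarray, reference: np.ndarray) -> float:
    """Pooled-variance sensitivity index (mu1-mu0)/sqrt((s1^2+s0^2)/2)."""
    driven = np.asarray(driven, dtype=float)
    reference = np.asarray(reference, dtype=float)
    pooled = (driven.var(ddof=1) + reference.var(ddof=1)) / 2.0
    if pooled == 0:
        return float("inf") if driven.mean() != reference.mean() else 0.0
    return float((driven.mean() - reference.mean()) / np.sqrt(pooled))


def dprime_threshold(
    rlf: RateLevelFunction, criterion: float = 1.0, step_db: float = DPRIME_STEP_DB
) -> float | None:
    """Detection threshold: lowest interpolated level with d' >= criterion.

    d' is computed at each measured level against the spontaneous reference,
    linearly interpolated on a ``step_db`` grid between the lowest and
    highest measured levels.  Returns ``None`` when no grid level reaches
    the criterion; raises when the lowest measured level is already above
    criterion (no sub-threshold measurement, so the crossing is unknown).
    """
    if rlf.n_levels < 2:
        raise ValueError("at least two levels are required")
    d = np.array([dprime(r, rlf.spont_rates) for r in rlf.trial_rates])
    if d[0] >= criterion:
        raise ValueError(
            "no sub-threshold level was measured: threshold undefined"
        )
    grid = np.arange(rlf.levels[0], rlf.levels[-1] + step_db / 2.0, step_db)
    d_interp = np.interp(grid, rlf.levels, d)
    above = np.nonzero(d_interp >= criterion)[0]
    if above.size == 0:
        return None
    return float(grid[above[0]])


def _logistic(x, floor, span, midpoint, slope):
    return floor + span / (1.0 + np.exp(-(x - midpoint) / slope))


def dynamic_range(
    rlf: RateLevelFunction,
    criterion: float = 0.95,
    threshold_db: float | None = None,
) -> tuple[float, float]:
    """Dynamic range (dB) and driven rate (spikes/s) of a responding RLF.

    Saturating RLFs are fitted with a 4-parameter logistic; the upper point
    is the level where the fitted curve reaches ``criterion`` of its fitted
    maximum (95% by default; 0.99 is the documented alternative).
    Non-saturating RLFs use the highest tested level as the upper point.
    Returns ``(level span, rate difference)`` between threshold and the
    upper point.
    """
    label = rlf.class_label or classify_rlf(rlf)
    if label == "non-responding":
        raise ValueError("dynamic range is undefined for non-responding RLFs")
    if threshold_db is None:
        threshold_db = rlf.threshold_db
    if threshold_db is None:
        threshold_db = dprime_threshold(rlf)
    if threshold_db is None:
        raise ValueError("threshold undefined: cannot measure the dynamic range")

    levels, rates = rlf.levels, rlf.mean_rates
    if label == "saturating":
        span0 = max(rates.max() - rates.min(), 1e-6)
        p0 = [rates.min(), span0, levels[np.argmin(np.abs(rates - (rates.min() + span0 / 2)))], 1.0]
        try:
            popt, _ = curve_fit(
                _logistic, levels, rates, p0=p0,
                bounds=([-np.inf, 1e-9, levels[0] - 30, 1e-3],
                        [np.inf, np.inf, levels[-1] + 30, 50.0]),
                maxfev=20000,
            )
        except RuntimeError as err:
            raise RuntimeError(f"logistic fit did not converge: {err}") from err
        floor, span, midpoint, slope = popt
        fitted_max = floor + span
        target = criterion * fitted_max
        # closed-form inversion of the logistic at the criterion rate
        frac = (target - floor) / span
        if not (0.0 < frac < 1.0):
            raise RuntimeError("criterion rate lies outside the fitted span")
        upper_level = midpoint + slope * np.log(frac / (1.0 - frac))
        upper_rate = target
        rate_at_thr = _logistic(threshold_db, *popt)
        rlf.fit_params = {
            "floor": float(floor), "span": float(span),
            "midpoint": float(midpoint), "slope": float(slope),
        }
    else:
        upper_level = float(levels[-1])
        upper_rate = float(rates[-1])
        rate_at_thr = float(np.interp(threshold_db, levels, rates))
    dr = float(upper_level - threshold_db)
    driven = float(max(upper_rate - rate_at_thr, 0.0))
    rlf.threshold_db = float(threshold_db)
    rlf.dynamic_range_db = dr
    rlf.driven_rate = driven
    rlf.class_label = label
    return dr, driven
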