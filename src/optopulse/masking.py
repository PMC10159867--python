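"""Forward-masking analysis: recovery of spike probability after a masker.

A high-rate pulse burst (the masker) depresses excitability; a single
probe pulse presented at increasing masker-probe intervals traces the
recovery.  The probe spike probability, normalized to the longest
interval, is fitted with the saturating exponential

    y(dt) = max(0, a * (1 - exp(-(k + dt) / b)))

whose zero crossing -k is the absolute recovery time and whose 95% point
-k + 3b (1 - e^-3 = 0.9502) is the relative recovery time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .metrics import RESPONSE_WINDOW_MS, adaptation_ratio, discharge_rate, response_spans
from .synth import SpikeRecording

__all__ = [
    "RecoveryFit",
    "recovery_model",
    "classify_masker_adaptation",
    "probe_probabilities",
    "recovery_curve",
    "fit_recovery",
]

ADAPTED_RATIO_MAX = 1.8  # non-adapted requires adaptation ratio <= 1.8 ...
ADAPTED_RATE_MIN = 100.0  # ... and discharge rate >= 100 spikes/s


@dataclass
class RecoveryFit:
    intervals: np.ndarray  # ms
    p_norm: np.ndarray
    a: float  # asymptote
    k: float  # offset (ms); y = 0 at dt = -k
    b: float  # time constant (ms)
    rmse: float

    @property
    def t_abs(self) -> float:
        """Absolute recovery time: interval at which any firing returns."""
        return -self.k

    @property
    def t_rel(self) -> float:
        """Relative recovery time: interval recovering 95% of the asymptote."""
        return -self.k + 3.0 * self.b

    def __call__(self, dt) -> np.ndarray:
        return recovery_model(np.asarray(dt, dtype=float), self.a, self.k, self.b)


def recovery_model(dt, a, k, b):
    # clip the exponent: deeply negative (k + dt)/b would overflow, and the
    # outer max(0, .) discards those values anyway
    z = np.clip(-(np.asarray(dt, dtype=float) + k) / b, None, 50.0)
    return np.maximum(0.0, a * (1.0 - np.exp(z)))


def classify_masker_adaptation(
    rec_masker: SpikeRecording | None = None,
    adaptation: float | None = None,
    rate: float | None = None,
    train_len: float = 400.0,
) -> str:
    """Classify the masker response as ``adapted`` or ``non-adapted``.

    Non-adapted requires both a low adaptation ratio (<= 1.8) and a
    sustained discharge rate (>= 100 spikes/s); anything else, including a
    silent response, counts as adapted.
    """
    if rec_masker is not None:
        adaptation = adaptation_ratio(rec_masker, full_ms=train_len)
        rate = discharge_rate(rec_masker, 0.0, train_len)
    if adaptation is None or rate is None:
        raise ValueError("provide a recording or both adaptation and rate")
    if np.isnan(adaptation):
        return "adapted"
    if adaptation <= ADAPTED_RATIO_MAX and rate >= ADAPTED_RATE_MIN:
        return "non-adapted"
    return "adapted"


def probe_probabilities(
    recs_by_interval: dict,
    probe_onsets: dict,
    window_ms: float = RESPONSE_WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw probe spike probability per masker-probe interval.

    ``recs_by_interval`` maps interval (ms) to the recording of that
    condition; ``probe_onsets`` maps interval to the probe pulse onset.
    The probability is the fraction of trials with at least one spike in
    the probe response span.
    """
    intervals = np.array(sorted(recs_by_interval), dtype=float)
    probs = []
    for iv in intervals:
        rec = recs_by_interval[iv]
        onset = probe_onsets[iv]
        hit = 0
        for t in rec.trials:
            spikes = rec.trials[t]
            if np.searchsorted(spikes, onset + window_ms) > np.searchsorted(spikes, onset):
                hit += 1
        probs.append(hit / max(rec.n_trials, 1))
    return intervals, np.array(probs)


def recovery_curve(
    recs_by_interval: dict,
    probe_onsets: dict,
    window_ms: float = RESPONSE_WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized recovery curve: probe probability / longest-interval value."""
    intervals, probs = probe_probabilities(recs_by_interval, probe_onsets, window_ms)
    if intervals.size < 2:
        raise ValueError("at least two intervals are required")
    ref = probs[-1]
    if ref <= 0:
        raise ValueError("no response at the longest interval: normalization undefined")
    return intervals, probs / ref


def fit_recovery(
    intervals: np.ndarray,
    p_norm: np.ndarray,
    b_inits: tuple = (5.0, 15.0, 40.0, 100.0, 250.0),
) -> RecoveryFit:
    """Least-squares fit of the saturating-exponential recovery model.

    Multistarted over several time-constant initializations to dodge local
    minima; bounds a in (0, 1.5], b in (0, 500] ms.
    """
    intervals = np.asarray(intervals, dtype=float)
    p_norm = np.asarray(p_norm, dtype=float)
    if intervals.size < 4:
        raise ValueError("at least four intervals are required for the fit")
    order = np.argsort(intervals)
    intervals, p_norm = intervals[order], p_norm[order]

    def resid(theta):
        return recovery_model(intervals, *theta) - p_norm

    best = None
    for b0 in b_inits:
        x0 = [max(p_norm.max(), 0.5), -intervals[0] + b0 / 10.0, b0]
        try:
            sol = least_squares(
                resid, x0,
                bounds=([1e-6, -1000.0, 1e-6], [1.5, 1000.0, 500.0]),
                max_nfev=20000,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        raise RuntimeError("recovery fit did not converge")
    a, k, b = best.x
    if b <= 0:
        raise RuntimeError(f"degenerate recovery fit: b = {b}")
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return RecoveryFit(intervals=intervals, p_norm=p_norm, a=float(a), k=float(k),
                       b=float(b), rmse=rmse)
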