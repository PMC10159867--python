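"""Analysis of semi-stochastic recordings.

The semi-stochastic schedule interleaves every (repetition rate, pulse
duration) combination in random order, so a single acquisition yields a
grid of per-condition spike statistics.  The response window is located by
a spike-triggered average, metrics are tabulated per combo or per
(inter-stimulus dark time, duration) condition, and units are clustered on
their per-condition spike counts with PCA + k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .stimuli import ConditionKey, SemiStochasticProtocol
from .synth import SpikeRecording

__all__ = [
    "ConditionGrid",
    "UnitClustering",
    "sta_window",
    "condition_metrics",
    "iteration_sufficiency",
    "duration_threshold",
    "cluster_units",
    "STA_WINDOW_MS",
]

STA_WINDOW_MS = 3.0


@dataclass
class ConditionGrid:
    """Per-condition spike statistics for one unit."""

    mode: str  # "combo" | "isi"
    unit_id: str
    keys: list  # list[ConditionKey]
    spikes_per_pulse: np.ndarray
    fsl: np.ndarray
    fsl_jitter: np.ndarray
    n_presentations: np.ndarray
    window_offset: float = 0.0
    window_width: float = STA_WINDOW_MS

    def as_dict(self) -> dict:
        return {k: v for k, v in zip(self.keys, self.spikes_per_pulse)}

    def value(self, key: ConditionKey) -> float:
        return float(self.spikes_per_pulse[self.keys.index(key)])


@dataclass
class UnitClustering:
    pc_scores: np.ndarray
    variance_explained: np.ndarray
    labels: np.ndarray
    unit_ids: list
    inertia: float
    meta: dict = field(default_factory=dict)


def _pulse_table(protocol: SemiStochasticProtocol, include_fm: bool = False):
    """(iteration, onset, duration, rate, condition_id) for analysis pulses."""
    rows = []
    for it, pulses in enumerate(protocol.schedule):
        for p in pulses:
            if not include_fm and p.condition_id.startswith("fm_"):
                continue
            rows.append(p)
    return rows


def sta_window(
    rec: SpikeRecording,
    protocol: SemiStochasticProtocol,
    width: float = STA_WINDOW_MS,
    max_lag: float = 10.0,
    bin_ms: float = 0.05,
    min_spikes: int = 50,
    default_offset: float = 1.0,
) -> float:
    """Locate the response window by spike-triggered averaging.

    Builds the histogram of spike lags from the preceding pulse onset and
    returns the window start offset (ms) that maximizes the spike mass
    captured by a ``width``-long window.  With fewer than ``min_spikes``
    spikes a warning is issued and ``default_offset`` is returned.
    """
    lags = []
    for it, pulses in enumerate(protocol.schedule):
        onsets = np.array([p.onset for p in pulses])
        spikes = rec.trials.get(it)
        if spikes is None or spikes.size == 0:
            continue
        idx = np.searchsorted(onsets, spikes, side="right") - 1
        ok = idx >= 0
        lag = spikes[ok] - onsets[idx[ok]]
        lags.append(lag[lag < max_lag])
    lags = np.concatenate(lags) if lags else np.empty(0)
    if lags.size < min_spikes:
        warnings.warn(
            f"only {lags.size} spikes available for the spike-triggered average; "
            f"falling back to a {default_offset} ms window offset"
        )
        return default_offset
    hist, edges = np.histogram(lags, bins=np.arange(0.0, max_lag + bin_ms, bin_ms))
    w = int(round(width / bin_ms))
    mass = np.convolve(hist, np.ones(w), mode="valid")
    return float(edges[int(np.argmax(mass))])


def condition_metrics(
    rec: SpikeRecording,
    protocol: SemiStochasticProtocol,
    mode: str = "combo",
    window_offset: float | None = None,
    width: float = STA_WINDOW_MS,
    round_ndigits: int = 6,
) -> ConditionGrid:
    """Per-condition spike statistics inside the STA-derived window.

    ``mode="combo"`` keys conditions by (rate, duration); ``mode="isi"``
    keys them by (dark time before the pulse, duration), skipping each
    iteration's first pulse and the forward-masking insert.
    """
    if mode not in ("combo", "isi"):
        raise ValueError(f"unknown mode {mode!r}")
    if window_offset is None:
        window_offset = sta_window(rec, protocol, width)

    counts: dict[ConditionKey, list] = {}
    firsts: dict[ConditionKey, list] = {}

    for it, pulses in enumerate(protocol.schedule):
        spikes = rec.trials.get(it, np.empty(0))
        analysis = [p for p in pulses if not p.condition_id.startswith("fm_")]
        if mode == "combo":
            items = [
                (p, ConditionKey(mode="combo", rate=p.rate,
                                 duration=round(p.duration, round_ndigits)))
                for p in analysis if p.condition_id.startswith("combo:")
            ]
        else:
            items = []
            for prev, cur in zip(analysis[:-1], analysis[1:]):
                dark = cur.onset - (prev.onset + prev.duration)
                items.append(
                    (cur, ConditionKey(mode="isi",
                                       dark_time=round(dark, round_ndigits),
                                       duration=round(cur.duration, round_ndigits)))
                )
        for p, key in items:
            t0 = p.onset + window_offset
            t1 = t0 + width
            lo = np.searchsorted(spikes, t0)
            hi = np.searchsorted(spikes, t1)
            counts.setdefault(key, []).append(hi - lo)
            if hi > lo:
                firsts.setdefault(key, []).append(spikes[lo] - p.onset)

    keys = sorted(counts, key=lambda k: (k.rate or 0, k.dark_time or 0, k.duration))
    spp = np.array([np.mean(counts[k]) for k in keys])
    npres = np.array([len(counts[k]) for k in keys])
    fsl = np.array([np.mean(firsts[k]) if k in firsts else np.nan for k in keys])
    jit = np.array([
        np.std(firsts[k], ddof=1) if k in firsts and len(firsts[k]) > 1 else np.nan
        for k in keys
    ])
    return ConditionGrid(
        mode=mode, unit_id=rec.unit_id, keys=keys, spikes_per_pulse=spp,
        fsl=fsl, fsl_jitter=jit, n_presentations=npres,
        window_offset=window_offset, window_width=width)


def _grid_from_iterations(rec, protocol, n, window_offset, width):
    sub = SpikeRecording(
        unit_id=rec.unit_id,
        trials={t: rec.trials[t] for t in range(n)},
        stimulus=protocol,
        unit_class=rec.unit_class,
    )
    sub_protocol = _truncate_protocol(protocol, n)
    return condition_metrics(sub, sub_protocol, mode="combo",
                             window_offset=window_offset, width=width)


def _truncate_protocol(protocol: SemiStochasticProtocol, n: int) -> SemiStochasticProtocol:
    from dataclasses import replace

    return replace(protocol, n_iterations=n, schedule=protocol.schedule[:n],
                   iteration_len=protocol.iteration_len[:n])


def iteration_sufficiency(
    rec: SpikeRecording,
    protocol: SemiStochasticProtocol,
    tolerance: float = 0.05,
    window_offset: float | None = None,
    width: float = STA_WINDOW_MS,
    n_min: int = 2,
) -> tuple[int, bool]:
    """Smallest iteration count whose grid matches the full-data grid.

    Recomputes the combo grid from the first n iterations and reports the
    smallest n whose per-condition spikes/pulse deviates from the full-data
    value by at most ``tolerance`` everywhere.  Returns ``(n, stabilized)``;
    when no n satisfies the tolerance the full count is returned with
    ``stabilized=False``.
    """
    n_total = protocol.n_iterations
    if window_offset is None:
        window_offset = sta_window(rec, protocol, width)
    full = condition_metrics(rec, protocol, mode="combo",
                             window_offset=window_offset, width=width)
    ref = full.as_dict()
    # n = n_total trivially matches the reference, so it never counts as
    # evidence of stability
    for n in range(n_min, n_total):
        grid = _grid_from_iterations(rec, protocol, n, window_offset, width)
        dev = max(
            abs(v - ref[k]) for k, v in zip(grid.keys, grid.spikes_per_pulse)
        )
        if dev <= tolerance:
            return n, True
    return n_total, False


def duration_threshold(
    grid: ConditionGrid,
    criterion: float = 0.1,
) -> tuple[dict, float | None]:
    """Per-rate pulse-duration threshold and its regression slope on rate.

    The threshold at each rate is the shortest duration where the linear
    interpolant of spikes/pulse vs duration reaches ``criterion`` (0.1
    spikes per pulse by default); rates that never reach it get ``None``.
    The second return value is the OLS slope of threshold vs rate
    (ms per pps), or ``None`` with fewer than two defined thresholds.
    """
    if grid.mode != "combo":
        raise ValueError("duration thresholds require a combo-mode grid")
    rates = sorted({k.rate for k in grid.keys})
    thresholds: dict = {}
    for rate in rates:
        pairs = sorted(
            (k.duration, s) for k, s in zip(grid.keys, grid.spikes_per_pulse)
            if k.rate == rate
        )
        durs = np.array([p[0] for p in pairs])
        spp = np.array([p[1] for p in pairs])
        thr = None
        for i in range(durs.size):
            if spp[i] >= criterion:
                if i == 0:
                    thr = float(durs[0])
                else:
                    # linear interpolation between the bracketing durations
                    f = (criterion - spp[i - 1]) / (spp[i] - spp[i - 1])
                    thr = float(durs[i - 1] + f * (durs[i] - durs[i - 1]))
                break
        thresholds[rate] = thr
    defined = [(r, t) for r, t in thresholds.items() if t is not None]
    slope = None
    if len(defined) >= 2:
        x = np.array([r for r, _ in defined])
        y = np.array([t for _, t in defined])
        slope = float(np.polyfit(x, y, 1)[0])
    return thresholds, slope


def cluster_units(
    features: np.ndarray,
    unit_ids: list | None = None,
    n_components: int = 2,
    k: int = 3,
    seed: int | None = None,
    n_restarts: int = 50,
) -> UnitClustering:
    """PCA + seeded k-means clustering of units on per-condition spike counts.

    ``features`` is units x conditions (spikes per pulse); features are
    mean-centered (they share units, so no per-feature standardization),
    projected on the first ``n_components`` principal components, and
    clustered with k-means using ``n_restarts`` initializations.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a units x conditions matrix")
    n_units = features.shape[0]
    if k > n_units:
        raise ValueError("more clusters than units")
    if seed is None:
        raise ValueError("a seed is required")
    if np.any(np.isnan(features)):
        col_means = np.nanmean(features, axis=0)
        idx = np.where(np.isnan(features))
        features = features.copy()
        features[idx] = np.take(col_means, idx[1])
        warnings.warn("missing condition values were mean-imputed")

    n_components = min(n_components, n_units - 1, features.shape[1])
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(features)
    total_var = features.var(axis=0, ddof=1).sum()
    unstable = total_var <= 1e-12
    if unstable:
        warnings.warn("degenerate feature matrix: clustering is unstable")
        var_explained = np.zeros(n_components)
    else:
        var_explained = pca.explained_variance_ratio_
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(scores)
    return UnitClustering(
        pc_scores=scores,
        variance_explained=var_explained,
        labels=labels,
        unit_ids=unit_ids if unit_ids is not None else list(range(n_units)),
        inertia=float(km.inertia_),
        meta={"k": k, "n_components": n_components, "seed": seed,
              "unstable": bool(unstable)},
    )
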