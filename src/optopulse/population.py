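"""Population-level statistics: bootstrap neurograms, neural-gain maps and
the gain-vs-jitter correlation restricted to iso-rate regions of interest.

The population raster is built by drawing one whole trial (iteration) per
unit; pooled first-spike latencies therefore mix within-unit trial jitter
with across-unit latency spread, so the population jitter squared
approaches sigma_w^2 + sigma_L^2 (law of total variance).  Neural gain is
the per-condition difference in spikes/stimulus between a downstream
(AVCN) population and its (SGN) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import RESPONSE_WINDOW_MS, response_spans
from .stimuli import ConditionKey, PulseTrain
from .synth import SpikeRecording

__all__ = [
    "PopulationStats",
    "GainMap",
    "population_bootstrap",
    "population_condition_stats",
    "neural_gain",
    "select_iso_rate_band",
    "gain_jitter_correlation",
    "DEFAULT_ROIS",
]

#: spikes/stimulus bands where rate is matched but jitter varies
DEFAULT_ROIS = ((0.0, 0.26), (0.65, 0.73))


@dataclass
class PopulationStats:
    n_boot: int
    spikes_per_stimulus: np.ndarray  # per bootstrap
    fsl: np.ndarray
    fsl_jitter: np.ndarray

    def summary(self) -> dict:
        out = {}
        for name in ("spikes_per_stimulus", "fsl", "fsl_jitter"):
            v = getattr(self, name)
            mean = float(np.nanmean(v))
            half = 1.96 * float(np.nanstd(v, ddof=1)) / np.sqrt(len(v))
            out[name] = (mean, half)
        return out


@dataclass
class GainMap:
    keys: list  # common ConditionKeys
    gain: np.ndarray  # AVCN - SGN spikes/stimulus
    jitter_change: np.ndarray  # AVCN - SGN first-spike jitter
    threshold: float = 0.1
    sgn_spikes: np.ndarray | None = None
    avcn_spikes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def frac_gain(self) -> float:
        """Fraction of conditions with gain >= +threshold."""
        return float(np.mean(self.gain >= self.threshold))

    @property
    def frac_loss(self) -> float:
        """Fraction of conditions with gain <= -threshold."""
        return float(np.mean(self.gain <= -self.threshold))


def _pooled_metrics(
    spikes_per_unit: list,
    onsets: np.ndarray,
    window_ms: float,
) -> tuple[float, float, float]:
    """Per-fiber spikes/stimulus plus pooled first-spike mean and jitter."""
    spans = response_spans(onsets, window_ms)
    total = 0
    firsts = []
    for spikes in spikes_per_unit:
        lo = np.searchsorted(spikes, spans[:, 0])
        hi = np.searchsorted(spikes, spans[:, 1])
        total += int((hi - lo).sum())
        hit = lo < hi
        firsts.append(spikes[lo[hit]] - spans[hit, 0])
    firsts = np.concatenate(firsts) if firsts else np.empty(0)
    spp = total / (onsets.size * len(spikes_per_unit))
    fsl = float(np.mean(firsts)) if firsts.size else float("nan")
    jit = float(np.std(firsts, ddof=1)) if firsts.size > 1 else float("nan")
    return spp, fsl, jit


def population_bootstrap(
    recs: list,
    n_boot: int = 50,
    seed: int | None = None,
    window_ms: float = RESPONSE_WINDOW_MS,
    onsets: np.ndarray | None = None,
) -> PopulationStats:
    """Bootstrap the population response: one random trial per unit per draw.

    Each bootstrap builds a pseudo-population raster from one randomly
    chosen trial of every unit and computes the per-fiber spikes/stimulus,
    the pooled first-spike latency and the pooled latency jitter; sampling
    is with replacement across bootstraps.
    """
    if len(recs) < 2:
        raise ValueError("at least two units are required")
    if seed is None:
        raise ValueError("a seed is required")
    if onsets is None:
        stim = recs[0].stimulus
        if not isinstance(stim, PulseTrain):
            raise ValueError("pass onsets explicitly for non-train stimuli")
        if any(rec.stimulus is not stim for rec in recs):
            raise ValueError("all recordings must share the stimulus")
        onsets = stim.onsets
    rng = np.random.default_rng(seed)
    spp = np.empty(n_boot)
    fsl = np.empty(n_boot)
    jit = np.empty(n_boot)
    for b in range(n_boot):
        draw = [rec.trials[rng.integers(rec.n_trials)] for rec in recs]
        spp[b], fsl[b], jit[b] = _pooled_metrics(draw, onsets, window_ms)
    return PopulationStats(n_boot=n_boot, spikes_per_stimulus=spp, fsl=fsl,
                           fsl_jitter=jit)


def population_condition_stats(
    recs: list,
    protocol,
    mode: str = "isi",
    window_offset: float | None = None,
    width: float = 3.0,
) -> dict:
    """Pooled per-condition spikes/stimulus, latency and jitter across units.

    For every condition key of the semi-stochastic protocol, pools the
    response spans of all units and all iterations: spikes/stimulus is the
    per-fiber average count, and the jitter is the SD of the pooled
    first-spike latencies across units.  Returns
    ``{key: (spikes_per_stimulus, fsl, fsl_jitter, n)}``.
    """
    from .stochastic import condition_metrics, sta_window

    if window_offset is None:
        window_offset = sta_window(recs[0], protocol, width)

    counts: dict = {}
    firsts: dict = {}
    n_units = len(recs)
    for rec in recs:
        for it, pulses in enumerate(protocol.schedule):
            spikes = rec.trials.get(it, np.empty(0))
            analysis = [p for p in pulses if not p.condition_id.startswith("fm_")]
            if mode == "combo":
                items = [
                    (p, ConditionKey(mode="combo", rate=p.rate,
                                     duration=round(p.duration, 6)))
                    for p in analysis if p.condition_id.startswith("combo:")
                ]
            else:
                items = [
                    (cur, ConditionKey(mode="isi",
                                       dark_time=round(cur.onset - prev.onset - prev.duration, 6),
                                       duration=round(cur.duration, 6)))
                    for prev, cur in zip(analysis[:-1], analysis[1:])
                ]
            for p, key in items:
                t0 = p.onset + window_offset
                lo = np.searchsorted(spikes, t0)
                hi = np.searchsorted(spikes, t0 + width)
                counts.setdefault(key, []).append(hi - lo)
                if hi > lo:
                    firsts.setdefault(key, []).append(spikes[lo] - p.onset)

    out = {}
    for key, c in counts.items():
        f = np.asarray(firsts.get(key, []), dtype=float)
        spp = float(np.sum(c)) / len(c)  # pooled count per presentation per fiber
        fsl = float(f.mean()) if f.size else float("nan")
        jit = float(f.std(ddof=1)) if f.size > 1 else float("nan")
        out[key] = (spp, fsl, jit, len(c) // n_units)
    return out


def neural_gain(
    sgn_stats: dict,
    avcn_stats: dict,
    threshold: float = 0.1,
    response_contour: float = 0.2,
) -> GainMap:
    """Per-condition neural gain between an SGN and an AVCN population.

    Both arguments map ConditionKey to ``(spikes_per_stimulus, fsl,
    fsl_jitter, n)`` as produced by :func:`population_condition_stats`.
    Only keys present in both maps enter; disjoint grids raise.
    """
    common = [k for k in sgn_stats if k in avcn_stats]
    if not common:
        raise ValueError("the two grids share no condition keys")
    common.sort(key=lambda k: (k.rate or 0, k.dark_time or 0, k.duration))
    sgn = np.array([sgn_stats[k][0] for k in common])
    avcn = np.array([avcn_stats[k][0] for k in common])
    jit_s = np.array([sgn_stats[k][2] for k in common])
    jit_a = np.array([avcn_stats[k][2] for k in common])
    return GainMap(
        keys=common,
        gain=avcn - sgn,
        jitter_change=jit_a - jit_s,
        threshold=threshold,
        sgn_spikes=sgn,
        avcn_spikes=avcn,
        meta={"response_contour": response_contour,
              "sgn_above_contour": float(np.mean(sgn >= response_contour)),
              "avcn_above_contour": float(np.mean(avcn >= response_contour))},
    )


def select_iso_rate_band(
    spikes_per_stimulus: np.ndarray,
    jitter: np.ndarray,
    width: float = 0.15,
    min_n: int = 35,
    above_median: bool = True,
    step: float = 0.01,
) -> tuple[float, float]:
    """Pick a rate band where rate is matched but jitter varies the most.

    Slides a window of ``width`` spikes/stimulus over the observed range
    (above the median rate by default) and returns the band maximizing the
    interquartile range of the jitter among bands holding at least
    ``min_n`` conditions.  This is the data-driven rule for defining a
    region of interest when the default absolute bounds do not fit a
    dataset's rate distribution.
    """
    spp = np.asarray(spikes_per_stimulus, dtype=float)
    jit = np.asarray(jitter, dtype=float)
    ok = np.isfinite(jit) & np.isfinite(spp)
    start = float(np.median(spp[ok])) if above_median else 0.0
    best, best_spread = None, -np.inf
    for lo in np.arange(start, spp[ok].max() - width + 1e-9, step):
        sel = ok & (spp >= lo) & (spp <= lo + width)
        if sel.sum() < min_n:
            continue
        spread = float(np.subtract(*np.percentile(jit[sel], [75, 25])))
        if spread > best_spread:
            best_spread, best = spread, (float(lo), float(lo + width))
    if best is None:
        best = (start, start + width)
    return best


def gain_jitter_correlation(
    gain_map: GainMap,
    jitter: np.ndarray | None = None,
    roi: tuple[float, float] = DEFAULT_ROIS[0],
) -> dict:
    """Correlate neural gain with population first-spike jitter inside a ROI.

    The ROI restricts conditions to a band of SGN population
    spikes/stimulus so that rate is matched while jitter varies.  Returns
    Pearson R, its two-sided p-value and the least-squares line.
    """
    if gain_map.sgn_spikes is None:
        raise ValueError("gain map lacks the SGN spike rates needed for the ROI")
    if jitter is None:
        raise ValueError("per-key population jitter values are required")
    jitter = np.asarray(jitter, dtype=float)
    lo, hi = roi
    sel = (gain_map.sgn_spikes >= lo) & (gain_map.sgn_spikes <= hi) & np.isfinite(jitter)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 conditions fall in ROI {roi}")
    x = jitter[sel]
    y = gain_map.gain[sel]
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": float(r), "p": float(p), "slope": float(slope),
            "intercept": float(intercept), "n": int(sel.sum()), "roi": roi}
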