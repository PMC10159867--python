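"""Per-unit spike-train statistics and minimal evoked-potential analysis.

Conventions: each stimulus pulse owns the response span starting at its
onset and lasting ``window_ms`` (default 10 ms), truncated at the next
pulse onset when the repetition period is shorter than the window so that
no spike is counted twice.  First-spike statistics pool the first spike of
every pulse x trial span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .stimuli import PulseTrain
from .synth import SpikeRecording

__all__ = [
    "UnitMetrics",
    "response_spans",
    "spikes_per_stimulus",
    "first_spike_latencies",
    "first_spike_stats",
    "adaptation_ratio",
    "spontaneous_rate",
    "classify_unit",
    "abr_wave1",
    "unit_metrics",
    "RESPONSE_WINDOW_MS",
    "NO_RESPONSE_SPIKES_PER_STIM",
]

#: response span following each pulse (ms)
RESPONSE_WINDOW_MS = 10.0
#: units below this evoked rate in every condition are flagged unresponsive
NO_RESPONSE_SPIKES_PER_STIM = 0.3


@dataclass
class UnitMetrics:
    spikes_per_stimulus: float
    fsl: float
    fsl_jitter: float
    adaptation_ratio: float
    discharge_rate: float  # spikes/s over the whole train
    spont_rate: float | None = None

    @property
    def responsive(self) -> bool:
        return self.spikes_per_stimulus >= NO_RESPONSE_SPIKES_PER_STIM


def response_spans(onsets: np.ndarray, window_ms: float = RESPONSE_WINDOW_MS,
                   limit: float | None = None) -> np.ndarray:
    """(start, end) response span per pulse; spans never reach the next onset."""
    onsets = np.asarray(onsets, dtype=float)
    ends = onsets + window_ms
    if onsets.size > 1:
        ends[:-1] = np.minimum(ends[:-1], onsets[1:])
    if limit is not None:
        ends[-1] = min(ends[-1], limit)
    return np.column_stack([onsets, ends])


def _per_span_counts(spikes: np.ndarray, spans: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(spikes, spans[:, 0], side="left")
    hi = np.searchsorted(spikes, spans[:, 1], side="left")
    return hi - lo


def spikes_per_stimulus(
    rec: SpikeRecording,
    window_ms: float = RESPONSE_WINDOW_MS,
    onsets: np.ndarray | None = None,
) -> float:
    """Mean evoked spike count per pulse over all pulses and trials."""
    if onsets is None:
        onsets = _stimulus_onsets(rec)
    if onsets.size == 0:
        raise ValueError("stimulus has no pulses")
    spans = response_spans(onsets, window_ms)
    if not rec.trials:
        return 0.0
    total = sum(int(_per_span_counts(rec.trials[t], spans).sum()) for t in rec.trials)
    return total / (onsets.size * len(rec.trials))


def first_spike_latencies(
    rec: SpikeRecording,
    window_ms: float = RESPONSE_WINDOW_MS,
    onsets: np.ndarray | None = None,
) -> np.ndarray:
    """Latency of the first spike in every responding pulse x trial span."""
    if onsets is None:
        onsets = _stimulus_onsets(rec)
    spans = response_spans(onsets, window_ms)
    lats = []
    for t in rec.trials:
        spikes = rec.trials[t]
        lo = np.searchsorted(spikes, spans[:, 0], side="left")
        hi = np.searchsorted(spikes, spans[:, 1], side="left")
        hit = lo < hi
        lats.append(spikes[lo[hit]] - spans[hit, 0])
    return np.concatenate(lats) if lats else np.empty(0)


def first_spike_stats(
    rec: SpikeRecording,
    window_ms: float = RESPONSE_WINDOW_MS,
    onsets: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean first-spike latency and its jitter (sample SD, ddof=1).

    Returns ``(nan, nan)`` when no span contains a spike; jitter is ``nan``
    with a single observation.
    """
    lats = first_spike_latencies(rec, window_ms, onsets)
    if lats.size == 0:
        return float("nan"), float("nan")
    jitter = float(np.std(lats, ddof=1)) if lats.size > 1 else float("nan")
    return float(np.mean(lats)), jitter


def adaptation_ratio(
    rec: SpikeRecording,
    onset_ms: float = 50.0,
    full_ms: float = 400.0,
) -> float:
    """Discharge-rate ratio: first ``onset_ms`` of the train vs the whole train.

    Counts are aggregated across trials before taking the ratio; 1 means a
    time-homogeneous response, larger values mean onset-dominated firing.
    Returns ``nan`` when no spike falls inside the full window.
    """
    if full_ms <= onset_ms:
        raise ValueError("full_ms must exceed onset_ms")
    n_on = n_full = 0
    for t in rec.trials:
        spikes = rec.trials[t]
        n_on += int(np.searchsorted(spikes, onset_ms, side="left")
                    - np.searchsorted(spikes, 0.0, side="left"))
        n_full += int(np.searchsorted(spikes, full_ms, side="left")
                      - np.searchsorted(spikes, 0.0, side="left"))
    if n_full == 0:
        return float("nan")
    return (n_on / (onset_ms / 1000.0)) / (n_full / (full_ms / 1000.0))


def discharge_rate(rec: SpikeRecording, t0: float = 0.0, t1: float = 400.0) -> float:
    """Mean rate (spikes/s) in [t0, t1) across trials."""
    if t1 <= t0:
        raise ValueError("empty window")
    n = sum(
        int(np.searchsorted(rec.trials[t], t1) - np.searchsorted(rec.trials[t], t0))
        for t in rec.trials
    )
    return n / ((t1 - t0) / 1000.0) / max(len(rec.trials), 1)


def spontaneous_rate(rec: SpikeRecording, windows: list[tuple[float, float]]) -> float:
    """Spontaneous rate from dark windows: total spikes / total dark time."""
    if not windows:
        raise ValueError("no dark windows provided")
    total_time = sum((t1 - t0) for t0, t1 in windows) * len(rec.trials) / 1000.0
    if total_time <= 0:
        raise ValueError("dark windows have zero total duration")
    n = 0
    for t in rec.trials:
        spikes = rec.trials[t]
        for t0, t1 in windows:
            n += int(np.searchsorted(spikes, t1) - np.searchsorted(spikes, t0))
    return n / total_time


def classify_unit(depth_um: float, fsl_ms: float, waveform_monophasic: bool) -> str:
    """SGN vs AVCN classification from depth, first-spike latency and waveform.

    A unit is an SGN iff its depth below the cerebellar surface is >= 1000
    um, its first-spike latency is <= 3 ms and its action potential is
    monophasic and positive; otherwise it is an AVCN neuron.
    """
    if depth_um is None or fsl_ms is None or waveform_monophasic is None:
        raise ValueError("all three classification criteria are required")
    if depth_um >= 1000.0 and fsl_ms <= 3.0 and waveform_monophasic:
        return "SGN"
    return "AVCN"


def abr_wave1(
    trace: np.ndarray,
    fs: float,
    search_window_ms: tuple[float, float] = (1.0, 3.0),
    band_hz: tuple[float, float] = (300.0, 3000.0),
    order: int = 2,
) -> float:
    """P1-N1 amplitude (uV) of the first evoked-potential wave.

    The trace is band-passed with a zero-phase Butterworth filter and the
    amplitude is the max-min excursion inside the search window.
    """
    if fs < 10_000:
        raise ValueError("sampling rate must be at least 10 kHz")
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(search_window_ms[0] * fs / 1000.0))
    i1 = int(round(search_window_ms[1] * fs / 1000.0))
    if i0 < 0 or i1 > trace.size or i1 <= i0:
        raise ValueError("search window lies outside the trace")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, trace)
    seg = filt[i0:i1]
    return float(seg.max() - seg.min())


def _stimulus_onsets(rec: SpikeRecording) -> np.ndarray:
    stim = rec.stimulus
    if isinstance(stim, PulseTrain):
        return stim.onsets
    raise ValueError("recording has no pulse-train stimulus; pass onsets explicitly")


def unit_metrics(
    rec: SpikeRecording,
    window_ms: float = RESPONSE_WINDOW_MS,
    train_len: float | None = None,
    spont_windows: list[tuple[float, float]] | None = None,
) -> UnitMetrics:
    """Bundle of the standard per-unit metrics for one condition."""
    stim = rec.stimulus
    if train_len is None:
        train_len = stim.train_len if isinstance(stim, PulseTrain) else 400.0
    fsl, jitter = first_spike_stats(rec, window_ms)
    return UnitMetrics(
        spikes_per_stimulus=spikes_per_stimulus(rec, window_ms),
        fsl=fsl,
        fsl_jitter=jitter,
        adaptation_ratio=adaptation_ratio(rec, full_ms=train_len),
        discharge_rate=discharge_rate(rec, 0.0, train_len),
        spont_rate=(spontaneous_rate(rec, spont_windows) if spont_windows else None),
    )
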