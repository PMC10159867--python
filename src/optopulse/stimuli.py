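"""Stimulus construction for optogenetic and acoustic pulse-train experiments.

Three protocol families are supported:

* deterministic pulse trains (fixed repetition rate and pulse duration,
  e.g. 400 ms of light followed by 100 ms of dark),
* forward-masking sequences (a high-rate masker burst followed by a single
  probe pulse at a set of masker-probe intervals),
* a semi-stochastic schedule that interleaves every (repetition rate, pulse
  duration) combination in seeded random order so that a single acquisition
  samples the whole input/output function.

All times are in milliseconds and trial-relative; optical intensity is the
radiant flux in mW, so intensity x duration is a pulse energy in uJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PulseTrain",
    "ScheduledPulse",
    "SemiStochasticProtocol",
    "ConditionKey",
    "DutyCycleError",
    "make_pulse_train",
    "make_forward_masking",
    "make_semistochastic",
    "decompose_isi",
    "stimulus_energy",
    "DEFAULT_RATES",
    "DEFAULT_DURATIONS",
]

#: repetition rates (pps) and pulse durations (ms) of the default
#: semi-stochastic protocol: 5 x 7 = 35 combinations.
DEFAULT_RATES = (10.0, 56.0, 100.0, 179.0, 313.0)
DEFAULT_DURATIONS = (0.2, 0.4, 0.6, 0.8, 1.2, 1.6, 2.4)


class DutyCycleError(ValueError):
    """Pulse duration meets or exceeds the stimulation period.

    Mirrors the acquisition rule that no recording is made for a condition
    whose pulse cannot fit inside one period of its repetition rate.
    """


@dataclass
class PulseTrain:
    """One stimulus realization: pulse onsets and widths at one intensity.

    ``onsets`` are trial-relative (ms) and strictly increasing; each pulse
    must end before the next one starts.  ``meta`` carries protocol-specific
    annotations (e.g. the masker-probe interval of a forward-masking trial).
    """

    onsets: np.ndarray
    durations: np.ndarray
    intensity: float
    modality: str  # "optic" | "acoustic"
    train_len: float
    dark_len: float
    n_trials: int = 1
    rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.ndim == 0:
            self.durations = np.full_like(self.onsets, float(self.durations))
        if self.onsets.shape != self.durations.shape:
            raise ValueError("onsets and durations must have equal length")
        if self.modality not in ("optic", "acoustic"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if np.any(self.durations <= 0):
                raise ValueError("durations must be positive")
            offsets = self.onsets[:-1] + self.durations[:-1]
            if np.any(offsets > self.onsets[1:] + 1e-9):
                raise ValueError("pulses overlap the following onset")
            if np.any(self.onsets >= self.train_len):
                raise ValueError("all onsets must precede train_len")

    @property
    def n_pulses(self) -> int:
        return int(self.onsets.size)

    @property
    def total_len(self) -> float:
        """Train plus trailing dark/silence (ms)."""
        return self.train_len + self.dark_len


@dataclass(frozen=True)
class ScheduledPulse:
    """One pulse of a realized semi-stochastic schedule."""

    onset: float  # ms, iteration-relative
    duration: float  # ms
    rate: float  # pps of the combo (or masker) the pulse belongs to
    condition_id: str  # "combo:<rate>:<dur>" | "masker" | "fm_masker" | "fm_probe:<interval>"
    iteration: int


@dataclass(frozen=True)
class ConditionKey:
    """Analysis condition: either a (rate, duration) combo or an
    (inter-stimulus dark time, duration) pair after ISI decomposition."""

    mode: str  # "combo" | "isi"
    duration: float  # ms
    rate: float | None = None  # pps, combo mode
    dark_time: float | None = None  # ms, isi mode

    def __post_init__(self) -> None:
        if self.mode not in ("combo", "isi"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "isi" and (self.dark_time is None or self.dark_time <= 0):
            raise ValueError("isi keys require a positive dark_time")


@dataclass
class SemiStochasticProtocol:
    """Seeded randomized schedule of (rate, duration) conditions.

    Each iteration begins with a desensitizing masker, contains a random
    permutation of every combination repeated ``reps_per_iter`` times (each
    presentation occupying one period of its rate), includes one
    forward-masking insert, and ends with a dark tail.  Regeneration with
    the same seed yields an identical schedule.
    """

    rates: tuple
    durations: tuple
    reps_per_iter: int
    n_iterations: int
    seed: int
    masker_rate: float
    masker_n: int
    masker_duration: float
    fm_intervals: tuple
    fm_masker_rate: float
    fm_masker_n: int
    fm_masker_duration: float
    fm_probe_duration: float
    fm_dark: float
    tail_dark: float
    intensity: float
    modality: str
    schedule: list  # list (per iteration) of list[ScheduledPulse]
    iteration_len: list  # ms per iteration

    @property
    def combos(self) -> list:
        return [(r, d) for r in self.rates for d in self.durations]

    @property
    def n_combos(self) -> int:
        return len(self.combos)

    @property
    def total_duration_ms(self) -> float:
        return float(sum(self.iteration_len))

    def presentations_per_combo(self) -> int:
        return self.reps_per_iter * self.n_iterations

    def combo_pulses(self, iteration: int) -> list:
        """Scheduled pulses of the randomized combo block of one iteration."""
        return [p for p in self.schedule[iteration] if p.condition_id.startswith("combo:")]


def _period_ms(rate: float) -> float:
    return 1000.0 / rate


def make_pulse_train(
    rate: float,
    duration: float,
    train_len: float = 400.0,
    dark_len: float = 100.0,
    intensity: float = 35.0,
    modality: str = "optic",
    n_trials: int = 20,
) -> PulseTrain:
    """Build a constant-rate, constant-duration pulse train.

    Pulses start at k/rate for k = 0 .. floor(train_len * rate / 1000) - 1.
    Raises :class:`DutyCycleError` if the pulse duration reaches the period,
    i.e. the condition could not be acquired.
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if train_len < 0 or dark_len < 0:
        raise ValueError("train_len and dark_len must be non-negative")
    period = _period_ms(rate)
    if duration >= period:
        raise DutyCycleError(
            f"pulse duration {duration} ms >= period {period:.4g} ms at {rate} pps: "
            "no acquisition for this condition"
        )
    n = int(np.floor(train_len * rate / 1000.0 + 1e-9))
    onsets = np.arange(n) * period
    return PulseTrain(
        onsets=onsets,
        durations=np.full(n, float(duration)),
        intensity=intensity,
        modality=modality,
        train_len=train_len,
        dark_len=dark_len,
        n_trials=n_trials,
        rate=rate,
    )


def make_forward_masking(
    masker_rate: float = 316.0,
    masker_n: int = 10,
    duration: float = 1.6,
    intervals: Sequence[float] | None = None,
    trials_per_interval: int = 20,
    tail_dark: float = 200.0,
    intensity: float = 35.0,
    modality: str = "optic",
) -> list[PulseTrain]:
    """Build the forward-masking protocol: masker burst + one probe pulse.

    Returns one :class:`PulseTrain` per masker-probe interval (each with
    ``trials_per_interval`` trials); the probe onset sits one masker period
    plus the interval after the last masker onset, and the train is followed
    by ``tail_dark`` ms of dark.  The probe's interval and index are stored
    in ``meta``.
    """
    if intervals is None:
        # 20 intervals spanning 4-180 ms, log-spaced (recovery is roughly
        # exponential so log spacing samples the rising phase densely).
        intervals = np.geomspace(4.0, 180.0, 20)
    intervals = np.sort(np.asarray(intervals, dtype=float))
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    if np.any(intervals < duration):
        raise ValueError("masker-probe interval smaller than the pulse duration")
    if masker_n < 1:
        raise ValueError("masker_n must be >= 1")
    period = _period_ms(masker_rate)
    if duration >= period:
        raise DutyCycleError("masker pulse duration exceeds the masker period")

    trains = []
    masker_onsets = np.arange(masker_n) * period
    for interval in intervals:
        probe_onset = masker_onsets[-1] + period + interval
        onsets = np.append(masker_onsets, probe_onset)
        trains.append(
            PulseTrain(
                onsets=onsets,
                durations=np.full(masker_n + 1, float(duration)),
                intensity=intensity,
                modality=modality,
                train_len=probe_onset + duration,
                dark_len=tail_dark,
                n_trials=trials_per_interval,
                rate=masker_rate,
                meta={"interval_ms": float(interval), "probe_index": masker_n},
            )
        )
    return trains


def make_semistochastic(
    rates: Sequence[float] = DEFAULT_RATES,
    durations: Sequence[float] = DEFAULT_DURATIONS,
    reps_per_iter: int = 10,
    n_iterations: int = 20,
    seed: int | None = None,
    masker_rate: float = 100.0,
    masker_n: int = 10,
    masker_duration: float = 2.4,
    fm_intervals: Sequence[float] = (15.0, 80.0),
    fm_masker_rate: float = 313.0,
    fm_masker_n: int = 10,
    fm_masker_duration: float = 1.6,
    fm_probe_duration: float = 1.6,
    fm_dark: float = 200.0,
    tail_dark: float = 200.0,
    intensity: float = 35.0,
    modality: str = "optic",
) -> SemiStochasticProtocol:
    """Realize the semi-stochastic schedule.

    Each iteration is laid out as::

        masker | seeded permutation of combos x reps | forward-masking insert | dark tail

    Every combo presentation occupies exactly one period (1/rate) with its
    pulse at the slot start.  The forward-masking insert (its own masker, a
    probe after a masker-probe interval, then ``fm_dark`` of dark) is placed
    once per iteration, alternating through ``fm_intervals``.

    Randomness is drawn from per-iteration child streams of the root seed,
    so extending ``n_iterations`` never changes earlier iterations.
    """
    rates = tuple(float(r) for r in rates)
    durations = tuple(float(d) for d in durations)
    if not rates or not durations:
        raise ValueError("rates and durations must be non-empty")
    if seed is None:
        raise ValueError("a seed is required: the schedule must be reproducible")
    combos = [(r, d) for r in rates for d in durations]
    for r, d in combos:
        if d >= _period_ms(r):
            raise DutyCycleError(
                f"combo ({r} pps, {d} ms) violates the duty rule; drop it from the design"
            )
    if masker_duration >= _period_ms(masker_rate):
        raise DutyCycleError("masker pulse exceeds the masker period")

    child_seeds = np.random.SeedSequence(seed).spawn(n_iterations)
    schedule: list[list[ScheduledPulse]] = []
    iteration_len: list[float] = []
    masker_period = _period_ms(masker_rate)
    fm_period = _period_ms(fm_masker_rate)

    for it in range(n_iterations):
        rng = np.random.default_rng(child_seeds[it])
        pulses: list[ScheduledPulse] = []
        # consecutive onsets are spaced by the CURRENT pulse's period, so the
        # dark time preceding a pulse is its own period minus the previous
        # pulse's duration: the condition's repetition rate physically sets
        # the recovery time available before each of its pulses
        t = 0.0
        # desensitizing masker: masker_n pulses at the masker period
        for i in range(masker_n):
            if i > 0:
                t += masker_period
            pulses.append(ScheduledPulse(t, masker_duration, masker_rate, "masker", it))
        # randomized combo block: one presentation per slot
        order = rng.permutation(len(combos) * reps_per_iter) % len(combos)
        for idx in order:
            r, d = combos[idx]
            t += _period_ms(r)
            pulses.append(ScheduledPulse(t, d, r, f"combo:{r:g}:{d:g}", it))
        # forward-masking insert, alternating intervals across iterations
        interval = float(fm_intervals[it % len(fm_intervals)])
        for _ in range(fm_masker_n):
            t += fm_period
            pulses.append(ScheduledPulse(t, fm_masker_duration, fm_masker_rate, "fm_masker", it))
        t += fm_period + interval
        pulses.append(
            ScheduledPulse(t, fm_probe_duration, fm_masker_rate, f"fm_probe:{interval:g}", it)
        )
        t += fm_probe_duration + fm_dark
        # dark tail
        t += tail_dark
        schedule.append(pulses)
        iteration_len.append(t)

    return SemiStochasticProtocol(
        rates=rates,
        durations=durations,
        reps_per_iter=reps_per_iter,
        n_iterations=n_iterations,
        seed=seed,
        masker_rate=masker_rate,
        masker_n=masker_n,
        masker_duration=masker_duration,
        fm_intervals=tuple(float(i) for i in fm_intervals),
        fm_masker_rate=fm_masker_rate,
        fm_masker_n=fm_masker_n,
        fm_masker_duration=fm_masker_duration,
        fm_probe_duration=fm_probe_duration,
        fm_dark=fm_dark,
        tail_dark=tail_dark,
        intensity=intensity,
        modality=modality,
        schedule=schedule,
        iteration_len=iteration_len,
    )


def decompose_isi(
    protocol: SemiStochasticProtocol,
    include_fm: bool = False,
    round_ndigits: int = 6,
) -> dict[ConditionKey, int]:
    """Decompose the realized schedule into (dark time, duration) conditions.

    Every scheduled pulse except each iteration's first is assigned the key
    (dark time separating it from the preceding pulse's offset, its own
    duration); the per-key presentation counts are returned.  With onsets
    spaced by the current pulse's period the dark time is that period minus
    the preceding pulse's duration, so the default 5-rate x 7-duration
    design yields 35 distinct dark times x 7 durations = 245 conditions.

    Forward-masking-insert pulses are excluded by default: their probe gaps
    would add singleton conditions outside the combo design, and they are
    analyzed by the masking pipeline instead.
    """
    counts: dict[ConditionKey, int] = {}
    for it_pulses in protocol.schedule:
        pulses = it_pulses if include_fm else [
            p for p in it_pulses if not p.condition_id.startswith("fm_")
        ]
        for prev, cur in zip(pulses[:-1], pulses[1:]):
            dark = cur.onset - (prev.onset + prev.duration)
            if dark <= 0:
                raise ValueError("non-positive dark time in schedule")
            key = ConditionKey(
                mode="isi",
                duration=round(cur.duration, round_ndigits),
                dark_time=round(dark, round_ndigits),
            )
            counts[key] = counts.get(key, 0) + 1
    return counts


def stimulus_energy(train: PulseTrain, window: tuple[float, float] | None = None) -> float:
    """Radiant energy (uJ) delivered by pulses whose onset falls in ``window``.

    Energy = intensity (mW) x summed pulse duration (ms); only defined for
    the optic modality.
    """
    if train.modality != "optic":
        raise ValueError("stimulus energy is only defined for optical stimuli")
    if window is None:
        window = (0.0, train.train_len)
    t0, t1 = window
    sel = (train.onsets >= t0) & (train.onsets < t1)
    return float(train.intensity * train.durations[sel].sum())
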