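"""Readers, writers, run configuration, the demo pipeline and fixtures.

Spike recordings travel as plain CSV (``unit_id, trial, spike_time_ms``),
protocols as JSON, and analysis outputs as tidy CSV/JSON.  Times are
serialized at 1 us resolution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, rlf, stimuli, synth

__all__ = [
    "RunConfig",
    "write_spikes",
    "read_spikes",
    "write_protocol",
    "read_protocol",
    "schedule_frame",
    "make_fixtures",
    "run_pipeline",
]

SPIKE_COLUMNS = ["unit_id", "trial", "spike_time_ms"]


@dataclass
class RunConfig:
    """Analysis defaults; all values mirror the standard protocol constants."""

    seed: int = 0
    window_ms: float = 10.0
    adapted_window_ms: tuple = (100.0, 400.0)
    dprime_criterion: float = 1.0
    dprime_step_db: float = 0.2
    saturation_criterion: float = 0.95
    gain_threshold: float = 0.1
    response_contour: float = 0.2
    n_boot: int = 50
    roi_bounds: tuple = ((0.0, 0.26), (0.65, 0.73))
    n_sgn: int = 12
    n_avcn: int = 4
    out_dir: str = "optopulse_out"


def write_spikes(recs, path) -> None:
    """Write one or more recordings to a spike-time CSV (1 us resolution)."""
    if isinstance(recs, synth.SpikeRecording):
        recs = [recs]
    rows = []
    for rec in recs:
        for t in sorted(rec.trials):
            for s in rec.trials[t]:
                rows.append((rec.unit_id, t, round(float(s), 6)))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def read_spikes(path) -> list:
    """Read spike-time CSV into recordings (one per unit_id).

    Unsorted spike times are sorted with a warning; missing columns raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table is missing columns {missing}")
    bad = df[pd.to_numeric(df["spike_time_ms"], errors="coerce").isna()]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header and 0-base
        raise ValueError(f"malformed spike_time_ms values at lines {lines}")
    recs = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        trials = {}
        for t, tg in grp.groupby("trial"):
            vals = tg["spike_time_ms"].to_numpy(dtype=float)
            if np.any(np.diff(vals) < 0):
                warnings.warn(f"unsorted spike times for unit {unit_id!r}; sorting")
            trials[int(t)] = np.sort(vals)
        recs.append(synth.SpikeRecording(unit_id=str(unit_id), trials=trials))
    return recs


def write_protocol(protocol: stimuli.SemiStochasticProtocol, path) -> None:
    """Serialize the protocol parameters (not the realized schedule) as JSON."""
    fields = {
        f.name: getattr(protocol, f.name)
        for f in dataclasses.fields(protocol)
        if f.name not in ("schedule", "iteration_len")
    }
    Path(path).write_text(json.dumps(fields, indent=1, default=list))


def read_protocol(path) -> stimuli.SemiStochasticProtocol:
    """Re-realize a protocol from its JSON parameters (same seed, same schedule)."""
    params = json.loads(Path(path).read_text())
    return stimuli.make_semistochastic(**params)


def schedule_frame(protocol: stimuli.SemiStochasticProtocol) -> pd.DataFrame:
    """Realized schedule as a tidy table."""
    rows = [
        (p.iteration, round(p.onset, 6), p.duration, p.rate, p.condition_id)
        for it_pulses in protocol.schedule
        for p in it_pulses
    ]
    return pd.DataFrame(
        rows, columns=["iteration", "onset_ms", "duration_ms", "rate_pps", "condition_id"]
    )


def make_fixtures(seed: int = 0, n_sgn: int = 12, n_avcn: int = 4) -> dict:
    """Small synthetic cohort used by tests and the demo pipeline.

    Returns SGN parameter sets drawn from the 3-cluster mixture, their
    responses to a 100 pps deterministic train and to the default
    semi-stochastic protocol, plus AVCN units pooling SGN subsets.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + n_sgn + n_avcn)]
    params = synth.sample_population(n_sgn, seed=seeds[0])
    train = stimuli.make_pulse_train(rate=100.0, duration=1.6, intensity=35.0)
    protocol = stimuli.make_semistochastic(seed=seeds[1])
    sgn_train = [
        synth.simulate_sgn(p, train, seed=seeds[4 + i], unit_id=f"sgn{i:02d}")
        for i, p in enumerate(params)
    ]
    sgn_sched = [
        synth.simulate_schedule(p, protocol, seed=seeds[4 + i], unit_id=f"sgn{i:02d}")
        for i, p in enumerate(params)
    ]
    avcn = synth.simulate_avcn_population(sgn_sched, n_units=n_avcn, seed=seeds[2])
    return {
        "seed": seed,
        "params": params,
        "train": train,
        "protocol": protocol,
        "sgn_train": sgn_train,
        "sgn_schedule": sgn_sched,
        "avcn": avcn,
    }


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate the demo cohort and run every analysis stage on it.

    Writes spike tables, per-unit metrics, a clustering summary, the
    population gain analysis and a JSON run log (seeds, versions, output
    hashes); returns the paths and headline numbers.
    """
    from . import population, stochastic

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixtures(config.seed, config.n_sgn, config.n_avcn)

    write_spikes(fx["sgn_train"], out / "sgn_train_spikes.csv")
    write_spikes(fx["sgn_schedule"], out / "sgn_schedule_spikes.csv")
    write_spikes(fx["avcn"], out / "avcn_spikes.csv")
    write_protocol(fx["protocol"], out / "protocol.json")
    schedule_frame(fx["protocol"]).to_csv(out / "schedule.csv", index=False)

    rows = []
    for rec in fx["sgn_train"]:
        m = metrics.unit_metrics(rec, window_ms=config.window_ms)
        rows.append((rec.unit_id, m.spikes_per_stimulus, m.fsl, m.fsl_jitter,
                     m.adaptation_ratio, m.discharge_rate))
    unit_df = pd.DataFrame(
        rows, columns=["unit_id", "spikes_per_stimulus", "fsl_ms",
                       "fsl_jitter_ms", "adaptation_ratio", "discharge_rate"]
    )
    unit_df.to_csv(out / "unit_metrics.csv", index=False)

    grids = [stochastic.condition_metrics(rec, fx["protocol"], mode="combo")
             for rec in fx["sgn_schedule"]]
    feats = np.vstack([g.spikes_per_pulse for g in grids])
    clustering = stochastic.cluster_units(
        feats, unit_ids=[g.unit_id for g in grids], seed=config.seed)

    sgn_stats = population.population_condition_stats(
        fx["sgn_schedule"], fx["protocol"], mode="isi")
    avcn_stats = population.population_condition_stats(
        fx["avcn"], fx["protocol"], mode="isi")
    gain = population.neural_gain(sgn_stats, avcn_stats,
                                  threshold=config.gain_threshold,
                                  response_contour=config.response_contour)
    gain_df = pd.DataFrame({
        "dark_ms": [k.dark_time for k in gain.keys],
        "duration_ms": [k.duration for k in gain.keys],
        "sgn_spikes": gain.sgn_spikes,
        "avcn_spikes": gain.avcn_spikes,
        "gain": gain.gain,
        "jitter_change": gain.jitter_change,
    })
    gain_df.to_csv(out / "gain_map.csv", index=False)

    import scipy
    import sklearn

    summary = {
        "seed": config.seed,
        "n_sgn": config.n_sgn,
        "n_avcn": config.n_avcn,
        "n_combo_conditions": len(grids[0].keys),
        "n_isi_conditions": len(sgn_stats),
        "variance_explained_pc12": float(clustering.variance_explained[:2].sum()),
        "frac_gain": gain.frac_gain,
        "frac_loss": gain.frac_loss,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__, "sklearn": sklearn.__version__},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    log = {
        "config": dataclasses.asdict(config),
        "outputs": {p.name: _hash_file(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    summary["out_dir"] = str(out)
    return summary
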