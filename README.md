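# optopulse

Stimulus design and spike-train analysis for optogenetic stimulation of the
auditory nerve.

Optogenetic cochlear implants drive spiral ganglion neurons (SGNs) with
light pulses instead of electrical current. Characterizing that interface
means asking, for every combination of pulse duration, repetition rate and
radiant flux: how many spikes does a pulse evoke, how precisely timed are
they, how fast does the pathway recover from preceding stimulation, and how
do downstream cochlear-nucleus (AVCN) neurons — which act as coincidence
detectors on converging SGN inputs — re-code the population response?

`optopulse` implements the full computational chain used in this kind of
study, together with a seeded synthetic-response generator so that every
stage can be validated against known ground truth:

- **stimuli** — deterministic pulse trains (duty-cycle rule: no acquisition
  when the pulse exceeds its period), forward-masking sequences, and a
  semi-stochastic schedule that tests all 35 combinations of repetition
  rate {10, 56, 100, 179, 313} pps and pulse duration
  {0.2 … 2.4} ms in seeded random order (200 presentations per combination,
  ≈210 s per acquisition), plus its decomposition into 245
  (inter-stimulus dark time, duration) conditions.
- **synth** — phenomenological SGN model: per-pulse Bernoulli spiking with
  probability `sigmoid((I·min(d, τ_int) − Q50)/s) · availability`, where
  availability depletes per spike and recovers as `1 − (1 − a₀)e^(−Δt/τ_rec)`
  (adaptation, forward masking, depolarization block above a critical
  rate); Gaussian conduction latency whose mean and jitter grow as drive
  weakens; Poisson spontaneous firing; 3-cluster population heterogeneity;
  and a coincidence-counting AVCN layer (`n_required` input spikes within a
  coincidence window).
- **metrics** — spikes per stimulus (10 ms response spans, truncated at the
  next onset), first-spike latency and jitter, adaptation ratio
  (rate in the first 50 ms ÷ rate over the 400 ms train), spontaneous rate,
  SGN/AVCN unit classification, and evoked-potential wave-1 amplitude
  (zero-phase Butterworth 300–3000 Hz band-pass).
- **rlf** — intensity coding: levels in dB re the evoked-potential
  threshold (`10·log10(A/A0)`), adapted rates from the 100–400 ms plateau,
  rate-level classification, d′-based thresholds
  (`d′ = (μ1−μ0)/√((σ1²+σ0²)/2)`, linear interpolation on a 0.2 dB grid,
  threshold at d′ ≥ 1), and logistic dynamic-range fits.
- **masking** — forward-masking recovery curves and the saturating model
  `y(Δt) = max(0, a(1 − e^(−(k+Δt)/b)))`, giving the absolute recovery time
  `−k` and the 95% recovery time `−k + 3b` (1 − e⁻³ = 0.9502).
- **stochastic** — spike-triggered-average response windows, per-condition
  metric grids (35 combo / 245 ISI conditions), iteration-sufficiency
  checks, pulse-duration thresholds (0.1 spikes per pulse criterion) with
  threshold-vs-rate regression, and PCA + k-means unit clustering.
- **population** — bootstrap population neurograms (one trial per unit per
  draw), neural-gain maps (AVCN − SGN spikes/stimulus per condition, ±0.1
  gain/loss contours), and the gain-vs-jitter correlation restricted to
  iso-rate regions of interest.
- **transduction** — Gaussian-mixture thresholding of per-soma fluorescence
  (threshold = μ_low + 3σ_low, BIC component selection) and transduction
  rates.

## Worked example

```python
import numpy as np
from optopulse import stimuli, synth, metrics, masking

# a 400 ms, 100 pps train of 1.6 ms pulses at 35 mW, 20 trials
train = stimuli.make_pulse_train(rate=100, duration=1.6,
                                 train_len=400, dark_len=100, intensity=35.0)
rec = synth.simulate_sgn(synth.NeuronParams(), train, n_trials=20, seed=42)
m = metrics.unit_metrics(rec)
print(f"spikes/stimulus = {m.spikes_per_stimulus:.3f}")
print(f"first-spike latency = {m.fsl:.3f} ms, jitter = {m.fsl_jitter:.3f} ms")
print(f"adaptation ratio = {m.adaptation_ratio:.2f}")

# forward-masking recovery: binomial-noise curve, saturating-exponential fit
dt = np.geomspace(4, 180, 20)
p = masking.recovery_model(dt, 1.0, -5.0, 10.0)
p_obs = np.random.default_rng(0).binomial(20, p) / 20
fit = masking.fit_recovery(dt, p_obs)
print(f"t_abs={fit.t_abs:.2f} ms, t_rel={fit.t_rel:.2f} ms")
```

prints

```
spikes/stimulus = 0.631
first-spike latency = 2.312 ms, jitter = 0.779 ms
adaptation ratio = 1.12
t_abs=6.54 ms, t_rel=41.62 ms
```

The simulated fiber answers about 63% of the pulses at ~2.3 ms latency with
mild onset adaptation (ratio 1.12; 1 would be none). The recovery fit says
the fiber regains any probe response 6.5 ms after a masker and 95% of its
asymptotic spike probability by 42 ms — close to the generating values
(5 ms and 35 ms) despite 20-trial binomial noise.

A complete synthetic study (cohort simulation → metrics → clustering →
gain maps) runs from the shell:

```bash
optopulse run --seed 1 --out demo_out
```

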