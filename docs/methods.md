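# Methods

This note documents the models, numerical choices and known limitations of
`optopulse`. It is written for users who want to know what the synthetic
generator does and does not emulate, and why the analysis defaults are what
they are.

## Stimulus protocols

**Deterministic trains.** `make_pulse_train` places pulses at multiples of
the period over a light/sound phase (default 400 ms) followed by dark
(default 100 ms). A condition whose pulse duration reaches its period is
rejected (`DutyCycleError`) — the acquisition simply cannot exist.

**Forward masking.** A masker burst (default 10 pulses of 1.6 ms at
316 pps; 313 pps inside the semi-stochastic protocol — both values are in
circulation for this protocol and the module keeps them configurable)
followed by a single probe pulse one masker period plus Δt after the last
masker onset, a 200 ms dark tail, 20 trials per interval, 20 intervals
log-spaced over 4–180 ms (log spacing samples the rising phase of an
exponential recovery densely; the exact spacing of the original hardware
protocol is not specified).

**Semi-stochastic schedule.** Each of the 20 iterations contains a
desensitizing masker (10 × 2.4 ms at 100 pps), a seeded random permutation
of all 35 (rate, duration) combinations × 10 repetitions, one
forward-masking insert (alternating the 15 ms and 80 ms probe intervals
across iterations; their placement within the acquisition is a design
choice), and a 200 ms dark tail. Consecutive onsets are spaced by the
*current* pulse's period, so the dark time preceding a pulse equals its own
period minus the previous pulse's duration. This is what makes the
repetition rate physically meaningful in a randomized schedule — a 313 pps
presentation gives the fiber at most 3 ms of recovery — and what produces
exactly 5 × 7 = 35 distinct dark times, hence 35 × 7 = 245
(dark time, duration) conditions on decomposition. Total duration is the
sum of the periods plus masker/insert/tail overhead, ≈ 203 s, and is
invariant across permutation seeds. Seeding uses one root
`SeedSequence` with per-iteration child streams, so extending an
acquisition never changes already-generated iterations.

`decompose_isi` assigns every pulse except each iteration's first to its
(dark time, duration) key. Forward-masking-insert pulses are excluded by
default: their probe gaps (≈16.6 and ≈81.6 ms) would contribute two
singleton conditions outside the 245-condition design, and the masking
module analyzes them separately. The within-iteration masker is kept; its
key (7.6 ms, 2.4 ms) coincides with an existing combo key.

## The synthetic SGN

The generator is deliberately phenomenological — a per-pulse Bernoulli
model rather than membrane dynamics — because the analysis chain estimates
response statistics, and a Bernoulli model makes every one of them
analytically checkable.

Per pulse, the spike probability is

    p = sigmoid((I · min(d, τ_int) − Q50) / s) · A(t)

with `I` the radiant flux (mW), `d` the pulse duration (ms), `τ_int` an
integration cap (1.8 ms; beyond it longer pulses add no effective charge,
which reproduces the non-monotonic efficiency of very long pulses), `Q50`
the effective charge (mW·ms) at 50% probability and `s` the sigmoid slope.
`A(t)` is an availability state in [0, 1]: it is multiplied by
(1 − `adapt_depletion`) after each spike and recovers between pulses as
`A = 1 − (1 − A₀)e^(−Δt/τ_rec)`. Two consequences: onset-dominated firing
in sustained trains (adaptation ratio > 1) and forward-masking recovery
curves of exactly the saturating-exponential form the masking module fits,
with `b ≈ τ_rec`. When the preceding inter-onset interval is shorter than
`1/block_rate` (default 250 pps), availability collapses to 0 after the
pulse — a depolarization-block stand-in that confines firing at very high
rates to the train onset.

Evoked spike times are `onset + latency` with latency
`N(μ + μ_drive·(1−p_det), (σ + σ_drive·(1−p_det))²)`, where `p_det` is the
deterministic sigmoid term. The drive-dependent terms (defaults
μ_drive = 0.5 ms, σ_drive = 0.7 ms) encode the well-known physiology that
near-threshold stimulation fires later and less precisely; they are what
lets pooled population jitter vary across conditions at matched spike
rates, which the gain-vs-jitter analysis requires. They are bounded so that
evoked spikes stay inside the 3 ms analysis window at the highest
repetition rate; larger values would censor late spikes and bias the
per-condition statistics. Spontaneous spikes are homogeneous Poisson;
a relative refractory period (0.7 ms) removes spikes closer than that to
their predecessor. At most one evoked spike per pulse is generated —
consistent with fast-closing opsins at moderate flux; opsins that fire
bursts per pulse are not emulated.

**Population heterogeneity.** `sample_population` draws fibers from a
3-cluster mixture (weak/intermediate/strong expression, proportions
0.3/0.5/0.2). Cluster centers differ in sensitivity (Q50 = 50/26/12 mW·ms),
input/output steepness (s = 9/6/4 — the weak cluster never saturates at
35 mW) and recovery speed (τ_rec = 120/60/25 ms), with within-cluster SDs
chosen so activation thresholds spread over several dB across a cohort.
The clusters are recoverable by PCA + k-means on the per-condition spike
counts, and the strong cluster is the fastest to recover from masking.

**The AVCN layer.** `simulate_avcn` emits a spike when `n_required` input
spikes (pooled over fibers) fall within a `coincidence_window`, at the
trigger time plus a Gaussian synaptic delay, subject to an absolute
refractory period. Defaults: 10 fibers, window 0.3 ms, `n_required` 3,
refractory 2.5 ms, delay 0.7 ± 0.1 ms. The refractory value is load-bearing
in both directions: shorter, and a pair detector can fire several times per
dispersed input volley (which would *reward* asynchrony); longer than the
shortest protocol period (3.195 ms at 313 pps), and responses at high rates
are suppressed by the previous pulse's output. `simulate_avcn_population`
builds a cohort whose `n_required` cycles through {2, 2, 2, 3, 3, 4}: the
low-threshold units keep the cohort sensitive to input synchrony at low
spike rates, the high-threshold units at high rates, as expected from bushy
cells of differing convergence.

## Analysis choices

- **Response spans.** Spikes are attributed to the pulse whose
  [onset, onset + 10 ms) span contains them; spans truncate at the next
  onset so no spike is counted twice at 316/1000 pps. First-spike
  statistics pool pulses × trials (not per-trial means); jitter is the
  sample SD (ddof = 1).
- **Adaptation ratio** aggregates counts across trials before dividing
  (ratio of mean rates), which avoids the Jensen bias of averaging
  per-trial ratios at low counts.
- **Wave-1 amplitude** is max − min of the zero-phase band-passed trace
  (2nd-order Butterworth, 300–3000 Hz) inside a configurable 1–3 ms search
  window — a deterministic replacement for semi-automatic visual marking.
  The synthetic evoked wave is a 1 kHz Gabor atom whose spectrum sits well
  inside the passband (filter loss < 1%), so noiseless amplitudes round-trip.
- **d′ thresholds** use the pooled-variance form
  `(μ1−μ0)/√((σ1²+σ0²)/2)` on per-trial plateau rates, the standard
  psychophysical convention. The d′-level function is linearly interpolated
  at 0.2 dB; the threshold is the lowest grid level with d′ ≥ 1 and is
  declared undefined when even the lowest measured level exceeds criterion
  (the crossing would be extrapolation). The saturation criterion for the
  dynamic range is 0.95 of the fitted maximum by default with 0.99
  available (`criterion=`), since both conventions appear in practice.
- **Recovery fits** use `y = max(0, a(1 − e^(−(k+Δt)/b)))` — the unique
  saturating reading of the model under which "95% recovery" lands exactly
  at −k + 3b. Fits are least squares on normalized probabilities with `a`
  free in (0, 1.5], `b` in (0, 500] ms, multistarted over 5 initial time
  constants; noiseless curves are recovered to machine precision.
- **Iteration sufficiency** replaces an unspecified classifier with a
  transparent criterion: the smallest iteration count whose per-condition
  spikes/pulse grid deviates from the full-data grid by at most 0.05
  everywhere (the full count itself never counts as evidence).
- **Clustering** mean-centers the units × conditions matrix without
  per-feature standardization (all features share units), takes 2 principal
  components and runs seeded k-means (k = 3, 50 restarts).
- **Population statistics** draw one whole trial per unit per bootstrap
  (50 draws). Pooled first-spike variance then obeys the law of total
  variance, σ_pooled² = σ_within² + σ_across², which the tests verify to
  2% at ≥10⁴ pooled spikes. Neural gain is the per-condition difference of
  per-fiber spikes/stimulus (AVCN − SGN); ±0.1 delimits gain/loss regions.
- **Iso-rate regions of interest.** The low-rate band defaults to 0–0.26
  spikes/stimulus. A fixed high-rate band only makes sense relative to a
  specific dataset's rate distribution, so `select_iso_rate_band`
  implements the underlying rule directly: slide a 0.15-wide band above the
  median rate and keep the one maximizing the jitter interquartile range
  (≥35 conditions). Correlations are Pearson (Spearman by flag), with
  permutation p-values where distributional assumptions are doubtful.
- **Mixture thresholding** fits 1–3 Gaussian components by EM (10 seeded
  restarts each), selects by BIC, and thresholds at μ + 3σ of the
  lowest-mean component. Per-specimen fitting is recommended since
  background brightness varies between preparations.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the sizes a single-unit study would produce: cohorts of 12–13 SGNs and
16–24 AVCN units, 20 trials per condition, 20-iteration semi-stochastic
acquisitions, 50–100 seed replicates for stochastic checks. The
gain-vs-jitter check pools three independent 13-fiber cohorts
(standardized within cohort, permuted within cohort) — a replication-style
design that averages over the considerable cohort-composition variance a
single 13-unit draw exhibits.

## What passing tests do and do not show

The generator shares the analysis chain's assumptions (Bernoulli spikes,
Gaussian latencies, exponential recovery), so parameter-recovery tests
validate the *estimators*, not the biological fidelity of the model. Real
recordings add electrode drift, bursting, spike-sorting errors, non-Poisson
spontaneous activity and opsin kinetics that none of this emulates. The
qualitative behaviors the generator is calibrated to — graded activation,
adaptation at high rates, slower/looser firing near threshold, synchrony-
dependent downstream gain — are reproduced in sign and rough magnitude, not
fitted to any particular dataset.
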