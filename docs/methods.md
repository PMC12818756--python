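# Methods

## Scope and design

The package studies how the dispersion of synaptic weights across converging
auditory-nerve (AN) fibers shapes the output of a globular bushy cell (GBC).
Its three computational stages — input generation, synaptic integration, and
response quantification — are deliberately phenomenological: the claim under
test is that the rate-versus-precision trade-off follows from input
*statistics* interacting with a thresholded coincidence detector, not from
biophysical detail.  Everything is seeded and deterministic; identical
configuration and master seed reproduce byte-identical result tables.

## Surrogate auditory-nerve input

A full auditory-periphery model (cochlear filtering, hair-cell transduction,
synaptic adaptation) is replaced by a thinned inhomogeneous renewal process
that reproduces only the output statistics that matter downstream:

- **Rate profile.**  Spontaneous rate 70 spikes/s (high-spontaneous-rate
  fiber).  During the tone, an onset peak decays double-exponentially
  (0.7 weight on a 2 ms component, 0.3 on a 20 ms component) from
  `onset_rate` to `sustained_rate`.  Defaults: onset 3000 spikes/s,
  sustained 220 spikes/s.  These two numbers are calibrated, not measured
  from any particular dataset: they were chosen once so that the default
  model cell passes the physiological screening criteria below (sustained
  driven rates of a few hundred spikes/s per fiber and instantaneous onset
  rates of a few thousand are within the physiological range for
  high-spontaneous AN fibers).  Sound level is carried as metadata only;
  there is no rate-level function.
- **Phase locking.**  Candidate events are accepted with a von Mises factor
  `exp(κ cos φ)/I₀(κ)` on the fine-structure phase (tones) or modulator
  phase (SAM).  The factor's phase average is 1, so thinning preserves mean
  rate.  κ at a given frequency is obtained by inverting the Bessel ratio
  `I₁(κ)/I₀(κ) = VS` for the target vector strength, interpolated
  log-linearly between anchors (0.75 at 350 Hz, 0.77 at 1,000 Hz, 0 at
  3,500 Hz), followed by a fixed-point refinement against a deterministic
  simulated protocol.  The refinement exists because dead-time pruning
  inside the cycle peak biases the measured VS by about −0.01 at 350 Hz;
  the calibration contract is on the *measured* statistic.
- **Refractoriness.**  A hard dead time of 0.45 ms, then acceptance with
  probability `1 − exp(−Δt/0.5125 ms)` where Δt is measured from the end of
  the dead time.  The recovery form is a modeling choice; only the two time
  constants are constrained.  At a driven rate `r` the realized rate is
  ≈ `r/(1 + r·(t_abs + τ_rel))`.
- **Envelope locking (SAM).**  For modulation frequencies ≤ 600 Hz the
  sustained rate is multiplied by a unit-mean raised cosine
  `1 + depth·cos(2π f_m t)`; at 2,000 Hz the profile is identical to the
  unmodulated carrier.  With full depth this yields an envelope vector
  strength of 0.5 for the AN input, which the GBC sharpens or broadens
  depending on the weight condition.  The von Mises factor on modulator
  phase is supported (κ is config-exposed) but defaults to 0 for SAM so the
  rate gain is the single source of envelope locking; using both would
  compound two locking mechanisms with no independent constraint to
  separate them.
- **Seeding.**  One master seed; each (fiber, repetition) pair gets an
  independent substream via explicit `SeedSequence` spawn keys, so enlarging
  the fiber count or repetition count never perturbs existing trains.

What the surrogate does *not* emulate: spectral selectivity (the SAM carrier
is metadata), level dependence, long-range rate fluctuations
(fractional-Gaussian-noise spontaneous activity), across-fiber correlation,
and any species-specific tuning internals.  Passing tests therefore show
that the downstream conclusions follow from first- and second-order input
statistics; they do not validate a periphery model.

## Synaptic weights and conductance

Weights are gamma-distributed with shape `1/v²`, scale `m·v²`.  Draws are
rescaled to a sample mean of exactly `m` (the protocol holds the *average*
input strength constant across variation conditions; without the rescale the
sample-mean standard error at n = 10, v = 1 is ~32% and injected charge is
not comparable across conditions).  The rescale leaves the sample CV
untouched; raw i.i.d. draws are available with `exact_mean=False`.
`v = 0` returns exactly equal weights.

The `morph_MED` / `morph_HIGH` presets are **synthetic** 8-element vectors
(gamma mid-quantiles rescaled to CV 0.33 and 0.80 exactly); the individual
reconstructed endbulb sizes they stand in for are not published.

Conductance templates convolve each train with a peak-normalized
alpha-function EPSG kernel (τ = 0.2 ms), scale by the weight, and sum
linearly across fibers at dt = 0.01 ms (100 kHz).  Peak normalization means
a weight of `w` nS produces a `w`-nS unitary peak — weights scale amplitude,
not charge.  Ohm's-law current uses a reversal potential of −12 mV.

## The coincidence-counting cell

Each AN spike contributes a rectangle of width `W` and per-fiber amplitude
`A_i = A·w_i/mean(w)` in units of the static threshold `θ_S = 1`; the mean
amplitude across fibers is exactly `A`, so the conductance arm and the model
arm share one weight vector.  The dynamic threshold obeys
`T·dθ_D/dt = −θ_D + S·u²`; the quadratic drive stands in for the joint
activation of adaptive conductances and feed-forward inhibition, and is what
lets the cell reject poorly synchronized input.

Numerical choices:

- `u(t)` is exactly piecewise constant, so the exponential-Euler update of
  θ_D is exact at sample points.  Because θ_D is **not reset at spikes** it
  is a linear first-order filter of `u²` and is computed with a vectorized
  IIR filter; spike emission is then a single pass over upward-crossing
  events.
- Spike rule: a spike requires a *fresh* upward crossing of `u` through θ
  outside the refractory period `R`.  A level-hold of `u ≥ θ` across the
  refractory boundary does not re-trigger; this prevents pathological tonic
  firing at exactly `1/R` from one wide input.  Whether the original
  formulation re-triggers on level is not documented; the crossing rule is
  this package's documented choice, as is letting θ_D continue to integrate
  during refractoriness.
- θ_D starts at 0 and each repetition is preceded by a 50 ms settling
  segment (the spontaneous tail of that repetition's pause replayed at
  negative time, output spikes before 0 discarded) so the threshold is at
  its background steady state when the analysis window opens.
- Each emitted spike is delayed by `D_fix + D_rand` with `D_fix = 0.2` ms
  and `D_rand ~ Gamma(shape 2, scale 0.1 ms)` (the alpha distribution),
  adding 0.4 ms mean latency with 0.14 ms SD — the model's only stochastic
  element, standing in for intrinsic spike-generator jitter.
- An event-driven reference simulator integrates θ_D in closed form on each
  constant-`u` segment and locates crossings exactly.  Grid and oracle agree
  exactly on ≥95% of random small fixtures; the remainder are
  quantization-boundary cases (inter-crossing gap within one sample of `R`,
  near-tangent crossings where θ approaches `u` asymptotically) and differ
  by at most one spike.

## Response metrics

All metrics consume per-trial spike-time arrays; undefined values propagate
as NaN, never 0.

- **Vector strength**: resultant length at the locking frequency, computed
  over `[onset + 10 ms, stimulus end]` to skip the onset transient (window
  config-exposed; the exact window used in the source analyses is not
  documented).
- **Correlation index**: cross-trial coincidence count within a 0.05 ms
  window, normalized by `N(N−1)·r²·w·D`.  The window is standard
  shuffled-autocorrelogram practice and config-exposed.  The chance
  normalization assumes stationarity; on strongly adapting epochs the index
  reads slightly above 1.
- **Entrainment index**: fraction of within-trial ISIs in
  `[0.5, 1.5]` stimulus periods.
- **Corr_Norm**: non-mean-subtracted cosine similarity between the response
  PSTH (0.5 ms bins) and the stimulus envelope, maximized over lags in
  `[0, 10 ms]` to absorb response latency, with both signals normalized
  over the overlapping segment.  A constant response against a 100% SAM
  envelope scores `1/√1.5 ≈ 0.82` — the metric's floor for unmodulated
  firing; values above ~0.9 indicate genuine envelope tracking.
- **FSL_min**: earliest 0.1 ms PSTH bin whose pooled count is impossible
  under the spontaneous rate (one-sided Poisson tail, p < 1e−6).  This is a
  detection-theoretic latency: it cannot be fooled by high spontaneous
  activity, at the cost of sitting slightly right of the true first-spike
  distribution's edge.
- **First-spike jitter**: SD of per-trial first spikes in
  `[FSL_min − 0.6, FSL_min + 1.2]` ms.  **Onset probability**: fraction of
  trials with a spike within 1.5 ms of the response onset, read as the
  distance `|t − FSL_min| ≤ 1.5 ms` — first spikes legitimately precede the
  statistical detection edge, as the jitter window's backward reach
  acknowledges.
- **Rate epochs**: evoked over the whole tone; sustained over
  `[onset + 50, onset + 200]` ms; spontaneous over the final 150 ms of the
  pause.

## Screening

The default parameter grid spans A 0.28–0.50 (step 0.02), W 0.2–1.4 (0.2),
R 0.8–2.0 (0.2), S 0.4–1.6 (0.2), T 0.3–2.1 (0.3): 12·7·7·7·7 = 28,812
instances.  Each instance is simulated with 350 Hz and 3,500 Hz tones
(200 ms + 200 ms pause; 100 repetitions by default) on one shared AN train
set and equal weights, and must satisfy: (1) spontaneous rate 10–60
spikes/s; (2) 350 Hz sustained driven rate > 180 spikes/s and VS > 0.85;
(3) 3,500 Hz sustained rate 80–180 spikes/s and onset probability > 0.95;
and a primary-like-with-notch PSTH at 3,500 Hz — (4) notch within 3 ms of
the onset peak, (5) notch below 50% of the steady-state rate, (6) second
peak absent or below 300 spikes/s, (7) rate at 6–10 ms above 90% of steady
state, (8) second notch absent or above 50% of steady state (the
chopper-response discriminator).  Inequalities are applied as printed
(closed band for ranges, strict for `>`).  The onset peak is searched within
5 ms of response start, the second peak within 5 ms after the notch, and the
second notch within 3 ms after the second peak; bounding these searches is
this package's choice — at 100 repetitions and 0.5 ms bins an unbounded
search flags ordinary Poisson dips in the sustained epoch.

The default parameter set passes all eight criteria with the shipped
surrogate; this is a calibration assertion of the shipped defaults, checked
in the test suite.  The accepted *fraction* of the full grid depends on the
input statistics, so it is a property of this surrogate, not a universal
constant.  Decisions of marginal instances can flip between repeat runs at
the expected few-percent rate; screening seeds are derived per instance so
results are independent of evaluation order.

## Sweep experiments and problem sizes

A sweep shares one AN spike-train set per stimulus across all variation
conditions and instances (only the weights change), mirroring the
experimental protocol and isolating the effect of the weights.  The default
variation grid is v ∈ {0, 0.1, …, 1.2}.  The test suite runs the trade-off
trend checks at 5–10 repetitions per stimulus over 50 master seeds, and the
spontaneous-rate transition check over a 4-instance population
(A ∈ {0.32, 0.38, 0.44, 0.50}) with 12 seeds — sizes chosen to keep the full
suite in the tens of seconds while leaving the medians' ordering far from
the noise floor.  Full-grid screening (28,812 instances, ~0.5 s each) is a
several-hour single-core run and is exposed through the CLI, not the tests.

## Known limitations

- The surrogate's onset/sustained rates and latencies are calibrated
  quantities; conclusions that depend on their absolute values (rather than
  on comparisons across weight conditions) should be read accordingly.
- Simulated response distributions are narrower than biological ones: the
  only noise sources are the point process and the spike-delay jitter (no
  channel noise, no synaptic release stochasticity, no short-term
  plasticity, no NMDA component, no inhibition).
- Linear summation of statistically independent inputs is assumed
  throughout; correlated or dendritically interacting endbulbs would reduce
  the effective variation.
- The correlation-index normalization assumes a stationary rate within the
  analysis window.
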