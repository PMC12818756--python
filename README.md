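# bushycell

Globular bushy cells (GBCs) in the cochlear nucleus integrate converging
auditory-nerve (AN) inputs through large endbulb-of-Held synapses whose
strengths vary widely, even on a single cell.  `bushycell` is a simulation
and analysis package for studying what that heterogeneity does to sound
encoding: it generates surrogate AN spike trains with controlled statistics,
drives an adaptive coincidence-counting neuron model with synaptic weights of
a chosen coefficient of variation, and quantifies the resulting trade-off
between firing rate and temporal precision.

It is aimed at auditory/computational neuroscientists who want a desk-scale,
fully seeded pipeline for input-heterogeneity experiments — no auditory
periphery model, no recording rig required.

## The model

**Synaptic weights.**  Per-fiber strengths `w_i` (nS) are drawn from a gamma
distribution with shape `a = 1/v²` and scale `b = m·v²`, so the mean is `m`
and the coefficient of variation `v = s/m` is the experiment's control knob
(`v = 0`: all inputs equal; `v = 0.4`: "medium"; `v = 1`: "high", with the
largest input near or above threshold).  Two morphologically constrained
8-input presets (`morph_MED`, CV ≈ 0.33; `morph_HIGH`, CV ≈ 0.8) mirror
reconstructed endbulb populations.

**AN surrogate.**  Spike trains are produced by a thinned inhomogeneous
renewal process: a primary-like rate profile (onset peak adapting to a
sustained rate, spontaneous rate 70 spikes/s), a von Mises phase-locking
factor `exp(κ·cos φ)/I₀(κ)` with κ calibrated so the pooled vector strength
matches physiological anchors (0.75 at 350 Hz, 0.77 at 1 kHz, ~0 at
3.5 kHz), and absolute (0.45 ms) plus relative (τ = 0.5125 ms)
refractoriness.  For amplitude-modulated (SAM) stimuli the sustained rate
follows the envelope for modulation frequencies up to 600 Hz and not at
2 kHz.

**GBC.**  Each AN spike contributes a rectangular postsynaptic response of
width `W` and amplitude `A_i = A·w_i/mean(w)` (threshold units).  The summed
input `u(t)` is compared against an adaptive threshold
`θ(t) = θ_S + θ_D(t)`, with `θ_S = 1` and

```
T · dθ_D/dt = −θ_D + S · u(t)²
```

A spike fires at a fresh upward crossing of `u` through `θ` outside the
refractory period `R`, then is delayed by `D_fix + D_rand` (alpha-distributed
jitter; mean +0.4 ms, SD 0.14 ms).  The five free parameters `(A, W, R, S,
T)` default to `(0.38, 0.6 ms, 1.5 ms, 0.8, 0.7 ms)`; a 28,812-point grid
around these values can be screened against eight physiological criteria
(spontaneous rate band, driven rate and vector strength at 350 Hz, onset
reliability at 3.5 kHz, primary-like-with-notch PSTH shape).

**Metrics.**  Vector strength, shuffled-autocorrelogram correlation index,
entrainment index, normalized envelope cross-correlation (Corr_Norm),
Poisson-tail minimum first-spike latency, first-spike jitter, onset
probability, and evoked/sustained/spontaneous rate epochs.

## Worked example

```python
from bushycell import ExperimentConfig, StimulusSpec, run_sweep

stimuli = [
    StimulusSpec(kind="pure_tone", frequency=350.0, duration=200.0,
                 pause=200.0, n_reps=10, onset_latency=4.1),
    StimulusSpec(kind="pure_tone", frequency=3500.0, duration=200.0,
                 pause=200.0, n_reps=10, onset_latency=2.4),
]
cfg = ExperimentConfig(stimuli=stimuli, variation_grid=[0.0, 0.4, 1.0],
                       master_seed=1)
res = run_sweep(cfg)
print(res[["stimulus", "v", "firing_rate_sustained",
           "firing_rate_spont", "vs"]].round(3).to_string(index=False))
```

```
stimulus   v  firing_rate_sustained  firing_rate_spont    vs
 tone350 0.0                244.667             14.667 0.877
 tone350 0.4                251.333             15.333 0.858
 tone350 1.0                238.000             35.333 0.851
tone3500 0.0                 92.667              6.667 0.005
tone3500 0.4                116.000             16.667 0.036
tone3500 1.0                160.667             28.000 0.013
```

Reading the table: at 3.5 kHz (no phase locking available) increasing the
weight variation from `v = 0` to `v = 1` raises the sustained rate from
~93 to ~161 spikes/s and the spontaneous rate from ~7 to ~35 spikes/s — the
largest input starts driving the cell on its own.  At 350 Hz the rate is
already cycle-limited, and the cost appears instead as a loss of temporal
precision: vector strength drops from 0.88 to 0.85.  One AN spike-train set
is shared across all conditions of an instance, so the differences are
caused by the weights alone.

A command-line interface mirrors the library
(`bushycell generate | conductance | simulate | metrics via sweep | screen |
sweep | report`); all subcommands take `--seed` and a YAML config (see
`src/bushycell/data/default_config.yaml`).

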