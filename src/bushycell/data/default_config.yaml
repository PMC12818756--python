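# Default run configuration.
# Rates and refractory constants emulate a high-spontaneous-rate auditory
# nerve fiber; phase-locking anchors give vector strength 0.75 at 350 Hz and
# 0.77 at 1,000 Hz, declining to 0 by 3,500 Hz.
an:
  sr: 70.0                  # spontaneous rate, spikes/s
  abs_refractory: 0.45      # ms
  rel_refractory_tau: 0.5125  # ms
  onset_rate: 3000.0        # peak driven rate at tone onset, spikes/s
  sustained_rate: 220.0     # adapted driven rate, spikes/s
  adaptation_tau_fast: 2.0  # ms
  adaptation_tau_slow: 20.0 # ms
  vs_anchors:               # [frequency Hz, vector strength]
    - [350.0, 0.75]
    - [1000.0, 0.77]
    - [3500.0, 0.0]

synapse:
  epsc_tau: 0.2             # alpha-kernel time constant, ms
  e_syn: -12.0              # reversal potential, mV
  mean_weight: 10.0         # m, nS (in the 7-14 nS range that drives firing)
  dt: 0.01                  # ms (100 kHz)

model:                      # adaptive coincidence-counting cell, defaults
  A: 0.38                   # mean input amplitude (threshold units)
  W: 0.6                    # input duration, ms
  R: 1.5                    # refractory period, ms
  S: 0.8                    # adaptation strength
  T: 0.7                    # adaptation time constant, ms

screening:
  n_reps: 100
  duration: 200.0           # ms
  pause: 200.0              # ms
  n_fibers: 10

sweep:
  variation_grid: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2]
  n_fibers: 10              # 8 for the morph presets
  n_reps: 10
  stimuli:
    - {kind: pure_tone, frequency: 350.0, duration: 200.0, pause: 200.0, n_reps: 10, onset_latency: 4.1}
    - {kind: pure_tone, frequency: 1000.0, duration: 200.0, pause: 200.0, n_reps: 10, onset_latency: 4.1}
    - {kind: pure_tone, frequency: 3500.0, duration: 200.0, pause: 200.0, n_reps: 10, onset_latency: 2.4}
    - {kind: sam, frequency: 13000.0, mod_frequency: 200.0, mod_depth: 1.0, duration: 200.0, pause: 200.0, n_reps: 10, onset_latency: 2.4}
    - {kind: sam, frequency: 13000.0, mod_frequency: 600.0, mod_depth: 1.0, duration: 200.0, pause: 200.0, n_reps: 10, onset_latency: 2.4}
    - {kind: sam, frequency: 13000.0, mod_frequency: 2000.0, mod_depth: 1.0, duration: 200.0, pause: 200.0, n_reps: 10, onset_latency: 2.4}
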