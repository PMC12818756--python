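"""Synaptic weights with controlled heterogeneity, and conductance synthesis.

The coefficient of variation v = s/m of the per-fiber synaptic strengths is
the central manipulated quantity.  Weights are drawn from a gamma
distribution with shape a = 1/v^2 and scale b = m*v^2, so the mean is m and
the CV is exactly v in expectation.  Two morphologically constrained presets
(8 inputs, CV ~ 0.33 and ~ 0.80) mirror reconstructed endbulb size
distributions.

Spike trains are convolved with a peak-normalized alpha-function EPSG kernel
(tau = 0.2 ms) and summed linearly across fibers into a conductance trace,
the shape a conductance-clamp rig would consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .an_surrogate import SpikeTrainSet

__all__ = [
    "WeightVector",
    "EPSCKernel",
    "ConductanceTrace",
    "sample_gamma_weights",
    "morph_weights",
    "morph_preset",
    "build_conductance",
    "conductance_to_current",
]


@dataclass(frozen=True)
class WeightVector:
    """Per-fiber synaptic strengths in nS with their target statistics."""

    weights: np.ndarray          # nS, one per fiber
    mean_target: float           # m, nS
    cv_target: float             # v = s/m, dimensionless
    condition_label: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a nonempty 1-d array")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return self.weights.size

    @property
    def sample_cv(self) -> float:
        w = self.weights
        return float(w.std() / w.mean()) if w.mean() > 0 else float("nan")


@dataclass(frozen=True)
class EPSCKernel:
    """Alpha-function EPSG kernel, peak-normalized to 1 at lag tau."""

    tau: float = 0.2  # ms

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def sample(self, dt: float, n_taus: float = 12.0) -> np.ndarray:
        """Kernel sampled at dt up to n_taus time constants (value < 1e-4)."""
        t = np.arange(0.0, n_taus * self.tau, dt)
        return (t / self.tau) * np.exp(1.0 - t / self.tau)


@dataclass
class ConductanceTrace:
    """Summed synaptic conductance at uniform sampling."""

    samples: np.ndarray  # nS
    dt: float            # ms
    origin: float = 0.0  # stimulus-aligned time of the first sample, ms

    @property
    def t(self) -> np.ndarray:
        return self.origin + np.arange(self.samples.size) * self.dt

    def charge(self) -> float:
        """Time integral of the conductance, nS*ms."""
        return float(self.samples.sum() * self.dt)


def sample_gamma_weights(m: float, v: float, n: int, seed: int,
                         condition_label: str | None = None,
                         exact_mean: bool = True) -> WeightVector:
    """Draw n gamma-distributed weights with mean m and coefficient of variation v.

    Gamma shape a = 1/v^2 and scale b = m*v^2.  v = 0 returns n weights of
    exactly m (the "no variation" condition).  With ``exact_mean`` (the
    default) the draws are rescaled so the sample mean is exactly m: the
    experimental protocol holds the *average* input strength constant across
    variation conditions, which is what makes the injected charge comparable
    between conditions.  Rescaling leaves the sample CV untouched.  Pass
    ``exact_mean=False`` for raw i.i.d. draws.
    """
    if m <= 0:
        raise ValueError("m must be > 0")
    if v < 0:
        raise ValueError("v must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    label = condition_label if condition_label is not None else f"v={v:g}"
    if v == 0.0:
        return WeightVector(np.full(n, float(m)), m, 0.0, label)
    # dedicated spawn key keeps the weight stream independent of spike streams
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(87, 0)))
    shape = 1.0 / v**2
    scale = m * v**2
    w = rng.gamma(shape, scale, size=n)
    # gamma draws can underflow to ~0 at very high v; floor far below any
    # physiological weight so the positivity invariant holds
    w = np.maximum(w, 1e-12 * m)
    if exact_mean:
        w = w * (m / w.mean())
    return WeightVector(w, m, v, label)


def morph_weights(relative_sizes: np.ndarray, m: float,
                  condition_label: str = "custom") -> WeightVector:
    """Weights proportional to measured relative input sizes, rescaled to mean m.

    The CV of ``relative_sizes`` is preserved exactly.
    """
    rel = np.asarray(relative_sizes, dtype=float)
    if np.any(rel <= 0):
        raise ValueError("relative sizes must be positive")
    if m <= 0:
        raise ValueError("m must be > 0")
    w = m * rel / rel.mean()
    return WeightVector(w, m, float(rel.std() / rel.mean()), condition_label)


def morph_preset(name: str, m: float) -> WeightVector:
    """Shipped 8-input presets ``morph_MED`` (CV 0.33) and ``morph_HIGH`` (CV 0.80).

    The presets are synthetic vectors constructed to match the coefficients
    of variation of two reconstructed endbulb populations (the individual
    measured sizes are not published); see data/morph_presets.csv.
    """
    table = pd.read_csv(resources.files("bushycell.data") / "morph_presets.csv",
                        comment="#")
    if name not in table.columns:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{[c for c in table.columns]}")
    return morph_weights(table[name].to_numpy(), m, condition_label=name)


def build_conductance(trains: SpikeTrainSet, weights: WeightVector,
                      kernel: EPSCKernel | None = None,
                      dt: float = 0.01) -> list[ConductanceTrace]:
    """Summed conductance G(t) = sum_i w_i * sum_k alpha(t - t_ik), per repetition.

    The alpha kernel is peak-normalized, so one isolated spike on a fiber of
    weight w produces a w-nS conductance peak at lag tau.
    """
    if kernel is None:
        kernel = EPSCKernel()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if len(weights) != trains.n_fibers:
        raise ValueError("weights and trains must have matching fiber counts")
    n = int(np.ceil(trains.stimulus.total_ms / dt))
    k = kernel.sample(dt)
    out: list[ConductanceTrace] = []
    for r in range(trains.n_reps):
        impulses = np.zeros(n)
        for f in range(trains.n_fibers):
            times = trains.spikes[f][r]
            if times.size:
                idx = np.minimum((times / dt + 1e-9).astype(np.int64), n - 1)
                np.add.at(impulses, idx, weights.weights[f])
        g = fftconvolve(impulses, k)[:n]
        out.append(ConductanceTrace(np.maximum(g, 0.0), dt))
    return out


def conductance_to_current(g: ConductanceTrace, v_m: float,
                           e_syn: float = -12.0) -> np.ndarray:
    """Ohm's-law synaptic current I = G * (V_m - E_syn), in nA.

    G in nS and voltages in mV give pA; the result is converted to nA.
    Negative (inward, depolarizing) for V_m below the reversal potential.
    """
    return g.samples * (v_m - e_syn) * 1e-3
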