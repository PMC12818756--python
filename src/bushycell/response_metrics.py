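"""Response quantification: PSTH, rate epochs, phase locking, trial-to-trial
correlation, entrainment, envelope tracking, onset latency and jitter.

All metrics operate on lists of per-trial spike-time arrays (ms).  Undefined
metrics (no spikes, no intervals, no significant onset) propagate as NaN,
never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .an_surrogate import SpikeTrainSet, StimulusSpec

__all__ = [
    "PSTH",
    "MetricsReport",
    "make_psth",
    "vector_strength",
    "correlation_index",
    "entrainment_index",
    "corr_norm",
    "sam_envelope",
    "fsl_min",
    "first_spike_jitter",
    "onset_probability",
    "rate_epochs",
    "compute_metrics",
]


@dataclass
class PSTH:
    """Peristimulus time histogram."""

    edges: np.ndarray        # bin edges, ms
    counts: np.ndarray       # pooled spike counts per bin
    n_trials: int
    bin_width: float         # ms

    @property
    def rate(self) -> np.ndarray:
        """Per-bin firing rate in spikes/s."""
        return self.counts / (self.n_trials * self.bin_width * 1e-3)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def make_psth(trials: list[np.ndarray], t_stop: float, bin_width: float = 0.5,
              t_start: float = 0.0) -> PSTH:
    edges = np.arange(t_start, t_stop + bin_width * 0.5, bin_width)
    pooled = np.concatenate(trials) if trials else np.empty(0)
    counts, _ = np.histogram(pooled, bins=edges)
    return PSTH(edges=edges, counts=counts, n_trials=max(len(trials), 1),
                bin_width=bin_width)


def vector_strength(spikes: np.ndarray, period_hz: float,
                    window: tuple[float, float] | None = None) -> float:
    """Mean resultant length of spike phases at the given frequency.

    VS = |sum_k exp(i*2*pi*f*t_k)| / n over spikes in the window; 1 means
    perfect phase locking, 0 uniform phases.  NaN if no spikes qualify.
    """
    t = np.asarray(spikes, dtype=float)
    if window is not None:
        t = t[(t >= window[0]) & (t < window[1])]
    if t.size == 0:
        return float("nan")
    phase = 2.0 * np.pi * period_hz * t * 1e-3
    return float(np.hypot(np.cos(phase).sum(), np.sin(phase).sum()) / t.size)


def correlation_index(trials: list[np.ndarray], coinc_window: float = 0.05,
                      duration: float | None = None,
                      window: tuple[float, float] | None = None) -> float:
    """Normalized zero-lag peak of the shuffled (cross-trial) autocorrelogram.

    Counts spike pairs from distinct trials with |t_a - t_b| <= w/2 and
    normalizes by N(N-1) r^2 w D (N trials, r mean rate, D duration), the
    expected count for independent homogeneous trains; CI = 1 at chance.
    """
    if len(trials) < 2:
        raise ValueError("correlation index needs >= 2 trials")
    if window is not None:
        trials = [t[(t >= window[0]) & (t < window[1])] - window[0]
                  for t in trials]
        duration = window[1] - window[0]
    if duration is None:
        raise ValueError("duration required when no window is given")
    n_trials = len(trials)
    total = sum(t.size for t in trials)
    if total == 0 or duration <= 0:
        return float("nan")
    rate = total / (n_trials * duration)  # spikes per ms
    if rate == 0:
        return float("nan")
    half = coinc_window / 2.0
    sorted_trials = [np.sort(t) for t in trials]
    n_coinc = 0
    for i in range(n_trials):
        a = sorted_trials[i]
        if a.size == 0:
            continue
        for j in range(n_trials):
            if i == j:
                continue
            b = sorted_trials[j]
            if b.size == 0:
                continue
            n_coinc += int(np.sum(np.searchsorted(b, a + half, side="right")
                                  - np.searchsorted(b, a - half, side="left")))
    expected = n_trials * (n_trials - 1) * rate**2 * coinc_window * duration
    return float(n_coinc / expected)


def entrainment_index(trials: list[np.ndarray], period: float,
                      window: tuple[float, float] | None = None) -> float:
    """Fraction of within-trial interspike intervals in [0.5, 1.5] periods.

    1 means one spike on every stimulus cycle; skipped cycles push the index
    toward 0.  NaN when no trial contributes an interval.
    """
    isis = []
    for t in trials:
        tt = t if window is None else t[(t >= window[0]) & (t < window[1])]
        if tt.size >= 2:
            isis.append(np.diff(np.sort(tt)))
    if not isis:
        return float("nan")
    isi = np.concatenate(isis)
    inside = (isi >= 0.5 * period) & (isi <= 1.5 * period)
    return float(inside.mean())


def sam_envelope(t_ms: np.ndarray, stim: StimulusSpec) -> np.ndarray:
    """Stimulus envelope (1 + depth*cos) sampled at t_ms, zero outside the tone."""
    env = np.zeros_like(t_ms, dtype=float)
    on = stim.onset_latency
    off = on + stim.duration
    inside = (t_ms >= on) & (t_ms < off)
    phase = 2.0 * np.pi * stim.mod_frequency * (t_ms[inside] - on) * 1e-3
    env[inside] = 1.0 + stim.mod_depth * np.cos(phase)
    return env


def corr_norm(psth: PSTH, envelope: np.ndarray, max_lag: float = 10.0) -> float:
    """Normalized (non-mean-subtracted) PSTH/envelope cross-correlation.

    corr(l) = sum p(t) e(t-l) / sqrt(sum p^2 * sum e^2), maximized over lags
    in [0, max_lag] to correct for response latency.  For nonnegative
    signals the value lies in [0, 1]; a constant response against a fully
    modulated (1 + cos) envelope gives 1/sqrt(1.5) ~ 0.82.
    """
    p = psth.rate.astype(float)
    e = np.asarray(envelope, dtype=float)
    if p.size != e.size:
        raise ValueError("envelope must be sampled on the PSTH bin grid")
    if not np.any(p > 0):
        return float("nan")
    n_lags = int(round(max_lag / psth.bin_width))
    best = 0.0
    for lag in range(n_lags + 1):
        pl = p[lag:]
        el = e[:e.size - lag]
        # normalize over the overlapping segment so a latency-shifted copy
        # of the envelope scores exactly 1
        denom = math.sqrt(float(np.sum(pl * pl)) * float(np.sum(el * el)))
        if denom == 0:
            continue
        best = max(best, float(np.sum(pl * el)) / denom)
    return best


def fsl_min(trials: list[np.ndarray], sr: float, onset: float = 0.0,
            alpha: float = 1e-6, bin_width: float = 0.1,
            t_max: float | None = None) -> float:
    """Minimum first-spike latency: earliest significant rate increase.

    Scans a fine-binned pooled PSTH forward from the stimulus onset and
    returns the left edge of the first bin whose pooled count is impossible
    under the spontaneous rate (one-sided Poisson tail, p < alpha).  This
    guards against high spontaneous activity masquerading as an early first
    spike.  NaN when no bin reaches significance.
    """
    if sr < 0:
        raise ValueError("sr must be >= 0")
    n_trials = len(trials)
    pooled = np.concatenate(trials) if trials else np.empty(0)
    if t_max is None:
        t_max = float(pooled.max()) + bin_width if pooled.size else onset
    edges = np.arange(onset, t_max + bin_width * 0.5, bin_width)
    if edges.size < 2:
        return float("nan")
    counts, _ = np.histogram(pooled, bins=edges)
    mu = sr * 1e-3 * bin_width * n_trials  # expected pooled count per bin
    # P(X >= k) under Poisson(mu); for mu = 0 any spike is significant
    pvals = poisson.sf(counts - 1, mu) if mu > 0 else np.where(counts > 0, 0.0, 1.0)
    hits = np.flatnonzero(pvals < alpha)
    if hits.size == 0:
        return float("nan")
    return float(edges[hits[0]])


def first_spike_jitter(trials: list[np.ndarray], fsl: float,
                       pre: float = 0.6, post: float = 1.2) -> float:
    """SD of per-trial first spikes within [fsl - pre, fsl + post] ms.

    Trials without a spike in the window are excluded; NaN with fewer than
    two qualifying trials.
    """
    if not np.isfinite(fsl):
        return float("nan")
    firsts = []
    for t in trials:
        inside = t[(t >= fsl - pre) & (t <= fsl + post)]
        if inside.size:
            firsts.append(inside.min())
    if len(firsts) < 2:
        return float("nan")
    return float(np.std(firsts, ddof=1))


def onset_probability(trials: list[np.ndarray], fsl: float,
                      window: float = 1.5) -> float:
    """Fraction of trials with at least one spike within `window` ms of the
    response onset (|t - fsl| <= window; first spikes legitimately precede
    the statistical detection edge, as in the jitter window)."""
    if not np.isfinite(fsl):
        return float("nan")
    hits = sum(1 for t in trials
               if np.any((t >= fsl - window) & (t <= fsl + window)))
    return hits / len(trials)


def _rate_in(trials: list[np.ndarray], t0: float, t1: float) -> float:
    if t1 <= t0:
        return float("nan")
    n = sum(int(np.sum((t >= t0) & (t < t1))) for t in trials)
    return n / (len(trials) * (t1 - t0) * 1e-3)


def rate_epochs(trials: list[np.ndarray], stim: StimulusSpec,
                spont_window: float = 150.0) -> tuple[float, float, float]:
    """(evoked, sustained, spontaneous) firing rates in spikes/s.

    Evoked covers the whole stimulus, sustained the [onset+50, onset+200] ms
    window, spontaneous the final `spont_window` ms of the pause.
    """
    on = stim.onset_latency
    off = on + stim.duration
    evoked = _rate_in(trials, on, off)
    sustained = _rate_in(trials, on + 50.0, min(on + 200.0, off))
    total = stim.total_ms
    spont = _rate_in(trials, max(total - spont_window, off), total)
    return evoked, sustained, spont


@dataclass
class MetricsReport:
    """All response metrics for one (instance x stimulus x condition)."""

    firing_rate_evoked: float = float("nan")
    firing_rate_sustained: float = float("nan")
    firing_rate_spont: float = float("nan")
    vs: float = float("nan")
    rayleigh_n: int = 0
    ci: float = float("nan")
    ei: float = float("nan")
    corr_norm: float = float("nan")
    fsl_min: float = float("nan")
    jitter: float = float("nan")
    onset_prob: float = float("nan")
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "firing_rate_evoked", "firing_rate_sustained", "firing_rate_spont",
            "vs", "rayleigh_n", "ci", "ei", "corr_norm", "fsl_min", "jitter",
            "onset_prob")}
        d.update(self.extra)
        return d


def compute_metrics(output: SpikeTrainSet, vs_skip: float = 10.0,
                    ci_window: float = 0.05, psth_bin: float = 0.5,
                    corr_max_lag: float = 10.0) -> MetricsReport:
    """Full metric suite for a single-cell output spike-train set.

    The phase-locking window starts `vs_skip` ms after response onset to
    exclude the onset transient.  SAM-specific metrics (EI, Corr_Norm) are
    computed against the modulator; for pure tones they use the tone period.
    """
    stim = output.stimulus
    trials = output.trial_trains(0)
    evoked, sustained, spont = rate_epochs(trials, stim)
    on = stim.onset_latency
    off = on + stim.duration
    f_lock = stim.locking_frequency
    vs_window = (on + vs_skip, off)
    pooled = output.pooled()
    in_win = pooled[(pooled >= vs_window[0]) & (pooled < vs_window[1])]
    vs = vector_strength(pooled, f_lock, vs_window) if f_lock > 0 else float("nan")
    ci = correlation_index(trials, ci_window, window=(on, off)) \
        if len(trials) >= 2 else float("nan")
    period = 1000.0 / f_lock if f_lock > 0 else float("nan")
    ei = entrainment_index(trials, period, window=(on, off)) \
        if f_lock > 0 else float("nan")
    fsl = fsl_min(trials, sr=spont if np.isfinite(spont) else 0.0,
                  onset=on, t_max=off)
    jit = first_spike_jitter(trials, fsl)
    oprob = onset_probability(trials, fsl)
    cn = float("nan")
    if stim.kind == "sam":
        psth = make_psth(trials, t_stop=off, t_start=on, bin_width=psth_bin)
        env = sam_envelope(psth.centers, stim)
        cn = corr_norm(psth, env, max_lag=corr_max_lag)
    return MetricsReport(
        firing_rate_evoked=evoked, firing_rate_sustained=sustained,
        firing_rate_spont=spont, vs=vs, rayleigh_n=int(in_win.size), ci=ci,
        ei=ei, corr_norm=cn, fsl_min=fsl, jitter=jit, onset_prob=oprob)
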