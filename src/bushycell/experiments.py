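"""Variation-sweep experiments: the rate/temporal-precision trade-off.

For each model instance and stimulus, one auditory-nerve spike-train set is
generated and shared across all variation conditions (mirroring the
experimental protocol, where the AN spike pattern for a given stimulus was
fixed across cells and conditions); only the synaptic weight vector changes
with v.  The full metric suite is computed for every (instance x stimulus x
condition) record and summarized as percentile boxes per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .an_surrogate import (ANFiberParams, SpikeTrainSet, StimulusSpec,
                           default_params_for_stimulus, generate_trains)
from .gbc_model import GBCParams, simulate
from .response_metrics import compute_metrics
from .synaptic_input import WeightVector, morph_preset, sample_gamma_weights

__all__ = ["ExperimentConfig", "run_sweep", "aggregate"]

log = logging.getLogger(__name__)

PERCENTILES = (0, 10, 25, 50, 75, 90, 100)


@dataclass
class ExperimentConfig:
    """Specification of one variation sweep."""

    stimuli: list[StimulusSpec]
    variation_grid: list[float | str] = field(
        default_factory=lambda: [0.0, 0.4, 1.0])
    n_fibers: int = 10
    mean_weight: float = 10.0       # nS
    instances: list[GBCParams] = field(
        default_factory=lambda: [GBCParams()])
    an_params: ANFiberParams | None = None
    master_seed: int = 0
    n_reps: int | None = None       # override StimulusSpec.n_reps if set

    def __post_init__(self) -> None:
        for v in self.variation_grid:
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError("variation values must be >= 0")


def _condition_weights(cond: float | str, m: float, n_fibers: int,
                       seed: int) -> WeightVector:
    """Weight vector for one condition: a CV value or a morph preset name."""
    if isinstance(cond, str):
        return morph_preset(cond, m)
    return sample_gamma_weights(m, float(cond), n_fibers, seed,
                                condition_label=f"v={cond:g}")


def run_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Long-format records: one row per (instance x stimulus x condition)."""
    rows = []
    for si, stim in enumerate(config.stimuli):
        if config.n_reps is not None and config.n_reps != stim.n_reps:
            stim = StimulusSpec(**{**stim.__dict__, "n_reps": config.n_reps})
        an = default_params_for_stimulus(stim, config.an_params)
        stim_seed = config.master_seed + 1000 * si
        trains = generate_trains(stim, an, config.n_fibers, stim_seed)
        for ii, params in enumerate(config.instances):
            for ci, cond in enumerate(config.variation_grid):
                # weights fixed per (instance, condition): one simulated cell
                w_seed = config.master_seed + 97 * ii + ci
                weights = None
                try:
                    weights = _condition_weights(cond, config.mean_weight,
                                                 config.n_fibers, w_seed)
                    out = simulate(trains, weights, params,
                                   seed=stim_seed + 7 * ii + 13 * ci)
                    report = compute_metrics(out)
                    row = report.as_dict()
                except Exception:
                    log.exception("sweep record failed (stim %d, instance %d,"
                                  " condition %r)", si, ii, cond)
                    row = {}
                row.update({
                    "instance": ii,
                    "stimulus": _stim_label(stim),
                    "v": cond if isinstance(cond, str) else float(cond),
                    "sample_cv": weights.sample_cv if weights is not None
                    else float("nan"),
                })
                rows.append(row)
    return pd.DataFrame(rows)


def _stim_label(stim: StimulusSpec) -> str:
    if stim.kind == "sam":
        return f"sam{stim.mod_frequency:g}"
    return f"tone{stim.frequency:g}"


def aggregate(results: pd.DataFrame,
              metrics: list[str] | None = None) -> pd.DataFrame:
    """Percentile summary (0/10/25/50/75/90/100) per (stimulus, v, metric).

    Missing metric values are excluded; the number of contributing records
    is reported per row.
    """
    if metrics is None:
        skip = {"instance", "stimulus", "v", "sample_cv", "rayleigh_n"}
        metrics = [c for c in results.columns
                   if c not in skip and results[c].dtype.kind == "f"]
    rows = []
    for (stim, v), group in results.groupby(["stimulus", "v"], sort=False):
        for metric in metrics:
            vals = group[metric].dropna().to_numpy()
            row = {"stimulus": stim, "v": v, "metric": metric,
                   "n": int(vals.size)}
            if vals.size:
                for p, q in zip(PERCENTILES, np.percentile(vals, PERCENTILES)):
                    row[f"p{p}"] = float(q)
            rows.append(row)
    return pd.DataFrame(rows)
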