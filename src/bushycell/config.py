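"""YAML run configuration: loading, defaults, and dataclass construction."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .an_surrogate import ANFiberParams, StimulusSpec
from .gbc_model import GBCParams

__all__ = ["load_config", "default_config", "an_params_from_config",
           "gbc_params_from_config", "stimuli_from_config"]


def default_config() -> dict:
    """The shipped default configuration."""
    text = (resources.files("bushycell.data") / "default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load a config file, filling missing sections from the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    return cfg


def an_params_from_config(cfg: dict, kappa: float = 0.0) -> ANFiberParams:
    an = cfg["an"]
    return ANFiberParams(
        sr=an["sr"], abs_refractory=an["abs_refractory"],
        rel_refractory_tau=an["rel_refractory_tau"], kappa=kappa,
        onset_rate=an["onset_rate"], sustained_rate=an["sustained_rate"],
        adaptation_tau_fast=an["adaptation_tau_fast"],
        adaptation_tau_slow=an["adaptation_tau_slow"])


def gbc_params_from_config(cfg: dict) -> GBCParams:
    m = cfg["model"]
    return GBCParams(A=m["A"], W=m["W"], R=m["R"], S=m["S"], T=m["T"])


def stimuli_from_config(cfg: dict) -> list[StimulusSpec]:
    return [StimulusSpec(**s) for s in cfg["sweep"]["stimuli"]]
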