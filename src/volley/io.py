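"""Structured-text configuration for models, simulations and stimuli."""

from __future__ import annotations

from typing import Tuple

import yaml

from .models import HHParams, LIFParams, ModelSpec, ThetaParams
from .stimuli import StimulusSpec, stimulus_from_dict, stimulus_to_dict

__all__ = [
    "model_from_dict",
    "model_to_dict",
    "load_run_config",
    "dump_run_config",
    "load_stimulus",
    "dump_stimulus",
]


def model_from_dict(d: dict) -> ModelSpec:
    name = d["model"]
    if name == "lif":
        return LIFParams(tau=float(d["tau"]))
    if name == "theta":
        return ThetaParams(tau=float(d["tau"]))
    if name in ("wb", "rtm"):
        level = float(d.get("detection_level_mV", 0.0))
        return HHParams.wb(level) if name == "wb" else HHParams.rtm(level)
    raise ValueError(f"unknown model {name!r}")


def model_to_dict(model: ModelSpec) -> dict:
    if isinstance(model, LIFParams):
        return {"model": "lif", "tau": model.tau}
    if isinstance(model, ThetaParams):
        return {"model": "theta", "tau": model.tau}
    if isinstance(model, HHParams):
        return {"model": model.model_id, "detection_level_mV": model.spike_detection_level}
    raise TypeError(f"not a model spec: {model!r}")


def load_run_config(path) -> Tuple[ModelSpec, dict]:
    """Read a YAML run config: keys model, tau, dt, t_end, detection_level_mV.

    Returns (model, simulation keyword arguments).
    """
    with open(path) as fh:
        d = yaml.safe_load(fh)
    model = model_from_dict(d)
    sim_kw = {k: float(d[k]) for k in ("dt", "t_end") if k in d}
    return model, sim_kw


def dump_run_config(path, model: ModelSpec, **sim_kw) -> None:
    d = model_to_dict(model)
    d.update({k: float(v) for k, v in sim_kw.items()})
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_stimulus(path) -> StimulusSpec:
    with open(path) as fh:
        return stimulus_from_dict(yaml.safe_load(fh))


def dump_stimulus(path, stim: StimulusSpec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(stimulus_to_dict(stim), fh, sort_keys=False)
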