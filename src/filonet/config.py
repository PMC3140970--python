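"""Configuration loading: one versioned YAML file holds every default.

A user config is a YAML mapping with the same keys as the packaged
``data/default_config.yaml``; any subset may be given and is deep-merged
over the defaults, so transcribed literature values can replace the
calibrated placeholders verbatim.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .params import PROTEINS, CellParameterSet


def default_config() -> dict:
    """The packaged default configuration as a dict."""
    text = (
        resources.files("filonet").joinpath("data/default_config.yaml").read_text()
    )
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional user YAML config file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def endogenous_params(config: Mapping | None = None) -> CellParameterSet:
    """Parameter set at endogenous expression levels (no context scaling)."""
    cfg = config if config is not None else default_config()
    kinetics = {
        int(key[1:]): (float(val["k_on"]), float(val["k_off"]))
        for key, val in cfg["kinetics"].items()
    }
    return CellParameterSet(
        totals={p: float(cfg["endogenous_totals_nM"][p]) for p in PROTEINS},
        b_total=float(cfg["b_total_nM"]),
        kinetics=kinetics,
        k_turn=float(cfg["k_turn_per_s"]),
        ga=float(cfg["g_actin_nM"]),
        context_label="endogenous",
    )


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
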