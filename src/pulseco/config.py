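"""YAML/JSON run-configuration loading.

A run configuration is a nested mapping with optional blocks
``population``, ``hyperparameters``, ``noise`` (with ``calibrated`` /
``uncalibrated`` sub-blocks), ``ratios``, ``n_trials``, ``sites`` and a
global ``seed``.  Every omitted field falls back to the package
default, so ``{}`` is a valid configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .cnn import ModelHyperparameters
from .exceptions import ConfigurationError
from .experiment import RunConfig
from .noise import CALIBRATED_NOISE, UNCALIBRATED_NOISE, NoiseConfig
from .population import (
    ArterialSiteSpec,
    GroupSampling,
    PopulationConfig,
    default_group_sampling,
    default_site_specs,
)


def _build(cls, defaults, block: dict, label: str):
    if not isinstance(block, dict):
        raise ConfigurationError(f"{label} block must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigurationError(f"unknown {label} keys: {sorted(unknown)}")
    kwargs = {**defaults, **block}
    return cls(**kwargs)


def _population(block: dict) -> PopulationConfig:
    block = dict(block)
    groups = default_group_sampling()
    for gname, gblock in (block.pop("groups", {}) or {}).items():
        if gname not in groups:
            raise ConfigurationError(f"unknown group {gname!r}")
        groups[gname] = _build(
            GroupSampling, dataclasses.asdict(groups[gname]), gblock, f"group {gname}"
        )
    sites = default_site_specs()
    for sname, sblock in (block.pop("sites", {}) or {}).items():
        if sname not in sites:
            raise ConfigurationError(f"unknown site {sname!r}")
        sites[sname] = _build(
            ArterialSiteSpec, dataclasses.asdict(sites[sname]), sblock, f"site {sname}"
        )
    for key in ("hr_bounds", "pwv_range"):
        for g in (block.get("groups") or {}).values():
            if key in g:
                g[key] = tuple(g[key])
    if "pwv_range" in block:
        block["pwv_range"] = tuple(block["pwv_range"])
    cfg = _build(
        PopulationConfig,
        {"groups": groups, "sites": sites},
        block,
        "population",
    )
    return cfg


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    seed = int(data.pop("seed", 0))
    kwargs: dict = {"seed": seed}
    if "population" in data:
        kwargs["population"] = _population(data.pop("population") or {})
    if "hyperparameters" in data:
        kwargs["hyperparameters"] = _build(
            ModelHyperparameters,
            dataclasses.asdict(ModelHyperparameters()),
            data.pop("hyperparameters") or {},
            "hyperparameters",
        )
    noise = data.pop("noise", None) or {}
    if "calibrated" in noise:
        kwargs["noise_calibrated"] = _build(
            NoiseConfig, dataclasses.asdict(CALIBRATED_NOISE), noise["calibrated"], "noise"
        )
    if "uncalibrated" in noise:
        kwargs["noise_uncalibrated"] = _build(
            NoiseConfig, dataclasses.asdict(UNCALIBRATED_NOISE), noise["uncalibrated"], "noise"
        )
    if "ratios" in data:
        kwargs["ratios"] = tuple(data.pop("ratios"))
    if "sites" in data:
        kwargs["sites"] = tuple(data.pop("sites"))
    if "n_trials" in data:
        kwargs["n_trials"] = int(data.pop("n_trials"))
    if "search_space" in data:
        kwargs["search_space"] = data.pop("search_space")
    if data:
        raise ConfigurationError(f"unknown configuration keys: {sorted(data)}")
    return RunConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) run configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    return run_config_from_dict(data)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (JSON, explicit seed)."""
    from .experiment import _config_dict

    Path(path).write_text(json.dumps(_config_dict(config), indent=2, default=str))
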