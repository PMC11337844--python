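"""Flat key-value run configuration.

A config file is flat YAML (``key: value`` per line).  Recognised keys
and defaults:

reactor parameters
    srt_days (5.0), hrt_days (1.8), capture_fraction (1.0),
    x_tot_inf (120.0), x_tot_as (800.0), gamma_dna_inf (1.0),
    gamma_dna_as (1.0), decay_per_day (0.2)
classification
    occupancy_threshold (0.8), abundance_threshold (0.001),
    residual_ratio (1.0)
simulation / processing
    rarefaction_depth (40000), n_core (60), n_noncore (125),
    n_growing_imm (130), n_residual_imm (8), sigma_block (0.5),
    sigma_replicate (0.15), mu_net_dna (-0.3),
    phase3_duration_srts (3.0), set_id ("A"), seed (0)

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Mapping

import yaml

from .growth import ReactorParameters
from .simulate import ExperimentDesign, PoolSizes

__all__ = ["DEFAULTS", "load_config", "make_params", "make_design",
           "make_pool_sizes", "config_hash"]

DEFAULTS: dict[str, Any] = {
    "srt_days": 5.0,
    "hrt_days": 1.8,
    "capture_fraction": 1.0,
    "x_tot_inf": 120.0,
    "x_tot_as": 900.0,
    "gamma_dna_inf": 1.0,
    "gamma_dna_as": 1.0,
    "decay_per_day": 0.2,
    "occupancy_threshold": 0.8,
    "abundance_threshold": 0.001,
    "residual_ratio": 1.0,
    "rarefaction_depth": 40000,
    "n_core": 60,
    "n_noncore": 125,
    "n_growing_imm": 130,
    "n_residual_imm": 8,
    "sigma_block": 0.5,
    "sigma_replicate": 0.15,
    "mu_net_dna": -0.3,
    "phase3_duration_srts": 3.0,
    "set_id": "A",
    "seed": 0,
}


def load_config(path=None, overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Defaults, updated by the YAML file at ``path``, then by ``overrides``."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path, "rt", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        unknown = sorted(set(loaded) - set(DEFAULTS))
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {unknown}")
        cfg.update(loaded)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key not in DEFAULTS:
            raise ValueError(f"unknown config key: {key}")
        cfg[key] = val
    return cfg


def make_params(cfg: Mapping[str, Any]) -> ReactorParameters:
    return ReactorParameters.from_mapping(cfg)


def make_design(cfg: Mapping[str, Any]) -> ExperimentDesign:
    return ExperimentDesign(
        set_id=str(cfg["set_id"]),
        rarefaction_depth=int(cfg["rarefaction_depth"]),
        sigma_block=float(cfg["sigma_block"]),
        sigma_replicate=float(cfg["sigma_replicate"]),
        mu_net_dna=float(cfg["mu_net_dna"]),
        phase3_duration_srts=float(cfg["phase3_duration_srts"]),
        seed=int(cfg["seed"]),
    )


def make_pool_sizes(cfg: Mapping[str, Any]) -> PoolSizes:
    return PoolSizes(
        n_core=int(cfg["n_core"]),
        n_noncore=int(cfg["n_noncore"]),
        n_growing_imm=int(cfg["n_growing_imm"]),
        n_residual_imm=int(cfg["n_residual_imm"]),
    )


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Short stable hash of a config for provenance headers."""
    blob = json.dumps({k: cfg[k] for k in sorted(cfg)}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
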