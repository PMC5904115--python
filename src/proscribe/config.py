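"""Run configuration: YAML schema, validation and run manifests.

All angles are degrees at this boundary and converted to radians when model
objects are built. Every stochastic run requires an explicit integer seed.
A manifest (config snapshot, config hash, seed, package version, timestamps
and output hashes) is written next to each run's artifacts so any run can
be replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from . import __version__
from .model import ModelConfig, SlantStimulus

__all__ = ["ConfigError", "load_config", "build_model_config",
           "build_stimulus", "write_manifest"]

_MODEL_KEYS = {"n_units", "k", "c", "beta", "pos_scale", "neg_scale",
               "n_trials", "rate_scale", "seed", "bimodal_ratio", "edge_margin"}
_STIM_KEYS = {"slant_delta_deg", "slant_chi_deg", "A_delta", "A_chi"}
_SWEEP_KEYS = {"n_sims", "beta_mean", "beta_sd", "intensity_sd"}
_RIVALRY_KEYS = {"tau", "tau_A", "gamma", "alpha", "sigma_noise", "dt", "T",
                 "naka_n", "naka_c50", "threshold_ratio", "min_episode",
                 "record_every"}
_TDCS_KEYS = {"observed"}
_COHORT_KEYS = {"n_observers", "trait_noise_sd", "trials_per_condition"}
_FIT_KEYS = {"input_csv", "group_by"}
_TOP_KEYS = {"seed", "model", "stimulus", "conflicts_deg", "sweep", "rivalry",
             "tdcs", "cohort", "fit"}

_SECTION_KEYS = {"model": _MODEL_KEYS, "stimulus": _STIM_KEYS,
                 "sweep": _SWEEP_KEYS, "rivalry": _RIVALRY_KEYS,
                 "tdcs": _TDCS_KEYS, "cohort": _COHORT_KEYS, "fit": _FIT_KEYS}


class ConfigError(ValueError):
    """A config file violates the documented schema; names the offending key."""


def load_config(path, require_seed: bool = True) -> Dict[str, Any]:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key in cfg:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown top-level config key: '{key}'")
    for section, allowed in _SECTION_KEYS.items():
        block = cfg.get(section)
        if block is None:
            continue
        if not isinstance(block, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        for key in block:
            if key not in allowed:
                raise ConfigError(f"unknown key '{section}.{key}'")
    if require_seed and not isinstance(cfg.get("seed"), int):
        raise ConfigError("an integer 'seed' is required for stochastic runs")
    return cfg


def build_model_config(cfg: Dict[str, Any]) -> ModelConfig:
    block = dict(cfg.get("model") or {})
    if "seed" not in block and isinstance(cfg.get("seed"), int):
        block["seed"] = cfg["seed"]
    return ModelConfig(**block)


def build_stimulus(cfg: Dict[str, Any]) -> SlantStimulus:
    block = cfg.get("stimulus")
    if block is None:
        raise ConfigError("section 'stimulus' is required for this subcommand")
    missing = _STIM_KEYS - set(block)
    if missing:
        raise ConfigError(f"stimulus section missing keys: {sorted(missing)}")
    return SlantStimulus.from_degrees(
        block["slant_delta_deg"], block["slant_chi_deg"],
        block["A_delta"], block["A_chi"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, cfg: Dict[str, Any], seed: int,
                   outputs: Dict[str, Path],
                   config_path: Optional[Path] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "proscribe",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "config_path": str(config_path) if config_path else None,
        "outputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in outputs.items()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
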