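"""Run configuration: YAML loading with defaults and validation."""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "inputs": {},          # table name -> CSV path
    "filters": {
        "include_wasps": True,
    },
    "abundance": {
        "span_zeros": "skip",        # skip | include
        "fallback": "species_mean",  # species_mean | min_positive | drop
    },
    "preference": {
        "scaling": "multiply",       # multiply | divide | none
        "granularity": 10_000,
        "n_null": 1000,
    },
    "models": {
        "abundance_transform": "identity",  # identity | log1p | log
        "cluster": "plant_id",
        "knapweed_plants": ["CENTAUREA"],
    },
    "generator": {},       # GeneratorConfig overrides; presence enables simulate
}

_CHOICES = {
    ("abundance", "span_zeros"): ("skip", "include"),
    ("abundance", "fallback"): ("species_mean", "min_positive", "drop"),
    ("preference", "scaling"): ("multiply", "divide", "none"),
    ("models", "abundance_transform"): ("identity", "log1p", "log"),
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    """Defaults, overlaid with the YAML file, overlaid with overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    for (section, key), allowed in _CHOICES.items():
        value = cfg[section][key]
        if value not in allowed:
            raise ValueError(f"{section}.{key}={value!r}; allowed: {allowed}")
    if int(cfg["preference"]["granularity"]) < 100:
        raise ValueError("preference.granularity must be >= 100")
    return cfg


def snapshot(cfg: dict, out_dir: str | Path, seed: int) -> Path:
    """Write the effective config + seed beside the outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"config": cfg, "seed": seed, "pollinet_version": __version__}
    p = out / "provenance.json"
    p.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
    return p
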