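"""Configuration files (YAML or JSON) for sites, behaviour-space
structure and run parameters.

A config file may contain any of three top-level keys::

    params:
      S: 1.0
      alpha_g: 0.2
      alpha_e: 0.8
      t_max: 6000
      sigma: 0.05
      seed: 42
    sites:
      - {name: site_1, x: 0.0, y: 13.75, n: 20}
      - ...
    gradient_region:
      - [-9.0, -28.7]
      - [60.0, 43.4]
    food_structure:
      - {size: 8, nutrient: Y}
      - ...

Missing keys fall back to the package defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .dynamics import SimulationParams
from .world import (
    BehaviourSpace,
    ConfigurationError,
    Site,
    SiteMap,
    build_behaviour_space,
)

__all__ = [
    "load_config",
    "default_config",
    "sitemap_from_config",
    "space_from_config",
    "params_from_config",
]

_PARAM_KEYS = ("S", "alpha_g", "alpha_e", "t_max", "sigma", "seed")


def default_config() -> dict:
    """The built-in defaults, in config-file form."""
    p = SimulationParams()
    return {
        "params": {k: getattr(p, k) for k in _PARAM_KEYS},
        "sites": [
            {"name": s.name, "x": s.x, "y": s.y, "n": s.n}
            for s in SiteMap.default().sites
        ],
        "gradient_region": [
            list(corner) for corner in SiteMap.default().gradient_region
        ],
        "food_structure": [
            {"size": f.size, "nutrient": f.nutrient}
            for f in build_behaviour_space().food_subcategories
        ],
    }


def load_config(path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    unknown = set(cfg) - {"params", "sites", "food_structure", "gradient_region"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def sitemap_from_config(cfg: dict) -> SiteMap:
    entries = cfg.get("sites")
    region = cfg.get("gradient_region")
    if region is not None:
        region = tuple((float(x), float(y)) for x, y in region)
    if entries is None:
        if region is None:
            return SiteMap.default()
        return SiteMap(SiteMap.default().sites, gradient_region=region)
    return SiteMap(
        tuple(
            Site(str(e["name"]), float(e["x"]), float(e["y"]), int(e["n"]))
            for e in entries
        ),
        gradient_region=region,
    )


def space_from_config(cfg: dict) -> BehaviourSpace:
    return build_behaviour_space(cfg.get("food_structure"))


def params_from_config(cfg: dict, **overrides) -> SimulationParams:
    """Build run parameters from config, with keyword overrides (CLI
    flags) taking precedence; an override of ``None`` is ignored."""
    merged = dict(cfg.get("params") or {})
    unknown = set(merged) - set(_PARAM_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
    for k, v in overrides.items():
        if v is not None:
            merged[k] = v
    return SimulationParams(**merged)
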