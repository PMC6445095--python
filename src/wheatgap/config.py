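"""Structured configuration: one YAML file, defaults = study settings.

The zero-override configuration encodes exactly the study's settings:
the Claire trait values, the trait-variation bounds, the 210/270 mm
soils, sowing on 20 October (UK) / 20 April (NZ), feasibility
thresholds CV <= 0.10 and HI <= 0.64, 8 parents x 16 offspring over
100 evaluation years, and the 10% LUE uplift for ideotype design.
Command-line flags override config values; unknown keys and
out-of-range values are rejected with the path to the offending key.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import asdict

import yaml

from .crop import ModelConstants
from .cultivar import CLAIRE, TRAIT_BOUNDS, TRAIT_NAMES, CultivarParams
from .easa import EASAConfig, IDEOTYPE_LUE
from .sites import SiteClimate, builtin_sites

__all__ = ["default_config", "load_config", "dump_config", "validate_config",
           "easa_config_from", "constants_from", "cultivar_from", "sites_from"]


def default_config() -> dict:
    return {
        "sites": {s.site_id: dataclasses.asdict(s) for s in builtin_sites()},
        "reference_cultivar": {
            "name": CLAIRE.name,
            **{t: getattr(CLAIRE, t) for t in TRAIT_NAMES},
        },
        "trait_bounds": {t: list(TRAIT_BOUNDS[t]) for t in TRAIT_NAMES},
        "soil": {"UK": {"total_awc_mm": 210.0, "n_layers": 28},
                 "NZ": {"total_awc_mm": 270.0, "n_layers": 36}},
        "management": {
            "sowing_doy": {"UK": 293, "NZ": 110},
            "ideotype_lue_multiplier": IDEOTYPE_LUE,
            "flowering_stress_enabled": True,
        },
        "easa": {
            "n_parents": 8,
            "n_offspring": 16,
            "n_years": 100,
            "cv_threshold": 0.10,
            "hi_threshold": 0.64,
            "max_generations": 200,
            "stall_generations": 15,
            "include_reference_parent": True,
        },
        "weather": {"n_years": 100},
        "constants": asdict(ModelConstants()),
    }


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def validate_config(cfg: dict) -> dict:
    sites_from(cfg)  # SiteClimate invariants
    for name, pair in cfg["trait_bounds"].items():
        if name not in TRAIT_NAMES:
            raise ConfigError(f"trait_bounds.{name}: unknown trait")
        lo, hi = pair
        if not lo < hi:
            raise ConfigError(f"trait_bounds.{name}: bounds not ordered ({lo}, {hi})")
    ref = cfg["reference_cultivar"]
    for t in TRAIT_NAMES:
        if ref[t] <= 0 and t != "S_G":
            raise ConfigError(f"reference_cultivar.{t}: must be positive")
    ea = cfg["easa"]
    for key in ("cv_threshold", "hi_threshold"):
        if not 0.0 < ea[key] < 1.0:
            raise ConfigError(f"easa.{key}: must lie in (0, 1), got {ea[key]}")
    for key in ("n_parents", "n_offspring", "n_years", "max_generations",
                "stall_generations"):
        if int(ea[key]) < 1:
            raise ConfigError(f"easa.{key}: must be >= 1")
    for country, soil in cfg["soil"].items():
        if soil["total_awc_mm"] <= 0 or int(soil["n_layers"]) < 1:
            raise ConfigError(f"soil.{country}: invalid profile")
    if cfg["management"]["ideotype_lue_multiplier"] <= 0:
        raise ConfigError("management.ideotype_lue_multiplier: must be positive")
    # constants are validated by construction
    constants_from(cfg)
    return cfg


def load_config(path=None) -> dict:
    """Load and validate a YAML config; defaults applied for absent keys."""
    base = default_config()
    if path is None:
        return validate_config(base)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return validate_config(_merge(base, user))


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def sites_from(cfg: dict) -> list[SiteClimate]:
    try:
        return [SiteClimate(**fields) for fields in cfg["sites"].values()]
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"sites: {exc}") from exc


def easa_config_from(cfg: dict, mode: str, seed: int = 0) -> EASAConfig:
    ea = cfg["easa"]
    return EASAConfig(
        n_parents=int(ea["n_parents"]),
        n_offspring=int(ea["n_offspring"]),
        n_years=int(ea["n_years"]),
        cv_threshold=float(ea["cv_threshold"]),
        hi_threshold=float(ea["hi_threshold"]),
        max_generations=int(ea["max_generations"]),
        stall_generations=int(ea["stall_generations"]),
        include_reference_parent=bool(ea["include_reference_parent"]),
        mode=mode,
        seed=seed,
    )


def constants_from(cfg: dict) -> ModelConstants:
    return ModelConstants(**cfg["constants"])


def cultivar_from(cfg: dict) -> CultivarParams:
    ref = cfg["reference_cultivar"]
    return CultivarParams(**{t: float(ref[t]) for t in TRAIT_NAMES},
                          name=str(ref["name"]))
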