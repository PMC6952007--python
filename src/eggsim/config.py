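"""Run configuration: schema-validated YAML loading, presets and fixtures.

A run configuration bundles everything a simulation needs — flock parameter
distributions, lighting program, nutrient constants, feeds, economics,
horizon and seed — so that any run is reproducible from its config file plus
seed.  Unknown keys are rejected (typos surface as errors naming the key
path) and defaults are filled for everything omitted.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .egg_model import BREEDER_EGG_CURVE, LAYER_EGG_CURVE
from .feedopt import EconomicInputs, Feed
from .flock import FlockConfig, ParamDist, breeder_flock_config, layer_flock_config
from .maturity import (
    BreederMaturityCoeffs,
    LightingProgram,
    MaturityModelParams,
    predict_afe_breeder,
    predict_afe_layer,
)
from .ovulation import ICLCurve
from .requirements import GrowthParams, MaintenanceParams, NutrientConstants

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "make_fixture"]

FIXTURE_NAMES = ("layer_default", "breeder_default", "deterministic_hen")


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key path."""


_FLOCK_PARAM_KEYS = (
    "afe_d",
    "icl_baseline_h",
    "icl_initial_excess_h",
    "icl_decay_rate",
    "icl_senescence_slope_h_per_d",
    "lag_threshold_h",
    "egg_size_factor",
    "body_protein_afe_g",
    "p_internal",
    "p_soft_shell",
)
_DIST_KEYS = {"mean", "sd", "lower", "upper"}
_SIM_KEYS = {
    "photoperiod_end_h",
    "anchor_offset_h",
    "sd_first_h",
    "sd_lag_h",
    "lag_floor_h",
    "external_cycle_h",
    "body_protein_start_g",
    "afe_floor_d",
}
_MATURITY_KEYS = {f.name for f in dataclasses.fields(MaturityModelParams)} - {"breeder"}
_BREEDER_KEYS = {f.name for f in dataclasses.fields(BreederMaturityCoeffs)}
_CONSTANT_KEYS = {f.name for f in dataclasses.fields(NutrientConstants)}
_MAINT_KEYS = {f.name for f in dataclasses.fields(MaintenanceParams)}
_GROWTH_KEYS = {f.name for f in dataclasses.fields(GrowthParams)}
_FEED_KEYS = {"name", "energy_mj_per_kg", "price_per_kg", "max_intake_g_per_d", "nutrients"}
_ECON_KEYS = {"egg_price_per_kg", "objective", "allocation_g_per_d"}
_TOP_KEYS = {
    "strain",
    "seed",
    "n_hens",
    "horizon_d",
    "start_age_d",
    "output_dir",
    "flock",
    "sim",
    "lighting",
    "maturity",
    "bw20_g",
    "nutrient_constants",
    "maintenance",
    "growth",
    "feeds",
    "economics",
}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str] | tuple, path: str) -> None:
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key: {path}.{key}" if path else f"unknown key: {key}")


def _parse_dist(raw: Mapping[str, Any], path: str) -> ParamDist:
    _check_keys(raw, _DIST_KEYS, path)
    if "mean" not in raw:
        raise ConfigError(f"{path}.mean is required")
    sd = float(raw.get("sd", 0.0))
    if sd < 0:
        raise ConfigError(f"{path}.sd must be >= 0, got {sd}")
    return ParamDist(
        mean=float(raw["mean"]),
        sd=sd,
        lower=float(raw.get("lower", -np.inf)),
        upper=float(raw.get("upper", np.inf)),
    )


@dataclass(frozen=True)
class RunConfig:
    """A fully validated, defaults-applied simulation run configuration."""

    flock: FlockConfig
    maturity: MaturityModelParams
    lighting: LightingProgram | None
    constants: NutrientConstants
    maintenance: MaintenanceParams
    growth: GrowthParams
    feeds: tuple[Feed, ...]
    economics: EconomicInputs
    horizon_d: int
    seed: int
    output_dir: str
    raw: dict = field(default_factory=dict, compare=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build(data: Mapping[str, Any]) -> RunConfig:
    _check_keys(data, _TOP_KEYS, "")
    strain = data.get("strain", "layer")
    if strain not in ("layer", "breeder"):
        raise ConfigError(f"strain: must be 'layer' or 'breeder', got {strain!r}")
    seed = int(data.get("seed", 0))
    n_hens = int(data.get("n_hens", 100))
    horizon_d = int(data.get("horizon_d", 300))
    start_age_d = int(data.get("start_age_d", 120))

    sim = dict(data.get("sim") or {})
    _check_keys(sim, _SIM_KEYS, "sim")

    maturity_raw = dict(data.get("maturity") or {})
    breeder_raw = maturity_raw.pop("breeder", {}) if "breeder" in maturity_raw else {}
    _check_keys(maturity_raw, _MATURITY_KEYS | {"breeder"}, "maturity")
    _check_keys(breeder_raw, _BREEDER_KEYS, "maturity.breeder")
    maturity = MaturityModelParams(
        **maturity_raw, breeder=BreederMaturityCoeffs(**breeder_raw)
    )

    lighting = None
    if data.get("lighting"):
        steps = []
        for i, step in enumerate(data["lighting"]):
            _check_keys(step, {"age_d", "photoperiod_h"}, f"lighting[{i}]")
            steps.append((float(step["age_d"]), float(step["photoperiod_h"])))
        try:
            lighting = LightingProgram(tuple(steps))
        except ValueError as exc:
            raise ConfigError(f"lighting: {exc}") from exc

    flock_over = {}
    for key, raw in (data.get("flock") or {}).items():
        if key not in _FLOCK_PARAM_KEYS:
            raise ConfigError(f"unknown key: flock.{key}")
        flock_over[key] = _parse_dist(raw, f"flock.{key}")

    # lighting-derived mean AFE unless an explicit distribution overrides it
    if lighting is not None and "afe_d" not in flock_over:
        if strain == "layer":
            mean_afe = predict_afe_layer(lighting, maturity)
        else:
            mean_afe = predict_afe_breeder(float(data.get("bw20_g", 2200.0)), lighting, maturity)
        flock_over["afe_d"] = ParamDist(mean_afe, maturity.afe_sd_d, lower=110.0)

    maker = layer_flock_config if strain == "layer" else breeder_flock_config
    flock = maker(
        n_hens=n_hens, seed=seed, params=flock_over, start_age_d=start_age_d, **sim
    )

    const_raw = dict(data.get("nutrient_constants") or {})
    _check_keys(const_raw, _CONSTANT_KEYS, "nutrient_constants")
    defaults = NutrientConstants()
    for mapping_key in ("energy_kj_per_g", "ideal_protein_g_per_g", "nitrogen_mg_per_g"):
        if mapping_key in const_raw:
            merged = dict(getattr(defaults, mapping_key))
            merged.update(const_raw[mapping_key])
            const_raw[mapping_key] = merged
    constants = NutrientConstants(**const_raw)

    maint_raw = dict(data.get("maintenance") or {})
    _check_keys(maint_raw, _MAINT_KEYS, "maintenance")
    maint = MaintenanceParams(**maint_raw)

    growth_raw = dict(data.get("growth") or {})
    _check_keys(growth_raw, _GROWTH_KEYS, "growth")
    growth = GrowthParams(**growth_raw)

    feeds = []
    for i, f in enumerate(data.get("feeds") or [_default_feed_dict()]):
        _check_keys(f, _FEED_KEYS, f"feeds[{i}]")
        try:
            feeds.append(
                Feed(
                    energy_mj_per_kg=float(f["energy_mj_per_kg"]),
                    nutrient_g_per_kg=dict(f.get("nutrients") or {}),
                    price_per_kg=float(f.get("price_per_kg", 0.0)),
                    max_intake_g_per_d=float(f.get("max_intake_g_per_d", np.inf)),
                    name=str(f.get("name", f"feed{i}")),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"feeds[{i}]: {exc}") from exc

    econ_raw = dict(data.get("economics") or {})
    _check_keys(econ_raw, _ECON_KEYS, "economics")
    if econ_raw.get("allocation_g_per_d") is not None:
        econ_raw["allocation_g_per_d"] = float(econ_raw["allocation_g_per_d"])
    economics = EconomicInputs(**econ_raw)

    return RunConfig(
        flock=flock,
        maturity=maturity,
        lighting=lighting,
        constants=constants,
        maintenance=maint,
        growth=growth,
        feeds=tuple(feeds),
        economics=economics,
        horizon_d=horizon_d,
        seed=seed,
        output_dir=str(data.get("output_dir", "out")),
        raw=_normalize(data),
    )


def _default_feed_dict() -> dict:
    return {
        "name": "basal",
        "energy_mj_per_kg": 11.5,
        "price_per_kg": 0.35,
        "max_intake_g_per_d": 140.0,
        "nutrients": {
            "ideal_protein": 160.0,
            "lysine": 8.2,
            "methionine": 4.0,
            "cystine": 3.2,
            "threonine": 5.9,
            "tryptophan": 1.9,
            "isoleucine": 6.3,
            "leucine": 10.3,
            "valine": 8.1,
            "arginine": 7.4,
            "phenylalanine": 6.5,
            "histidine": 2.9,
        },
    }


def _normalize(data: Mapping[str, Any]) -> dict:
    out = copy.deepcopy(dict(data))
    out.setdefault("strain", "layer")
    out.setdefault("seed", 0)
    out.setdefault("n_hens", 100)
    out.setdefault("horizon_d", 300)
    out.setdefault("start_age_d", 120)
    out.setdefault("output_dir", "out")
    out.setdefault("feeds", [_default_feed_dict()])
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, applying defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    return _build(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML; loading it again reproduces ``cfg``."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=True)


def make_fixture(name: str) -> RunConfig:
    """Deterministic preset configurations for tests and demonstrations.

    * ``layer_default`` / ``breeder_default`` — the strain presets.
    * ``deterministic_hen`` — one hen, every SD zero, a constant-lag ICL
      curve (lag 1 h, threshold 8.5 h) and noise-free lay times, so the
      closed-form clutch pattern (9 eggs then one pause day) applies exactly.
    """
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture name: {name!r}; choose from {FIXTURE_NAMES}")
    if name == "layer_default":
        return _build({"strain": "layer", "n_hens": 100, "horizon_d": 300, "seed": 0})
    if name == "breeder_default":
        return _build({"strain": "breeder", "n_hens": 100, "horizon_d": 300, "seed": 0})
    zero = lambda mean, **kw: {"mean": mean, "sd": 0.0, **kw}
    return _build(
        {
            "strain": "layer",
            "n_hens": 1,
            "horizon_d": 100,
            "seed": 0,
            "start_age_d": 140,
            "sim": {
                "photoperiod_end_h": 8.0,
                "sd_first_h": 0.0,
                "sd_lag_h": 0.0,
            },
            "flock": {
                "afe_d": zero(140),
                # baseline equals the first-egg value, so the lag is constant (1 h)
                "icl_baseline_h": zero(25.0),
                "icl_initial_excess_h": zero(1.0),
                "icl_decay_rate": zero(1.0),
                "icl_senescence_slope_h_per_d": zero(0.0),
                "lag_threshold_h": zero(8.5),
                "egg_size_factor": zero(1.0),
                "body_protein_afe_g": zero(254.0),
                "p_internal": zero(0.0, lower=0, upper=1),
                "p_soft_shell": zero(0.0, lower=0, upper=1),
            },
        }
    )
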