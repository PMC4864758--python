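"""YAML configuration with a namespaced schema and defaults.

Sections: viewing, display, stimulus, texture, dots, observer, cohort,
design, analysis, plus a top-level seed.  Defaults reproduce the study
design this package models (175 cm viewing distance, 13 deg display,
16 cm discs at +/-10 cm depth, 30 trials per condition, 16 + 14 subjects).
Unknown keys and type mismatches raise :class:`SchemaError` naming the
offending field path.
"""

from __future__ import annotations

import copy
import numbers

import yaml

from .cohort import CohortSpec, LognormalSpec
from .exceptions import SchemaError
from .geometry import ViewingGeometry

__all__ = ["default_config", "load_config", "validate_config",
           "viewing_geometry_from_config", "cohort_spec_from_config"]

_DEFAULTS = {
    "seed": 0,
    "viewing": {"distance_cm": 175.0, "iod_cm": 6.2},
    "display": {"width_deg": 13.0},
    "stimulus": {"width_cm": 16.0, "depth_cm": 10.0},
    "texture": {"grid_cm": 1.0, "jitter_cm": 0.225},
    "dots": {"grid_cm": 1.0, "jitter_cm": 1.5},
    "observer": {
        "sigma_T_deg": 4.0, "sigma_D_deg": 4.0, "sigma_c_deg": 0.0,
        "criterion_deg": 6.25, "regime": "mandatory_fusion",
        "gate_k": 2.0, "lapse": 0.0,
    },
    "cohort": {
        "n_per_group": {"ASD": 16, "TD": 14},
        "regime_by_group": {"ASD": "selective_fusion", "TD": "mandatory_fusion"},
        "sigma_median_deg": 4.0, "sigma_gsd": 1.3,
        "no_fusion_rule": "switch",
    },
    "design": {"trials_per_condition": 30},
    "analysis": {"alpha": 0.05, "correction": "loglinear"},
}

_STR_FIELDS = {("observer", "regime"), ("cohort", "no_fusion_rule"),
               ("analysis", "correction")}
_DICT_FIELDS = {("cohort", "n_per_group"), ("cohort", "regime_by_group")}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def validate_config(cfg: dict) -> dict:
    """Merge ``cfg`` over the defaults, rejecting unknown or mistyped keys."""
    if not isinstance(cfg, dict):
        raise SchemaError("<root>", "configuration must be a mapping")
    merged = default_config()
    for key, value in cfg.items():
        if key == "seed":
            if not isinstance(value, numbers.Integral):
                raise SchemaError("seed", "must be an integer")
            merged["seed"] = int(value)
            continue
        if key not in merged:
            raise SchemaError(key, "unknown section")
        if not isinstance(value, dict):
            raise SchemaError(key, "section must be a mapping")
        for sub, v in value.items():
            if sub not in merged[key]:
                raise SchemaError(f"{key}.{sub}", "unknown field")
            if (key, sub) in _DICT_FIELDS:
                if not isinstance(v, dict):
                    raise SchemaError(f"{key}.{sub}", "must be a mapping")
            elif (key, sub) in _STR_FIELDS:
                if not isinstance(v, str):
                    raise SchemaError(f"{key}.{sub}", "must be a string")
            elif not isinstance(v, numbers.Real) or isinstance(v, bool):
                raise SchemaError(f"{key}.{sub}", "must be a number")
            merged[key][sub] = v
    return merged


def load_config(path) -> dict:
    """Load and validate a YAML config file; a missing file uses defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as e:
        raise SchemaError("<file>", f"invalid YAML: {e}") from e
    return validate_config(raw)


def viewing_geometry_from_config(cfg: dict) -> ViewingGeometry:
    return ViewingGeometry(
        viewing_distance=cfg["viewing"]["distance_cm"],
        interocular_distance=cfg["viewing"]["iod_cm"],
        display_width=cfg["display"]["width_deg"])


def cohort_spec_from_config(cfg: dict) -> CohortSpec:
    c = cfg["cohort"]
    return CohortSpec(
        n_per_group={str(k): int(v) for k, v in c["n_per_group"].items()},
        regime_by_group={str(k): str(v) for k, v in c["regime_by_group"].items()},
        sigma_T_dist=LognormalSpec(c["sigma_median_deg"], c["sigma_gsd"]),
        sigma_D_dist=LognormalSpec(c["sigma_median_deg"], c["sigma_gsd"]),
        trials_per_condition=int(cfg["design"]["trials_per_condition"]),
        criterion=cfg["observer"]["criterion_deg"],
        gate_k=cfg["observer"]["gate_k"],
        lapse_rate=cfg["observer"]["lapse"],
        no_fusion_rule=c["no_fusion_rule"],
        seed=int(cfg["seed"]))
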