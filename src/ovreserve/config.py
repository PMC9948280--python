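"""Flat JSON/YAML configuration for all model constants.

Recognised keys (all optional; defaults are the published values):

decay anchors   n0, n_break, age_break, n_menopause, age_menopause
dose response   alpha
clinical        intercept, slope, rmse, ci_multiplier, natural_menopause_age
grid            age_min, age_max, age_step, dose_min, dose_step
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .clinical import ClinicalCoefficients
from .exceptions import ConfigurationError
from .grid_regression import GridSpec
from .radiation_response import RadiationParams
from .reserve_decay import DEFAULT_ANCHORS, DecayParams, calibrate_decay

__all__ = [
    "default_config",
    "load_config",
    "decay_from_config",
    "radiation_from_config",
    "clinical_from_config",
    "grid_from_config",
]

_DECAY_KEYS = tuple(DEFAULT_ANCHORS)
_RAD_KEYS = ("alpha",)
_CLINICAL_KEYS = ("intercept", "slope", "rmse", "ci_multiplier", "natural_menopause_age")
_GRID_KEYS = ("age_min", "age_max", "age_step", "dose_min", "dose_step")


def default_config() -> dict:
    cfg = dict(DEFAULT_ANCHORS)
    cfg.update(alpha=RadiationParams().alpha)
    coeffs = ClinicalCoefficients()
    cfg.update({k: getattr(coeffs, k) for k in _CLINICAL_KEYS})
    spec = GridSpec()
    cfg.update({k: getattr(spec, k) for k in _GRID_KEYS})
    return cfg


def load_config(path: str | Path | None) -> dict:
    """Defaults overlaid with a flat JSON or YAML mapping (by extension)."""
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        user = json.loads(text)
    else:
        user = yaml.safe_load(text)
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"{path}: expected a flat key-value mapping")
    unknown = set(user) - set(cfg)
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg.update(user)
    return cfg


def decay_from_config(cfg: dict) -> DecayParams:
    return calibrate_decay(*(float(cfg[k]) for k in _DECAY_KEYS))


def radiation_from_config(cfg: dict) -> RadiationParams:
    return RadiationParams(alpha=float(cfg["alpha"]))


def clinical_from_config(cfg: dict) -> ClinicalCoefficients:
    return ClinicalCoefficients(**{k: float(cfg[k]) for k in _CLINICAL_KEYS})


def grid_from_config(cfg: dict) -> GridSpec:
    return GridSpec(**{k: float(cfg[k]) for k in _GRID_KEYS})
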