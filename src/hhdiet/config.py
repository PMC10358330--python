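"""Default run configuration.

Everything here is a documented implementation default, user-replaceable via a
YAML config file.  The source study cites national requirement tables without
printing their values, so the numbers below are plausible FAO/IOM-style
defaults, not ground truth: the pipeline's behaviour is defined relative to
whatever table the user supplies.

Config layout (YAML)::

    nutrients: [protein, vitamin_a, ...]
    requirements:
      protein: {kind: normal_ear, ear: 39.2, cv: 0.10}
      iron:    {kind: iron_full_probability, median_absorbed_req: 1.46,
                log_sd: 0.39, bioavailability: 0.05}
      calcium: {kind: ai_threshold, ai: 1000.0}
    energy_requirements:
      reference: 2200.0
      rows: [[female, 19, 30, moderate, 2200.0], ...]
    thresholds:
      mpa_cutoff: 0.5
      dds_gram_threshold: 15.0
      dds_cutoff: 5
      loading_display_threshold: 0.20
      eigenvalue_retention: 1.0
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError
from .model import DEFAULT_NUTRIENTS

# (sex, age_min, age_max, activity_level) -> kcal/day.  Bands are inclusive.
# Reference stratum: female 19-30 moderate = 2,200 kcal (one AFE).
DEFAULT_ENERGY_ROWS: list[list[Any]] = [
    ["female", 0, 3, "light", 800.0],
    ["female", 0, 3, "moderate", 900.0],
    ["female", 0, 3, "heavy", 1000.0],
    ["female", 4, 6, "light", 1200.0],
    ["female", 4, 6, "moderate", 1300.0],
    ["female", 4, 6, "heavy", 1400.0],
    ["female", 7, 9, "light", 1500.0],
    ["female", 7, 9, "moderate", 1600.0],
    ["female", 7, 9, "heavy", 1800.0],
    ["female", 10, 13, "light", 1800.0],
    ["female", 10, 13, "moderate", 2000.0],
    ["female", 10, 13, "heavy", 2200.0],
    ["female", 14, 18, "light", 2000.0],
    ["female", 14, 18, "moderate", 2200.0],
    ["female", 14, 18, "heavy", 2400.0],
    ["female", 19, 30, "light", 2000.0],
    ["female", 19, 30, "moderate", 2200.0],
    ["female", 19, 30, "heavy", 2500.0],
    ["female", 31, 50, "light", 1900.0],
    ["female", 31, 50, "moderate", 2100.0],
    ["female", 31, 50, "heavy", 2400.0],
    ["female", 51, 69, "light", 1800.0],
    ["female", 51, 69, "moderate", 2000.0],
    ["female", 51, 69, "heavy", 2200.0],
    ["female", 70, 120, "light", 1600.0],
    ["female", 70, 120, "moderate", 1800.0],
    ["female", 70, 120, "heavy", 2000.0],
    ["male", 0, 3, "light", 850.0],
    ["male", 0, 3, "moderate", 950.0],
    ["male", 0, 3, "heavy", 1050.0],
    ["male", 4, 6, "light", 1250.0],
    ["male", 4, 6, "moderate", 1350.0],
    ["male", 4, 6, "heavy", 1500.0],
    ["male", 7, 9, "light", 1600.0],
    ["male", 7, 9, "moderate", 1700.0],
    ["male", 7, 9, "heavy", 1900.0],
    ["male", 10, 13, "light", 1900.0],
    ["male", 10, 13, "moderate", 2100.0],
    ["male", 10, 13, "heavy", 2300.0],
    ["male", 14, 18, "light", 2400.0],
    ["male", 14, 18, "moderate", 2700.0],
    ["male", 14, 18, "heavy", 3000.0],
    ["male", 19, 30, "light", 2500.0],
    ["male", 19, 30, "moderate", 2900.0],
    ["male", 19, 30, "heavy", 3300.0],
    ["male", 31, 50, "light", 2400.0],
    ["male", 31, 50, "moderate", 2800.0],
    ["male", 31, 50, "heavy", 3200.0],
    ["male", 51, 69, "light", 2200.0],
    ["male", 51, 69, "moderate", 2500.0],
    ["male", 51, 69, "heavy", 2800.0],
    ["male", 70, 120, "light", 1900.0],
    ["male", 70, 120, "moderate", 2100.0],
    ["male", 70, 120, "heavy", 2400.0],
]

DEFAULT_REFERENCE_REQUIREMENT = 2200.0

# EARs for adult women of reproductive age.  Where only an RDA is conventional
# the EAR is RDA/1.2; CV defaults to 10% for all normal-CDF nutrients.  Iron
# uses a skewed (log-normal) absorbed-requirement distribution at 5%
# bioavailability; calcium is scored against an adequate intake of 1,000 mg.
DEFAULT_REQUIREMENTS: dict[str, dict[str, Any]] = {
    "protein": {"kind": "normal_ear", "ear": 39.2, "cv": 0.10, "unit": "g"},
    "vitamin_a": {"kind": "normal_ear", "ear": 500.0, "cv": 0.10, "unit": "ug"},
    "vitamin_c": {"kind": "normal_ear", "ear": 62.5, "cv": 0.10, "unit": "mg"},
    "vitamin_b6": {"kind": "normal_ear", "ear": 1.1, "cv": 0.10, "unit": "mg"},
    "vitamin_b12": {"kind": "normal_ear", "ear": 2.0, "cv": 0.10, "unit": "ug"},
    "vitamin_e": {"kind": "normal_ear", "ear": 12.0, "cv": 0.10, "unit": "mg"},
    "folate": {"kind": "normal_ear", "ear": 320.0, "cv": 0.10, "unit": "ug"},
    "iron": {
        "kind": "iron_full_probability",
        "median_absorbed_req": 1.46,
        "log_sd": 0.39,
        "bioavailability": 0.05,
        "unit": "mg",
    },
    "zinc": {"kind": "normal_ear", "ear": 6.7, "cv": 0.10, "unit": "mg"},
    "calcium": {"kind": "ai_threshold", "ai": 1000.0, "unit": "mg"},
    "magnesium": {"kind": "normal_ear", "ear": 255.0, "cv": 0.10, "unit": "mg"},
}

DEFAULT_THRESHOLDS: dict[str, float] = {
    "mpa_cutoff": 0.5,
    "dds_gram_threshold": 15.0,
    "dds_cutoff": 5,
    "loading_display_threshold": 0.20,
    "eigenvalue_retention": 1.0,
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the full default configuration tree."""
    return copy.deepcopy(
        {
            "nutrients": list(DEFAULT_NUTRIENTS),
            "requirements": DEFAULT_REQUIREMENTS,
            "energy_requirements": {
                "reference": DEFAULT_REFERENCE_REQUIREMENT,
                "rows": DEFAULT_ENERGY_ROWS,
            },
            "thresholds": DEFAULT_THRESHOLDS,
        }
    )


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config, filling unspecified sections with defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    for key, value in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    _validate(cfg)
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _validate(cfg: dict[str, Any]) -> None:
    missing = [n for n in cfg["nutrients"] if n not in cfg["requirements"]]
    if missing:
        raise ConfigError(f"nutrients without a requirement block: {missing}")
    ref = cfg["energy_requirements"]["reference"]
    if not ref or ref <= 0:
        raise ConfigError("energy_requirements.reference must be > 0")
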