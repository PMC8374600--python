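"""YAML engine configuration: measure labels, cooking constants, occasions.

Only presentation and policy knobs live here — measure *ids* (1–16) are
immutable, and overriding the fried/baked oil-absorption defaults is logged
as a warning because it changes nutrient totals.

Example config::

    measures:
      1: Vaso chico
      16: Cucharón chico
    cooking:
      oil_fractions:
        fried: 0.12
      default_oil_food: oil-sunflower
    occasions: [Desayuno, Almuerzo, Merienda, Cena, Postre]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml

from . import cooking
from .errors import ValidationError
from .measures import HouseholdMeasure, MEASURE_REGISTRY
from .session import DEFAULT_OCCASIONS

logger = logging.getLogger(__name__)

__all__ = ["EngineConfig", "load_config", "apply_config"]


@dataclass
class EngineConfig:
    measure_labels: dict[int, str] = field(default_factory=dict)
    oil_fractions: dict[str, Fraction] = field(default_factory=dict)
    default_oil_food: str | None = None
    occasions: tuple[str, ...] = DEFAULT_OCCASIONS


def load_config(path: str | Path) -> EngineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    labels = {}
    for mid, label in (raw.get("measures") or {}).items():
        mid = int(mid)
        if mid not in MEASURE_REGISTRY:
            raise ValidationError(f"config: measure id {mid} outside the fixed registry 1-16")
        labels[mid] = str(label)
    cooking_raw = raw.get("cooking") or {}
    fractions = {}
    for method, frac in (cooking_raw.get("oil_fractions") or {}).items():
        if method not in cooking.DEFAULT_OIL_FRACTIONS:
            raise ValidationError(f"config: unknown cooking method {method!r}")
        f = Fraction(str(frac))
        if not (0 <= f <= 1):
            raise ValidationError(f"config: oil fraction for {method!r} must be in [0, 1]")
        fractions[method] = f
    occasions = tuple(raw["occasions"]) if "occasions" in raw else DEFAULT_OCCASIONS
    return EngineConfig(
        measure_labels=labels,
        oil_fractions=fractions,
        default_oil_food=cooking_raw.get("default_oil_food"),
        occasions=occasions,
    )


def apply_config(config: EngineConfig) -> None:
    """Install the configuration process-wide (registry labels, oil rule)."""
    for mid, label in config.measure_labels.items():
        old = MEASURE_REGISTRY[mid]
        MEASURE_REGISTRY[mid] = HouseholdMeasure(mid, label, old.is_volume)
    for method, frac in config.oil_fractions.items():
        if frac != cooking.DEFAULT_OIL_FRACTIONS[method]:
            logger.warning(
                "oil fraction for %s overridden: %s -> %s (default changed by config)",
                method, cooking.DEFAULT_OIL_FRACTIONS[method], frac)
        cooking.DEFAULT_OIL_FRACTIONS[method] = frac
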