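"""Kinetic parameters, thresholds, and flat key-value config I/O.

Canonical units are fixed package-wide: time in days, concentration in
pg/ml, volume in ml.  Constructors that accept other units (e.g. renal
clearance in ml/min) convert explicitly and record the original value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

#: minutes per day — converts clearance printed in ml/min to ml/day
MINUTES_PER_DAY = 1440.0
#: pg per mg
PG_PER_MG = 1.0e9
#: pg per ug
PG_PER_UG = 1.0e6

_CONFIG_KEYS = {
    "k_prod_pg_per_day_per_capsule": "k_prod",
    "k_trans_per_day": "k_trans",
    "k_clr_ml_per_day": "k_clr",
    "lambda_per_day": "lambda_decay",
    "V1_ml": "V1",
    "V2_ml": "V2",
}

_THRESHOLD_KEYS = {
    "effector_threshold_pg_per_ml": "effector",
    "toxicity_threshold_pg_per_ml": "toxicity",
}


def ml_per_min_to_ml_per_day(x: float) -> float:
    """Convert a clearance from ml/min to the canonical ml/day."""
    return x * MINUTES_PER_DAY


@dataclass(frozen=True)
class PKParameters:
    """The five kinetic constants plus two compartment volumes.

    Attributes
    ----------
    k_prod : float
        Per-capsule IL2 production rate (pg/day per capsule).
    k_trans : float
        Intercompartmental (IP <-> blood) transport rate (1/day).
    k_clr : float
        Renal clearance (ml/day).
    lambda_decay : float
        Capsule decay rate from the foreign-body response (1/day).
    V1 : float
        IP fluid volume (ml).
    V2 : float
        Blood volume (ml).
    """

    k_prod: float
    k_trans: float
    k_clr: float
    lambda_decay: float
    V1: float
    V2: float

    def __post_init__(self) -> None:
        for name in ("k_prod", "k_trans", "k_clr", "lambda_decay", "V1", "V2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(
                    f"PKParameters.{name} must be strictly positive and finite, got {v!r}"
                )

    def replace(self, **kwargs: float) -> "PKParameters":
        return replace(self, **kwargs)

    def to_config(self) -> dict[str, float]:
        return {key: float(getattr(self, attr)) for key, attr in _CONFIG_KEYS.items()}

    @classmethod
    def from_config(cls, mapping: dict) -> "PKParameters":
        missing = [k for k in _CONFIG_KEYS if k not in mapping]
        if missing:
            raise KeyError(f"parameter config missing keys: {missing}")
        return cls(**{attr: float(mapping[key]) for key, attr in _CONFIG_KEYS.items()})


@dataclass(frozen=True)
class Thresholds:
    """Effector-T-cell activation and systemic-toxicity concentration thresholds.

    Numeric values are study inputs, not package defaults: the model itself
    carries no opinion about what IL2 level activates cytotoxic T cells.
    """

    effector: float
    toxicity: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.effector) and self.effector > 0):
            raise ValueError(f"effector threshold must be > 0, got {self.effector!r}")
        if self.toxicity is not None and not self.toxicity > self.effector:
            raise ValueError("toxicity threshold must exceed the effector threshold")


def load_config(path: str | Path) -> dict:
    """Load a flat YAML or JSON mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return data


def load_parameters(path: str | Path) -> tuple[PKParameters, Thresholds | None]:
    """Read a parameter config file; thresholds are returned when present."""
    data = load_config(path)
    params = PKParameters.from_config(data)
    thresholds = None
    if "effector_threshold_pg_per_ml" in data:
        thresholds = Thresholds(
            effector=float(data["effector_threshold_pg_per_ml"]),
            toxicity=(
                float(data["toxicity_threshold_pg_per_ml"])
                if "toxicity_threshold_pg_per_ml" in data
                else None
            ),
        )
    return params, thresholds


def save_parameters(
    params: PKParameters,
    path: str | Path,
    thresholds: Thresholds | None = None,
    extra: dict | None = None,
) -> None:
    data: dict = params.to_config()
    if thresholds is not None:
        data["effector_threshold_pg_per_ml"] = float(thresholds.effector)
        if thresholds.toxicity is not None:
            data["toxicity_threshold_pg_per_ml"] = float(thresholds.toxicity)
    if extra:
        data.update(extra)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
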