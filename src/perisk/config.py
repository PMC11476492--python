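"""Run configuration: YAML loading, validation and defaults.

A run config resolves the five cohort roles (simoa, elecsys, fused,
first_trimester, test), the pipeline options and one master seed from which
every stage seed is derived deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec, TransferParams

__all__ = ["RunConfig", "validate_config", "DEFAULT_COHORT_SHAPES"]

#: Default class counts per dataset role.
DEFAULT_COHORT_SHAPES = {
    "simoa": {"n_cases": 145, "n_controls": 559, "platform_mix": 1.0},
    "elecsys": {"n_cases": 169, "n_controls": 525, "platform_mix": 0.0},
    "first_trimester": {
        "n_cases": 65,
        "n_controls": 190,
        "platform_mix": 1.0,
        "gestational_day_range": [77, 97],
    },
    "test": {"n_cases": 130, "n_controls": 892, "platform_mix": 1.0},
}

_DEFAULTS = {
    "seed": 0,
    "output_dir": "results",
    "rounds": 10,
    "folds": 10,
    "threshold": 0.5,
    "grid_step": 0.01,
    "predictor": {"algorithm": "rf", "hyperparameters": {}},
    "imputer": {"min_pairs": 10, "use_relations": True},
    "calibration": {"rounds": 100, "folds": 3, "n_pairs": 24},
    "augmentation": {"method": "kmeans_smote", "target_ratio": 1.2, "k_neighbors": 5},
    "missing_rate": 0.25,
    "transfer": {"slope": 0.6, "intercept": 8.0, "noise_sd": 4.0},
    "cohorts": DEFAULT_COHORT_SHAPES,
}

_ROLE_SEED_OFFSET = {"simoa": 1, "elecsys": 2, "first_trimester": 3, "test": 4}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    rounds: int = 10
    folds: int = 10
    threshold: float = 0.5
    grid_step: float = 0.01
    predictor: dict = field(default_factory=lambda: dict(_DEFAULTS["predictor"]))
    imputer: dict = field(default_factory=lambda: dict(_DEFAULTS["imputer"]))
    calibration: dict = field(default_factory=lambda: dict(_DEFAULTS["calibration"]))
    augmentation: dict = field(default_factory=lambda: dict(_DEFAULTS["augmentation"]))
    missing_rate: float = 0.25
    transfer: dict = field(default_factory=lambda: dict(_DEFAULTS["transfer"]))
    cohorts: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COHORT_SHAPES.items()})

    def transfer_params(self) -> TransferParams:
        return TransferParams(**self.transfer)

    def cohort_spec(self, role: str) -> CohortSpec:
        if role not in self.cohorts:
            raise KeyError(f"unknown cohort role {role!r}")
        shape = dict(self.cohorts[role])
        shape.setdefault("missing_rate", self.missing_rate)
        if "gestational_day_range" in shape:
            shape["gestational_day_range"] = tuple(shape["gestational_day_range"])
        shape["transfer_params"] = self.transfer_params()
        shape["seed"] = self.seed * 1000 + _ROLE_SEED_OFFSET[role]
        return CohortSpec(**shape)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "rounds": self.rounds,
            "folds": self.folds,
            "threshold": self.threshold,
            "grid_step": self.grid_step,
            "predictor": self.predictor,
            "imputer": self.imputer,
            "calibration": self.calibration,
            "augmentation": self.augmentation,
            "missing_rate": self.missing_rate,
            "transfer": self.transfer,
            "cohorts": self.cohorts,
        }


def _deep_merge(base: dict, override: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(source=None) -> RunConfig:
    """Load, default-fill and range-check a config file, dict or None.

    An empty/missing source yields the all-defaults config. Out-of-range
    values raise a single ``ValueError`` itemizing every offending field.
    """
    if source is None:
        raw = {}
    elif isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping at top level")

    merged = _deep_merge(_DEFAULTS, raw)
    errors = []
    if not (0.0 < merged["threshold"] < 1.0):
        errors.append(f"threshold: must lie in (0, 1), got {merged['threshold']}")
    if not (0.0 <= merged["missing_rate"] < 1.0):
        errors.append(f"missing_rate: must lie in [0, 1), got {merged['missing_rate']}")
    if merged["rounds"] < 1:
        errors.append(f"rounds: must be >= 1, got {merged['rounds']}")
    if merged["folds"] < 2:
        errors.append(f"folds: must be >= 2, got {merged['folds']}")
    if not (0.0 < merged["grid_step"] <= 0.5):
        errors.append(f"grid_step: must lie in (0, 0.5], got {merged['grid_step']}")
    if merged["calibration"]["rounds"] < 1:
        errors.append("calibration.rounds: must be >= 1")
    if merged["calibration"]["n_pairs"] < 3:
        errors.append("calibration.n_pairs: must be >= 3")
    if merged["augmentation"]["target_ratio"] <= 0:
        errors.append("augmentation.target_ratio: must be positive")
    from .prediction import ALGORITHMS

    if merged["predictor"]["algorithm"] not in ALGORITHMS:
        errors.append(
            f"predictor.algorithm: must be one of {ALGORITHMS}, "
            f"got {merged['predictor']['algorithm']!r}"
        )
    for role, shape in merged["cohorts"].items():
        if role not in DEFAULT_COHORT_SHAPES:
            errors.append(f"cohorts.{role}: unknown role")
            continue
        if shape.get("n_cases", 1) < 1 or shape.get("n_controls", 1) < 1:
            errors.append(f"cohorts.{role}: class counts must be >= 1")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))

    known = set(_DEFAULTS)
    return RunConfig(**{k: v for k, v in merged.items() if k in known})
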