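"""Encode raw clinical records into the fixed 22-column design matrix.

The 14 collected variables are expanded to 22 numeric features: ethnicity is
one-hot encoded over five levels, BMI variables and their increase rate are
derived from the weights, gestational age is converted to days, and mean
arterial pressure (MAP) is derived from the two blood pressures as
``(systolic + 2 * diastolic) / 3``. Missing inputs propagate to missing
derived outputs. Min-max normalization covers every feature except PlGF.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ETHNICITY_LEVELS, HISTORY_COLUMNS

__all__ = [
    "FEATURE_COLUMNS",
    "ETHNICITY_FEATURES",
    "DERIVED_COLUMNS",
    "EncodedMatrix",
    "encode",
    "recompute_derived",
    "MinMaxNormalizer",
    "fit_normalizer",
]

ETHNICITY_FEATURES = [f"ethnicity_{lvl.lower()}" for lvl in ETHNICITY_LEVELS]

#: Fixed order of the 22 design-matrix columns.
FEATURE_COLUMNS = (
    ["age"]
    + ETHNICITY_FEATURES
    + [
        "height",
        "pre_pregnancy_weight",
        "current_weight",
        "pre_pregnancy_bmi",
        "current_bmi",
        "bmi_increase_rate",
    ]
    + list(HISTORY_COLUMNS)
    + ["gestational_day", "diastolic_pressure", "systolic_pressure", "map", "plgf"]
)

#: Features computed from other features; recomputed after imputation.
DERIVED_COLUMNS = ("pre_pregnancy_bmi", "current_bmi", "bmi_increase_rate", "map")

assert len(FEATURE_COLUMNS) == 22


@dataclass
class EncodedMatrix:
    """A 22-column numeric design matrix with optional labels and normalizer."""

    frame: pd.DataFrame
    labels: pd.Series | None = None
    normalizer: "MinMaxNormalizer | None" = None
    platform: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.frame.columns) != FEATURE_COLUMNS:
            raise ValueError("encoded frame must have the 22 canonical columns")
        if self.labels is not None and len(self.labels) != len(self.frame):
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "EncodedMatrix":
        return EncodedMatrix(
            frame=self.frame.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            normalizer=self.normalizer,
            platform=None if self.platform is None else self.platform.copy(),
        )

    def subset(self, idx) -> "EncodedMatrix":
        idx = np.asarray(idx)
        return EncodedMatrix(
            frame=self.frame.iloc[idx].reset_index(drop=True),
            labels=None
            if self.labels is None
            else self.labels.iloc[idx].reset_index(drop=True),
            normalizer=self.normalizer,
            platform=None
            if self.platform is None
            else self.platform.iloc[idx].reset_index(drop=True),
        )

    def without_labels(self) -> "EncodedMatrix":
        return EncodedMatrix(
            frame=self.frame.copy(), labels=None,
            normalizer=self.normalizer, platform=self.platform,
        )

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def encode(table: pd.DataFrame) -> EncodedMatrix:
    """Transform a raw cohort table into the canonical 22-feature matrix.

    Rows keep their order. Labels ('case' -> 1, 'control' -> 0) and the
    platform tag are carried alongside the matrix when present. Unknown
    ethnicity levels are mapped to 'other' with a warning; a non-positive
    height is a record-level error.
    """
    n = len(table)
    out = pd.DataFrame(index=range(n), columns=FEATURE_COLUMNS, dtype=float)

    height = pd.to_numeric(table["height"], errors="coerce")
    if (height.dropna() <= 0).any():
        bad = list(table.index[height.notna() & (height <= 0)])
        raise ValueError(f"non-positive height in records {bad}")

    eth = table["ethnicity"].astype(object)
    known = eth.isin(ETHNICITY_LEVELS) | eth.isna()
    if not known.all():
        warnings.warn(
            f"{int((~known).sum())} unknown ethnicity level(s) mapped to 'other'",
            stacklevel=2,
        )
        eth = eth.where(known, "other")
    for lvl, col in zip(ETHNICITY_LEVELS, ETHNICITY_FEATURES):
        out[col] = np.where(eth.isna(), np.nan, (eth == lvl).astype(float))

    for raw in (
        "age",
        "height",
        "pre_pregnancy_weight",
        "current_weight",
        "diastolic_pressure",
        "systolic_pressure",
        "plgf",
        *HISTORY_COLUMNS,
    ):
        out[raw] = pd.to_numeric(table[raw], errors="coerce").to_numpy(dtype=float)

    weeks = pd.to_numeric(table["gestational_weeks"], errors="coerce")
    days = pd.to_numeric(table["gestational_days"], errors="coerce")
    out["gestational_day"] = (7 * weeks + days).to_numpy(dtype=float)

    out = recompute_derived(out)

    labels = None
    if "label" in table.columns and table["label"].notna().any():
        labels = (
            table["label"].map({"case": 1, "control": 0, 1: 1, 0: 0}).astype(int)
        )
        labels = labels.reset_index(drop=True)
    platform = None
    if "platform" in table.columns:
        platform = table["platform"].reset_index(drop=True)
    return EncodedMatrix(frame=out, labels=labels, platform=platform)


def recompute_derived(frame: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute BMI variables and MAP from their parent columns."""
    frame = frame.copy()
    h2 = frame["height"] ** 2
    frame["pre_pregnancy_bmi"] = frame["pre_pregnancy_weight"] / h2
    frame["current_bmi"] = frame["current_weight"] / h2
    frame["bmi_increase_rate"] = (
        frame["current_bmi"] - frame["pre_pregnancy_bmi"]
    ) / frame["pre_pregnancy_bmi"]
    frame["map"] = (frame["systolic_pressure"] + 2 * frame["diastolic_pressure"]) / 3
    return frame


class MinMaxNormalizer:
    """Per-column min-max scaler that always leaves PlGF untouched.

    Fitted on training data; transforming out-of-range values (e.g. test
    records beyond the training minimum or maximum) clips to [0, 1].
    Constant columns are left unscaled with a warning.
    """

    EXCLUDED = ("plgf",)

    def __init__(self) -> None:
        self.mins: dict[str, float] = {}
        self.maxs: dict[str, float] = {}
        self._fitted = False

    @property
    def is_fitted(self) -> bool:
        return self._fitted

    def fit(self, frame: pd.DataFrame) -> "MinMaxNormalizer":
        self.mins, self.maxs = {}, {}
        self._fitted = True
        for col in frame.columns:
            if col in self.EXCLUDED:
                continue
            vals = frame[col].dropna()
            if vals.empty:
                warnings.warn(f"column {col!r} fully missing; left unscaled", stacklevel=2)
                continue
            lo, hi = float(vals.min()), float(vals.max())
            if lo == hi:
                warnings.warn(f"constant column {col!r} left unscaled", stacklevel=2)
                continue
            self.mins[col], self.maxs[col] = lo, hi
        return self

    def transform(self, frame: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
        if not self.is_fitted:
            raise RuntimeError("normalizer is not fitted")
        out = frame.copy()
        for col, lo in self.mins.items():
            hi = self.maxs[col]
            out[col] = (out[col] - lo) / (hi - lo)
            if clip:
                out[col] = out[col].clip(0.0, 1.0)
        return out

    def inverse_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col, lo in self.mins.items():
            hi = self.maxs[col]
            out[col] = out[col] * (hi - lo) + lo
        return out

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"mins": self.mins, "maxs": self.maxs}, indent=2, sort_keys=True
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "MinMaxNormalizer":
        if isinstance(payload, Path) or (
            isinstance(payload, str) and "\n" not in payload and Path(payload).exists()
        ):
            payload = Path(payload).read_text()
        d = json.loads(payload)
        norm = cls()
        norm.mins = {k: float(v) for k, v in d["mins"].items()}
        norm.maxs = {k: float(v) for k, v in d["maxs"].items()}
        norm._fitted = True
        return norm


def fit_normalizer(matrix: EncodedMatrix) -> EncodedMatrix:
    """Fit a min-max normalizer on the matrix and return the scaled copy."""
    norm = MinMaxNormalizer().fit(matrix.frame)
    out = matrix.copy()
    out.frame = norm.transform(matrix.frame, clip=False)
    out.normalizer = norm
    return out
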