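"""Synthetic clinical cohort and paired calibration-set generation.

Cohorts mimic the structure the downstream pipeline assumes: a rare case
class with lower placental growth factor (PlGF) and higher blood pressure /
weight, two strongly dependent feature pairs (pre-pregnancy vs. current
weight as a function of gestational age; diastolic vs. systolic pressure),
a five-level ethnicity factor, two measurement platforms related by a known
monotone transfer function, and missing-completely-at-random gaps.

All generating relations are recorded in :class:`CohortSpec`, so tests can
verify recovery of the ground truth (e.g. the blood-pressure affine relation
or the cross-platform PlGF transfer).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "ETHNICITY_LEVELS",
    "PLATFORMS",
    "RAW_COLUMNS",
    "TransferParams",
    "CohortSpec",
    "generate_cohort",
    "inject_missingness",
    "generate_calibration_set",
    "write_cohort",
    "read_cohort",
    "write_calibration_set",
    "read_calibration_set",
]

ETHNICITY_LEVELS = ("Han", "Uygur", "Kazak", "Hui", "other")
PLATFORMS = ("SiMoA", "Elecsys")

#: Column order of a raw cohort table (one row per pregnancy).
RAW_COLUMNS = [
    "age",
    "ethnicity",
    "height",
    "pre_pregnancy_weight",
    "current_weight",
    "pregnancy_history",
    "fertility_history",
    "pe_history",
    "family_pe_history",
    "hypertension_history",
    "gestational_weeks",
    "gestational_days",
    "diastolic_pressure",
    "systolic_pressure",
    "plgf",
    "platform",
    "label",
]

#: Columns that the missingness mechanism may never mask.
PROTECTED_COLUMNS = frozenset(
    {"label", "platform", "gestational_weeks", "gestational_days"}
)

HISTORY_COLUMNS = (
    "pregnancy_history",
    "fertility_history",
    "pe_history",
    "family_pe_history",
    "hypertension_history",
)

_HISTORY_BASE_RATES = {
    "pregnancy_history": 0.50,
    "fertility_history": 0.40,
    "pe_history": 0.02,
    "family_pe_history": 0.03,
    "hypertension_history": 0.05,
}

_DEFAULT_EFFECTS = {
    "plgf": -80.0,
    "diastolic_pressure": 12.0,
    "pre_pregnancy_weight": 5.0,
    "age": 1.5,
    "pregnancy_history": 0.05,
    "fertility_history": 0.05,
    "pe_history": 0.13,
    "family_pe_history": 0.09,
    "hypertension_history": 0.20,
}


@dataclass(frozen=True)
class TransferParams:
    """Affine transfer mapping SiMoA-scale PlGF to the Elecsys scale."""

    slope: float = 0.6
    intercept: float = 8.0
    noise_sd: float = 4.0

    def apply(self, simoa_values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        e = self.slope * np.asarray(simoa_values, dtype=float) + self.intercept
        if self.noise_sd > 0:
            e = e + rng.normal(0.0, self.noise_sd, size=e.shape)
        return np.maximum(e, 0.5)


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 145
    n_controls: int = 559
    missing_rate: float = 0.25
    platform_mix: float = 0.5
    gestational_day_range: tuple[int, int] = (77, 237)
    effect_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    pair_noise_sd: float = 3.0
    weight_gain_per_day: float = 0.045
    bp_slope: float = 1.0
    bp_intercept: float = 42.0
    transfer_params: TransferParams = field(default_factory=TransferParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must each be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.platform_mix <= 1.0):
            raise ValueError("platform_mix must lie in [0, 1]")
        if self.pair_noise_sd < 0:
            raise ValueError("pair_noise_sd must be >= 0")
        lo, hi = self.gestational_day_range
        if lo < 1 or hi < lo:
            raise ValueError("gestational_day_range must be a valid day interval")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gestational_day_range"] = list(self.gestational_day_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "transfer_params" in d and isinstance(d["transfer_params"], dict):
            d["transfer_params"] = TransferParams(**d["transfer_params"])
        if "gestational_day_range" in d:
            d["gestational_day_range"] = tuple(d["gestational_day_range"])
        return cls(**d)


def _tnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _generate_class(rng: np.random.Generator, n: int, spec: CohortSpec, is_case: bool):
    eff = dict(_DEFAULT_EFFECTS) if spec.effect_sizes is None else spec.effect_sizes

    def shift(name):
        return float(eff.get(name, 0.0)) if is_case else 0.0

    lo_day, hi_day = spec.gestational_day_range
    gest_day = rng.integers(lo_day, hi_day + 1, size=n)

    age = _tnorm(rng, 29.0 + shift("age"), 5.0, 18.0, 48.0, n)
    ethnicity = rng.choice(
        ETHNICITY_LEVELS, size=n, p=[0.45, 0.35, 0.10, 0.05, 0.05]
    )
    height = _tnorm(rng, 1.60, 0.06, 1.40, 1.90, n)
    # parents are rounded to the stored precision *before* the dependent
    # member is derived, so noiseless pair relations hold exactly on the table
    pre_w = np.round(
        _tnorm(rng, 58.0 + shift("pre_pregnancy_weight"), 9.0, 40.0, 110.0, n), 1
    )
    cur_w = pre_w + spec.weight_gain_per_day * gest_day
    if spec.pair_noise_sd > 0:
        cur_w = cur_w + rng.normal(0.0, spec.pair_noise_sd, size=n)

    dbp = np.round(_tnorm(rng, 72.0 + shift("diastolic_pressure"), 8.0, 50.0, 115.0, n), 0)
    sbp = spec.bp_slope * dbp + spec.bp_intercept
    if spec.pair_noise_sd > 0:
        sbp = np.maximum(sbp + rng.normal(0.0, spec.pair_noise_sd, size=n), dbp)

    plgf_simoa = _tnorm(rng, 160.0 + shift("plgf"), 55.0, 5.0, 1200.0, n)
    platform = np.where(
        rng.random(n) < spec.platform_mix, PLATFORMS[0], PLATFORMS[1]
    )
    plgf = plgf_simoa.copy()
    on_elecsys = platform == PLATFORMS[1]
    plgf[on_elecsys] = spec.transfer_params.apply(plgf_simoa[on_elecsys], rng)

    cols = {
        "age": np.round(age, 1),
        "ethnicity": ethnicity,
        "height": np.round(height, 2),
        "pre_pregnancy_weight": pre_w,
        "current_weight": np.round(cur_w, 1) if spec.pair_noise_sd > 0 else cur_w,
        "gestational_weeks": gest_day // 7,
        "gestational_days": gest_day % 7,
        "diastolic_pressure": dbp,
        "systolic_pressure": np.round(sbp, 0) if spec.pair_noise_sd > 0 else sbp,
        "plgf": np.round(plgf, 1),
        "platform": platform,
        "label": np.repeat("case" if is_case else "control", n),
    }
    for name in HISTORY_COLUMNS:
        p = float(np.clip(_HISTORY_BASE_RATES[name] + shift(name), 0.0, 1.0))
        cols[name] = rng.binomial(1, p, size=n)
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a labelled cohort table with exactly the requested class counts.

    Cases and controls are drawn from truncated normals shifted by
    ``spec.effect_sizes``; the two dependent feature pairs follow the affine /
    gain relations stored on the spec, with residual spread ``pair_noise_sd``.
    Missingness at ``spec.missing_rate`` is injected afterwards. Deterministic
    under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cases = _generate_class(rng, spec.n_cases, spec, True)
    controls = _generate_class(rng, spec.n_controls, spec, False)
    table = pd.concat([cases, controls], ignore_index=True)
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)[RAW_COLUMNS]
    if spec.missing_rate > 0:
        table = inject_missingness(
            table, spec.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    return table


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask a ``rate`` fraction of maskable cells completely at random.

    Label, platform and gestational-age columns are never masked. Returns a
    copy; deterministic under ``seed``.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    maskable = [c for c in out.columns if c not in PROTECTED_COLUMNS]
    mask = rng.random((len(out), len(maskable))) < rate
    for j, col in enumerate(maskable):
        col_mask = mask[:, j]
        if col_mask.any():
            if out[col].dtype.kind in "iu":
                out[col] = out[col].astype(float)
            out.loc[col_mask, col] = np.nan
    return out


def generate_calibration_set(
    n: int = 24,
    transfer_params: TransferParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate ``n`` complete paired PlGF measurements (simoa, elecsys).

    The Elecsys value is the affine transfer of the SiMoA value plus noise.
    ``n`` must be at least 3 so a 3-fold split is possible downstream.
    """
    if n < 3:
        raise ValueError("need at least 3 calibration pairs")
    tp = transfer_params or TransferParams()
    rng = np.random.default_rng(seed)
    s = _tnorm(rng, 160.0, 70.0, 5.0, 1200.0, n)
    e = tp.apply(s, rng)
    return pd.DataFrame({"simoa": s, "elecsys": e})


# ---------------------------------------------------------------------------
# delimited-text IO (empty field = missing value)

_FLOAT_FMT = "%.10g"


def write_cohort(table: pd.DataFrame, path, spec: CohortSpec | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(spec.to_dict(), indent=2, sort_keys=True) + "\n")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_calibration_set(pairs: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_calibration_set(path) -> pd.DataFrame:
    pairs = pd.read_csv(path)
    if pairs.isna().any().any():
        raise ValueError("calibration pairs must be complete")
    if (pairs <= 0).any().any():
        raise ValueError("calibration PlGF values must be positive")
    return pairs
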