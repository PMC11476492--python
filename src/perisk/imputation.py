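"""Dual-strategy missing-data imputation.

Training rows carry a class label, so independent features are filled with
the *intra-class* median; test rows carry no label and use the *overall*
training median. Two feature pairs are treated as strongly dependent —
(pre-pregnancy weight, current weight), stratified into five gestational-age
intervals, and (diastolic, systolic pressure) — and a missing member of a
pair is predicted from the present member through a small sigmoid regressor
fitted on complete pairs. Only when both members are missing does the median
strategy apply. Test-time pair imputation uses class-free (pooled) regressor
refits so that no label information is ever consulted.

Derived features (BMIs, BMI increase rate, MAP) are recomputed from their
imputed parents so the matrix stays internally consistent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import DERIVED_COLUMNS, FEATURE_COLUMNS, EncodedMatrix, recompute_derived
from .nets import SigmoidNet

logger = logging.getLogger(__name__)

__all__ = [
    "GESTATIONAL_STRATA_DAYS",
    "DEPENDENT_PAIRS",
    "ImputerConfig",
    "ImputationModel",
    "fit_imputer",
    "impute_train",
    "impute_test",
]

#: Five gestational-age strata (in days, inclusive): weeks 11-13+6, 14-18+6,
#: 19-23+6, 24-28+6 and 29-33+6. Records outside are clamped to the nearest.
GESTATIONAL_STRATA_DAYS = ((77, 97), (98, 132), (133, 167), (168, 202), (203, 237))

#: (name, feature_a, feature_b, stratified?) for the two dependent pairs.
DEPENDENT_PAIRS = (
    ("weight", "pre_pregnancy_weight", "current_weight", True),
    ("pressure", "diastolic_pressure", "systolic_pressure", False),
)

_PAIR_MEMBERS = {m for _, a, b, _ in DEPENDENT_PAIRS for m in (a, b)}

POOLED = "pooled"


def stratum_of(gestational_day: float) -> int:
    """Index of the gestational stratum containing (or nearest to) a day."""
    if not np.isfinite(gestational_day):
        return 0
    for i, (lo, hi) in enumerate(GESTATIONAL_STRATA_DAYS):
        if lo <= gestational_day <= hi:
            return i
    if gestational_day < GESTATIONAL_STRATA_DAYS[0][0]:
        return 0
    return len(GESTATIONAL_STRATA_DAYS) - 1


@dataclass(frozen=True)
class ImputerConfig:
    #: minimum complete pairs in a (pair, group, stratum) cell to fit regressors
    min_pairs: int = 10
    #: disable the relation regressors entirely (median-only imputation)
    use_relations: bool = True
    net_max_iter: int = 150
    seed: int = 0


@dataclass
class ImputationModel:
    """Fitted medians and pair-relation regressors.

    ``pair_nets`` maps ``(pair_name, group, stratum, direction)`` to a fitted
    :class:`SigmoidNet`, where group is a class label (0/1) or ``"pooled"``,
    stratum is an interval index (or ``None`` for the unstratified pair) and
    direction is ``"a_to_b"`` or ``"b_to_a"``.
    """

    intra_class_medians: dict = field(default_factory=dict)
    overall_medians: dict = field(default_factory=dict)
    pair_nets: dict = field(default_factory=dict)
    pair_counts: dict = field(default_factory=dict)
    strata_bounds: tuple = GESTATIONAL_STRATA_DAYS
    config: ImputerConfig = field(default_factory=ImputerConfig)

    def class_median(self, feature: str, label: int) -> float:
        med = self.intra_class_medians.get(feature, {}).get(int(label))
        if med is None or not np.isfinite(med):
            med = self.overall_median(feature)
            logger.info(
                "feature %r has no class-%d median; overall median used", feature, label
            )
        return med

    def overall_median(self, feature: str) -> float:
        if feature not in self.overall_medians:
            raise KeyError(f"feature {feature!r} absent from imputation model")
        med = self.overall_medians[feature]
        if med is None or not np.isfinite(med):
            raise ValueError(f"feature {feature!r} has no observed training values")
        return med

    def net(self, pair: str, group, stratum, direction: str) -> SigmoidNet | None:
        return self.pair_nets.get((pair, group, stratum, direction))

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "intra_class_medians": {
                f: {str(k): v for k, v in d.items()}
                for f, d in self.intra_class_medians.items()
            },
            "overall_medians": self.overall_medians,
            "strata_bounds": [list(b) for b in self.strata_bounds],
            "pair_counts": {
                "|".join(map(str, k)): v for k, v in self.pair_counts.items()
            },
            "pair_nets": {
                "|".join(map(str, k)): net.to_dict()
                for k, net in self.pair_nets.items()
            },
            "config": {
                "min_pairs": self.config.min_pairs,
                "use_relations": self.config.use_relations,
                "net_max_iter": self.config.net_max_iter,
                "seed": self.config.seed,
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, payload: str | Path) -> "ImputationModel":
        if isinstance(payload, Path):
            payload = payload.read_text()
        d = json.loads(payload)

        def _key(s: str):
            pair, group, stratum, direction = s.split("|")
            group = int(group) if group in ("0", "1") else group
            stratum = None if stratum == "None" else int(stratum)
            return (pair, group, stratum, direction)

        model = cls(
            intra_class_medians={
                f: {int(k): v for k, v in dd.items()}
                for f, dd in d["intra_class_medians"].items()
            },
            overall_medians=d["overall_medians"],
            strata_bounds=tuple(tuple(b) for b in d["strata_bounds"]),
            config=ImputerConfig(**d["config"]),
        )
        model.pair_counts = {_key(k): v for k, v in d["pair_counts"].items()}
        model.pair_nets = {
            _key(k): SigmoidNet.from_dict(v) for k, v in d["pair_nets"].items()
        }
        return model


def _median_or_none(values: pd.Series):
    vals = values.dropna().to_numpy(dtype=float)
    return float(np.median(vals)) if vals.size else None


def _fit_pair_cell(model, frame, rows, pair, a, b, group, stratum, cfg, net_seed):
    both = rows & frame[a].notna() & frame[b].notna()
    n = int(both.sum())
    model.pair_counts[(pair, group, stratum, "a_to_b")] = n
    model.pair_counts[(pair, group, stratum, "b_to_a")] = n
    if n < max(cfg.min_pairs, 2):
        return
    xa = frame.loc[both, a].to_numpy(dtype=float)
    xb = frame.loc[both, b].to_numpy(dtype=float)
    fwd = SigmoidNet(max_iter=cfg.net_max_iter, seed=net_seed).fit(xa, xb)
    bwd = SigmoidNet(max_iter=cfg.net_max_iter, seed=net_seed + 1).fit(xb, xa)
    model.pair_nets[(pair, group, stratum, "a_to_b")] = fwd
    model.pair_nets[(pair, group, stratum, "b_to_a")] = bwd


def fit_imputer(
    train: EncodedMatrix, config: ImputerConfig | None = None
) -> ImputationModel:
    """Fit medians and pair-relation regressors on labelled training data.

    Medians are computed over non-missing values only; a regressor cell is
    fitted only when it holds at least ``config.min_pairs`` complete pairs,
    otherwise imputation in that cell falls back to medians.
    """
    if train.labels is None:
        raise ValueError("fit_imputer requires a labelled training matrix")
    cfg = config or ImputerConfig()
    frame = train.frame
    y = train.labels.to_numpy()
    model = ImputationModel(config=cfg)

    for feat in FEATURE_COLUMNS:
        model.overall_medians[feat] = _median_or_none(frame[feat])
        per_class = {}
        for label in (0, 1):
            med = _median_or_none(frame[feat][y == label])
            if med is None and model.overall_medians[feat] is not None:
                warnings.warn(
                    f"feature {feat!r} unobserved in class {label}; "
                    "falling back to overall median",
                    stacklevel=2,
                )
            per_class[label] = med
        model.intra_class_medians[feat] = per_class

    if not cfg.use_relations:
        return model

    gest_strat = frame["gestational_day"].map(stratum_of)
    seed = cfg.seed
    for pair, a, b, stratified in DEPENDENT_PAIRS:
        strata = list(range(len(GESTATIONAL_STRATA_DAYS))) if stratified else [None]
        for stratum in strata:
            in_stratum = (
                pd.Series(True, index=frame.index)
                if stratum is None
                else (gest_strat == stratum)
            )
            for group in (0, 1, POOLED):
                rows = in_stratum if group == POOLED else in_stratum & (y == group)
                _fit_pair_cell(
                    model, frame, rows, pair, a, b, group, stratum, cfg, seed
                )
                seed += 2
    return model


def _fill_pairs(frame, model, group_of_row, gest_strat):
    """Impute dependent pairs in place; returns mask of rows already handled."""
    for pair, a, b, stratified in DEPENDENT_PAIRS:
        ma, mb = frame[a].isna(), frame[b].isna()

        for idx in frame.index[ma & ~mb]:  # predict a from b
            group = group_of_row(idx)
            stratum = gest_strat[idx] if stratified else None
            net = model.net(pair, group, stratum, "b_to_a")
            if net is not None:
                frame.at[idx, a] = net.predict(float(frame.at[idx, b]))
            else:
                frame.at[idx, a] = _median_for(model, a, group)
        for idx in frame.index[mb & ~ma]:  # predict b from a
            group = group_of_row(idx)
            stratum = gest_strat[idx] if stratified else None
            net = model.net(pair, group, stratum, "a_to_b")
            if net is not None:
                frame.at[idx, b] = net.predict(float(frame.at[idx, a]))
            else:
                frame.at[idx, b] = _median_for(model, b, group)
        for idx in frame.index[ma & mb]:  # both missing -> medians
            group = group_of_row(idx)
            frame.at[idx, a] = _median_for(model, a, group)
            frame.at[idx, b] = _median_for(model, b, group)


def _median_for(model: ImputationModel, feature: str, group) -> float:
    if group == POOLED:
        return model.overall_median(feature)
    return model.class_median(feature, group)


def _impute_frame(matrix: EncodedMatrix, model: ImputationModel, pooled: bool):
    frame = matrix.frame.copy()
    gest_strat = frame["gestational_day"].map(stratum_of)

    if pooled:
        def group_of_row(idx):
            return POOLED
    else:
        y = matrix.labels

        def group_of_row(idx):
            return int(y.iloc[idx])

    _fill_pairs(frame, model, group_of_row, gest_strat)

    independent = [
        c
        for c in FEATURE_COLUMNS
        if c not in _PAIR_MEMBERS and c not in DERIVED_COLUMNS
    ]
    for feat in independent:
        missing = frame[feat].isna()
        if not missing.any():
            continue
        if pooled:
            frame.loc[missing, feat] = model.overall_median(feat)
        else:
            for label in (0, 1):
                rows = missing & (matrix.labels.to_numpy() == label)
                if rows.any():
                    frame.loc[rows, feat] = model.class_median(feat, label)

    frame = recompute_derived(frame)
    # derived columns are complete once their parents are; guard regardless
    for feat in DERIVED_COLUMNS:
        missing = frame[feat].isna()
        if missing.any():
            frame.loc[missing, feat] = model.overall_median(feat)

    out = matrix.copy()
    out.frame = frame
    return out


def impute_train(train: EncodedMatrix, model: ImputationModel) -> EncodedMatrix:
    """Impute a labelled training matrix using each record's own class.

    Independent features get the intra-class median; a missing dependent-pair
    member is predicted from its present partner via the class-specific
    relation regressor (stratified by gestational interval for the weight
    pair); when both members are missing, intra-class medians apply.
    The output contains no missing entries.
    """
    if train.labels is None:
        raise ValueError("impute_train requires labels")
    return _impute_frame(train, model, pooled=False)


def impute_test(test: EncodedMatrix, model: ImputationModel) -> EncodedMatrix:
    """Impute a test matrix without consulting any label.

    Independent features get the overall training median; dependent-pair
    members use the pooled (class-free) relation regressors when the partner
    is present, overall medians otherwise.
    """
    return _impute_frame(test.without_labels(), model, pooled=True)
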