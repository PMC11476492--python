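"""Bi-platform PlGF calibration via median-model selection.

For a small set of paired measurements (one value per platform per sample),
two directional pools of 1-2-1 sigmoid regressors are trained under repeated
3-fold cross-validation: forward (SiMoA -> Elecsys) and backward
(Elecsys -> SiMoA). Each candidate is scored by held-out mean squared error,
the model at the median rank of each pool is selected, and the direction
whose selected model has the smaller MSE wins. The output side of the
winning direction becomes the reference platform: its values pass through
unchanged, while values from the other platform are mapped through the
selected regressor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .cohort import PLATFORMS
from .nets import SigmoidNet

__all__ = [
    "DIRECTION_FORWARD",
    "DIRECTION_BACKWARD",
    "CalibrationModel",
    "fit_calibrators",
    "select_median_model",
    "calibrate",
]

DIRECTION_FORWARD = "simoa_to_elecsys"  # input SiMoA, output Elecsys
DIRECTION_BACKWARD = "elecsys_to_simoa"  # input Elecsys, output SiMoA

_OUTPUT_PLATFORM = {DIRECTION_FORWARD: PLATFORMS[1], DIRECTION_BACKWARD: PLATFORMS[0]}
_INPUT_PLATFORM = {DIRECTION_FORWARD: PLATFORMS[0], DIRECTION_BACKWARD: PLATFORMS[1]}


def select_median_model(pool: list[tuple]) -> tuple:
    """Return the (model, mse) entry at the median rank of held-out MSE.

    Entries are ranked ascending by MSE with a stable sort, so ties resolve
    to the earlier pool index. Even-sized pools return the lower-middle rank
    (rank n/2, 1-based), i.e. the better of the two middle models.
    """
    if not pool:
        raise ValueError("empty model pool")
    median_mse = sorted(m for _, m in pool)[(len(pool) - 1) // 2]
    return next(entry for entry in pool if entry[1] == median_mse)


@dataclass
class CalibrationModel:
    """Selected directional regressor plus full pool diagnostics."""

    direction: str
    selected: SigmoidNet
    mse_forward: float
    mse_backward: float
    pool_mses: dict = field(default_factory=dict)  # direction -> list of MSEs
    rounds: int = 100
    folds: int = 3
    seed: int = 0

    @property
    def reference_platform(self) -> str:
        return _OUTPUT_PLATFORM[self.direction]

    @property
    def calibrated_platform(self) -> str:
        return _INPUT_PLATFORM[self.direction]

    def report(self) -> dict:
        return {
            "direction": self.direction,
            "reference_platform": self.reference_platform,
            "selected_mse": {
                DIRECTION_FORWARD: self.mse_forward,
                DIRECTION_BACKWARD: self.mse_backward,
            },
            "pool_size": {d: len(m) for d, m in self.pool_mses.items()},
            "pool_mses": self.pool_mses,
            "rounds": self.rounds,
            "folds": self.folds,
            "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        payload = dict(self.report(), selected_net=self.selected.to_dict())
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, payload: str | Path) -> "CalibrationModel":
        if isinstance(payload, Path):
            payload = payload.read_text()
        d = json.loads(payload)
        return cls(
            direction=d["direction"],
            selected=SigmoidNet.from_dict(d["selected_net"]),
            mse_forward=d["selected_mse"][DIRECTION_FORWARD],
            mse_backward=d["selected_mse"][DIRECTION_BACKWARD],
            pool_mses=d["pool_mses"],
            rounds=d["rounds"],
            folds=d["folds"],
            seed=d["seed"],
        )


def _directional_pool(x, y, rounds, folds, rng, max_iter):
    pool = []
    for _ in range(rounds):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        for train_idx, test_idx in kf.split(x):
            net = SigmoidNet(max_iter=max_iter, seed=int(rng.integers(0, 2**31 - 1)))
            net.fit(x[train_idx], y[train_idx])
            pool.append((net, net.mse(x[test_idx], y[test_idx])))
    return pool


def fit_calibrators(
    pairs: pd.DataFrame,
    rounds: int = 100,
    folds: int = 3,
    seed: int = 0,
    max_iter: int = 150,
) -> CalibrationModel:
    """Train both directional pools under repeated k-fold CV and pick a model.

    ``pairs`` must hold complete positive columns ``simoa`` and ``elecsys``.
    Each direction yields ``rounds * folds`` candidates scored by held-out
    MSE on the raw pg/mL scale; the median-rank model of each pool is
    selected, and the direction with the smaller selected MSE is deployed
    (ties prefer Elecsys -> SiMoA).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    s = pairs["simoa"].to_numpy(dtype=float)
    e = pairs["elecsys"].to_numpy(dtype=float)
    if s.size < folds:
        raise ValueError(f"need at least {folds} pairs for {folds}-fold CV")
    if not (np.isfinite(s).all() and np.isfinite(e).all()):
        raise ValueError("non-finite PlGF value in calibration pairs")

    rng = np.random.default_rng(seed)
    pool_fwd = _directional_pool(s, e, rounds, folds, rng, max_iter)
    pool_bwd = _directional_pool(e, s, rounds, folds, rng, max_iter)

    sel_fwd, mse_fwd = select_median_model(pool_fwd)
    sel_bwd, mse_bwd = select_median_model(pool_bwd)
    if mse_bwd <= mse_fwd:  # tie prefers calibrating Elecsys onto SiMoA
        direction, selected = DIRECTION_BACKWARD, sel_bwd
    else:
        direction, selected = DIRECTION_FORWARD, sel_fwd

    return CalibrationModel(
        direction=direction,
        selected=selected,
        mse_forward=mse_fwd,
        mse_backward=mse_bwd,
        pool_mses={
            DIRECTION_FORWARD: [m for _, m in pool_fwd],
            DIRECTION_BACKWARD: [m for _, m in pool_bwd],
        },
        rounds=rounds,
        folds=folds,
        seed=seed,
    )


def calibrate(plgf, platform, model: CalibrationModel):
    """Map PlGF values onto the reference-platform scale.

    Values already on the reference platform are returned unchanged; values
    from the other platform pass through the selected regressor. ``plgf``
    may be a scalar or an array (with matching scalar/array ``platform``).
    """
    values = np.asarray(plgf, dtype=float)
    scalar = values.ndim == 0
    values = np.atleast_1d(values).astype(float)
    plats = np.atleast_1d(np.asarray(platform, dtype=object))
    if plats.size == 1 and values.size > 1:
        plats = np.repeat(plats, values.size)
    if plats.size != values.size:
        raise ValueError("platform and plgf lengths differ")
    unknown = set(plats[pd.notna(plats)]) - set(PLATFORMS)
    if unknown:
        raise ValueError(f"unknown platform tag(s): {sorted(unknown)}")

    out = values.copy()
    needs = (plats == model.calibrated_platform) & np.isfinite(values)
    if needs.any():
        out[needs] = model.selected.predict(values[needs])
    return float(out[0]) if scalar else out
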