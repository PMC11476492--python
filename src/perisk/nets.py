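"""Small sigmoid regression networks shared by imputation and calibration.

A :class:`SigmoidNet` is a one-input, two-hidden-unit, one-output regressor
with logistic hidden activations and a linear output. Inputs and targets are
z-scored before fitting and the prediction is mapped back to the raw scale;
the raw pg/mL or kg scales are otherwise far outside the useful range of the
logistic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["SigmoidNet"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class SigmoidNet:
    """1-2-1 regressor: linear(w2 . sigmoid(w1*x + b1) + b2) on z-scored data."""

    hidden_units: int = 2
    #: Levenberg-Marquardt function-evaluation cap per restart
    max_iter: int = 150
    #: random restarts; the lowest-cost solution wins
    restarts: int = 2
    seed: int = 0

    w1: np.ndarray = field(default=None, repr=False)  # (hidden,)
    b1: np.ndarray = field(default=None, repr=False)
    w2: np.ndarray = field(default=None, repr=False)
    b2: float = 0.0
    x_mean: float = 0.0
    x_std: float = 1.0
    y_mean: float = 0.0
    y_std: float = 1.0
    n_fit: int = 0

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SigmoidNet":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size or x.size < 2:
            raise ValueError("need at least two (x, y) pairs with equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training pairs")
        self.x_mean, self.x_std = float(x.mean()), float(x.std())
        self.y_mean, self.y_std = float(y.mean()), float(y.std())
        if self.x_std == 0.0:
            self.x_std = 1.0
        if self.y_std == 0.0:
            self.y_std = 1.0
        xs = (x - self.x_mean) / self.x_std
        ys = (y - self.y_mean) / self.y_std
        h = self.hidden_units
        rng = np.random.default_rng(self.seed)

        def residuals(p):
            hidden = _sigmoid(np.outer(xs, p[:h]) + p[h : 2 * h])
            return hidden @ p[2 * h : 3 * h] + p[3 * h] - ys

        def jacobian(p):
            hidden = _sigmoid(np.outer(xs, p[:h]) + p[h : 2 * h])
            dhid = hidden * (1.0 - hidden) * p[2 * h : 3 * h]
            jac = np.empty((xs.size, 3 * h + 1))
            jac[:, :h] = dhid * xs[:, None]
            jac[:, h : 2 * h] = dhid
            jac[:, 2 * h : 3 * h] = hidden
            jac[:, 3 * h] = 1.0
            return jac

        # LM needs at least as many residuals as parameters
        method = "lm" if xs.size >= 3 * h + 2 else "trf"
        best = None
        for _ in range(max(1, self.restarts)):
            p0 = rng.normal(0.0, 1.0, 3 * h + 1)
            sol = least_squares(
                residuals, p0, jac=jacobian, method=method, max_nfev=self.max_iter
            )
            if best is None or sol.cost < best.cost:
                best = sol
        p = best.x
        self.w1 = p[:h].copy()
        self.b1 = p[h : 2 * h].copy()
        self.w2 = p[2 * h : 3 * h].copy()
        self.b2 = float(p[3 * h])
        self.n_fit = int(x.size)
        return self

    @property
    def is_fitted(self) -> bool:
        return self.w1 is not None

    def predict(self, x) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError("SigmoidNet is not fitted")
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xs = (np.atleast_1d(x).astype(float) - self.x_mean) / self.x_std
        h = _sigmoid(np.outer(xs, self.w1) + self.b1)
        ys = h @ self.w2 + self.b2
        y = ys * self.y_std + self.y_mean
        return float(y[0]) if scalar else y

    def mse(self, x, y) -> float:
        """Mean squared prediction error on the raw target scale."""
        y = np.asarray(y, dtype=float).ravel()
        return float(np.mean((self.predict(np.asarray(x)) - y) ** 2))

    def to_dict(self) -> dict:
        if not self.is_fitted:
            raise RuntimeError("SigmoidNet is not fitted")
        return {
            "hidden_units": self.hidden_units,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean,
            "x_std": self.x_std,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "n_fit": self.n_fit,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SigmoidNet":
        net = cls(hidden_units=int(d["hidden_units"]), seed=int(d.get("seed", 0)))
        net.w1 = np.asarray(d["w1"], dtype=float)
        net.b1 = np.asarray(d["b1"], dtype=float)
        net.w2 = np.asarray(d["w2"], dtype=float)
        net.b2 = float(d["b2"])
        net.x_mean = float(d["x_mean"])
        net.x_std = float(d["x_std"])
        net.y_mean = float(d["y_mean"])
        net.y_std = float(d["y_std"])
        net.n_fit = int(d.get("n_fit", 0))
        return net
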