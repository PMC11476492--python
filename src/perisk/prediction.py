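"""Risk classifiers, output thresholding and feature-importance ranking.

Random forest is the primary algorithm; a multilayer perceptron, a support
vector machine, gradient boosting and adaptive boosting serve as
comparators. Every model exposes a continuous risk score in [0, 1]; a binary
call is the score compared against a decision threshold, which by default is
0.5 but can be optimized on out-of-fold F1 over a grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .evaluation import (
    f1_from_counts,
    median_abs_deviation,
    median_low,
    round_folds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "PredictorConfig",
    "RiskModel",
    "ThresholdSearchResult",
    "train_model",
    "predict_risk",
    "optimize_threshold",
    "feature_importance",
    "default_threshold_grid",
]

ALGORITHMS = ("rf", "mlp", "svm", "xgb", "ada")


@dataclass(frozen=True)
class PredictorConfig:
    algorithm: str = "rf"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly inside (0, 1)")

    def replace(self, **kw) -> "PredictorConfig":
        d = {
            "algorithm": self.algorithm,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
            "threshold": self.threshold,
        }
        d.update(kw)
        return PredictorConfig(**d)


def _build_estimator(config: PredictorConfig):
    hp = dict(config.hyperparameters)
    seed = config.seed
    if config.algorithm == "rf":
        hp.setdefault("n_estimators", 500)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, **hp)
    if config.algorithm == "mlp":
        hp.setdefault("hidden_layer_sizes", (32,))
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **hp)
    if config.algorithm == "svm":
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    if config.algorithm == "xgb":
        # gradient-boosted trees; the scikit-learn implementation stands in
        # for the XGBoost library behind the same config surface
        return GradientBoostingClassifier(random_state=seed, **hp)
    if config.algorithm == "ada":
        return AdaBoostClassifier(random_state=seed, **hp)
    raise ValueError(config.algorithm)


@dataclass
class RiskModel:
    estimator: object
    config: PredictorConfig
    feature_names: list[str]

    def scores(self, X) -> np.ndarray:
        X = self._check(X)
        return self.estimator.predict_proba(X)[:, 1]

    def _check(self, X) -> np.ndarray:
        if hasattr(X, "frame"):
            cols = list(X.frame.columns)
            if cols != self.feature_names:
                raise ValueError("feature schema mismatch with training matrix")
            X = X.frame
        if hasattr(X, "columns"):
            if list(X.columns) != self.feature_names:
                raise ValueError("feature schema mismatch with training matrix")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError("feature schema mismatch with training matrix")
        if np.isnan(X).any():
            raise ValueError("missing entries in feature matrix; impute first")
        return X

    def save(self, path) -> None:
        """Persist the estimator (binary) plus a JSON manifest alongside."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, path)
        manifest = {
            "algorithm": self.config.algorithm,
            "hyperparameters": self.config.hyperparameters,
            "seed": self.config.seed,
            "threshold": self.config.threshold,
            "feature_names": self.feature_names,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path) -> "RiskModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        config = PredictorConfig(
            algorithm=manifest["algorithm"],
            hyperparameters=manifest["hyperparameters"],
            seed=manifest["seed"],
            threshold=manifest["threshold"],
        )
        return cls(
            estimator=joblib.load(path),
            config=config,
            feature_names=manifest["feature_names"],
        )


def _as_xy(features, labels=None):
    if hasattr(features, "frame"):
        names = list(features.frame.columns)
        if labels is None and features.labels is not None:
            labels = features.labels
        X = features.frame.to_numpy(dtype=float)
    elif hasattr(features, "columns"):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = None if labels is None else np.asarray(labels, dtype=int)
    return X, y, names


def train_model(features, labels=None, config: PredictorConfig | None = None) -> RiskModel:
    """Fit a risk classifier on a complete, normalized design matrix.

    Raises if the matrix still has missing entries (imputation is upstream)
    or if only one class is present. Deterministic under ``config.seed``.
    """
    config = config or PredictorConfig()
    X, y, names = _as_xy(features, labels)
    if y is None:
        raise ValueError("labels are required to train a model")
    if np.isnan(X).any():
        raise ValueError("missing entries in feature matrix; impute first")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _build_estimator(config)
    est.fit(X, y)
    return RiskModel(estimator=est, config=config, feature_names=names)


def predict_risk(model: RiskModel, features, threshold: float | None = None):
    """Return (scores in [0, 1], binary calls); call = score >= threshold."""
    t = model.config.threshold if threshold is None else float(threshold)
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    scores = model.scores(features)
    return scores, (scores >= t).astype(int)


def default_threshold_grid(step: float = 0.01) -> np.ndarray:
    if not (0.0 < step <= 0.5):
        raise ValueError("grid step must lie in (0, 0.5]")
    n = int(round((0.99 - 0.01) / step))
    return np.round(0.01 + step * np.arange(n + 1), 10)


def best_threshold_for_scores(y: np.ndarray, scores: np.ndarray, grid: np.ndarray):
    """Exhaustively maximize F1 of (score >= t) over the grid.

    Ties resolve to the smallest threshold, which maximizes TPR at equal F1.
    """
    best_t, best_f1 = None, -1.0
    for t in grid:
        calls = scores >= t
        tp = int(np.sum(calls & (y == 1)))
        fp = int(np.sum(calls & (y == 0)))
        fn = int(np.sum(~calls & (y == 1)))
        f1 = f1_from_counts(tp, fp, fn)
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


@dataclass
class ThresholdSearchResult:
    per_round_optima: list[float]
    median: float
    deviation: float
    criterion: str = "f1"
    grid_step: float = 0.01
    per_round_f1: list[float] = field(default_factory=list)
    #: pooled out-of-fold scores per round (kept for oracle re-checking)
    per_round_scores: list = field(default_factory=list)
    labels: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "criterion": self.criterion,
            "median": self.median,
            "deviation": self.deviation,
            "per_round_optima": self.per_round_optima,
        }


def optimize_threshold(
    features,
    labels=None,
    config: PredictorConfig | None = None,
    rounds: int = 10,
    folds: int = 10,
    grid_step: float = 0.01,
    seed: int = 0,
    stratified: bool = False,
) -> ThresholdSearchResult:
    """Search the F1-optimal output threshold under repeated k-fold CV.

    Per round, out-of-fold scores from all folds are pooled and the grid
    threshold maximizing pooled F1 is recorded; the summary is the median of
    the per-round optima with the median absolute deviation about it.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    config = config or PredictorConfig()
    X, y, names = _as_xy(features, labels)
    grid = default_threshold_grid(grid_step)
    rng = np.random.default_rng(seed)

    optima, f1s, oofs = [], [], []
    for _ in range(rounds):
        splits = round_folds(y, folds, rng, stratified=stratified)
        oof = np.empty(len(y))
        for tr, te in splits:
            model = train_model(X[tr], y[tr], config)
            oof[te] = model.scores(X[te])
        t, f1 = best_threshold_for_scores(y, oof, grid)
        optima.append(t)
        f1s.append(f1)
        oofs.append(oof)

    return ThresholdSearchResult(
        per_round_optima=optima,
        median=median_low(optima),
        deviation=median_abs_deviation(optima),
        grid_step=grid_step,
        per_round_f1=f1s,
        per_round_scores=oofs,
        labels=y,
    )


def feature_importance(model: RiskModel, feature_names=None) -> list[tuple[str, float]]:
    """Ranked (name, importance) pairs from a fitted forest model.

    Importances are impurity-based, non-negative and sum to one; ties break
    by column order. Raises for non-forest models.
    """
    if not isinstance(model.estimator, RandomForestClassifier):
        raise TypeError("feature importance requires a random-forest model")
    names = list(feature_names) if feature_names is not None else model.feature_names
    imp = model.estimator.feature_importances_
    if len(names) != len(imp):
        raise ValueError("feature name count does not match the model")
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], i))
    return [(names[i], float(imp[i])) for i in order]
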