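"""Minority-class oversampling by interpolation.

Two variants are implemented natively: plain nearest-neighbor interpolation
(SMOTE) and a cluster-aware variant that first clusters the minority class
with k-means and interpolates only within clusters. Additional samplers can
be registered as pluggable backends. Synthetic rows are convex combinations
of existing minority rows, are appended after the untouched originals, and
carry an explicit origin flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

__all__ = ["AugmentationConfig", "augment", "make_augmenter", "register_backend"]

#: pluggable samplers: name -> callable(X_min, n_new, k, rng, config) -> ndarray
_BACKENDS: dict = {}


def register_backend(name: str, sampler) -> None:
    _BACKENDS[name] = sampler


@dataclass(frozen=True)
class AugmentationConfig:
    method: str = "kmeans_smote"
    #: desired minority/majority count ratio after augmentation
    target_ratio: float = 1.2
    k_neighbors: int = 5
    #: cluster count for the cluster-aware variant; None -> round(sqrt(n_min))
    n_clusters: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _interpolate(x_base: np.ndarray, x_neigh: np.ndarray, rng) -> np.ndarray:
    gaps = rng.random((len(x_base), 1))
    return x_base + gaps * (x_neigh - x_base)


def _smote_samples(x_min: np.ndarray, n_new: int, k: int, rng) -> np.ndarray:
    if len(x_min) == 1:
        return np.repeat(x_min, n_new, axis=0)
    k_eff = min(k, len(x_min) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x_min)
    neigh = nn.kneighbors(x_min, return_distance=False)[:, 1:]
    base_idx = rng.integers(0, len(x_min), size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    neigh_idx = neigh[base_idx, pick]
    return _interpolate(x_min[base_idx], x_min[neigh_idx], rng)


def _kmeans_smote_samples(
    x_min: np.ndarray, n_new: int, k: int, rng, n_clusters: int | None
) -> np.ndarray:
    if len(x_min) == 1:
        return np.repeat(x_min, n_new, axis=0)
    kc = n_clusters or max(1, int(round(np.sqrt(len(x_min)))))
    kc = min(kc, len(x_min))
    km = KMeans(n_clusters=kc, n_init=10, random_state=int(rng.integers(0, 2**31 - 1)))
    assign = km.fit_predict(x_min)
    sizes = np.bincount(assign, minlength=kc)
    # allocate synthetic counts proportionally to cluster size
    quota = np.floor(n_new * sizes / sizes.sum()).astype(int)
    for i in np.argsort(-(n_new * sizes / sizes.sum() - quota))[: n_new - quota.sum()]:
        quota[i] += 1
    out = []
    for c in range(kc):
        if quota[c] == 0:
            continue
        members = x_min[assign == c]
        out.append(_smote_samples(members, int(quota[c]), k, rng))
    return np.vstack(out) if out else np.empty((0, x_min.shape[1]))


def augment(features, labels, config: AugmentationConfig | None = None):
    """Oversample the minority class up to ``target_ratio`` x majority count.

    Returns ``(features', labels', origin)`` where the original rows appear
    first and unmodified, synthetic rows follow with the minority label, and
    ``origin`` flags each row ``'real'`` or ``'synthetic'``. Deterministic
    under ``config.seed``.
    """
    cfg = config or AugmentationConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.isnan(X).any():
        raise ValueError("augmentation requires a complete numeric matrix")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes to identify the minority")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    target = int(round(cfg.target_ratio * n_maj))
    if target < n_min:
        raise ValueError(
            f"target_ratio {cfg.target_ratio} implies {target} minority rows, "
            f"fewer than the existing {n_min}"
        )
    n_new = target - n_min
    origin = np.array(["real"] * len(y), dtype=object)
    if n_new == 0:
        return X.copy(), y.copy(), origin

    k = cfg.k_neighbors
    if n_min <= k:
        warnings.warn(
            f"minority count {n_min} <= k_neighbors {k}; k reduced", stacklevel=2
        )
        k = max(1, n_min - 1)

    rng = np.random.default_rng(cfg.seed)
    x_min = X[y == minority]
    if cfg.method == "smote":
        synth = _smote_samples(x_min, n_new, k, rng)
    elif cfg.method == "kmeans_smote":
        synth = _kmeans_smote_samples(x_min, n_new, k, rng, cfg.n_clusters)
    elif cfg.method in _BACKENDS:
        synth = np.asarray(_BACKENDS[cfg.method](x_min, n_new, k, rng, cfg))
    else:
        raise ValueError(f"unknown augmentation method {cfg.method!r}")

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    origin = np.concatenate([origin, np.array(["synthetic"] * n_new, dtype=object)])
    return X_out, y_out, origin


def make_augmenter(config: AugmentationConfig | None = None):
    """Close an :func:`augment` call over a config, for use by CV protocols."""
    cfg = config or AugmentationConfig()

    def _augmenter(X, y):
        return augment(X, y, cfg)

    return _augmenter
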