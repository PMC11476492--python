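"""Metric suite and repeated cross-validation protocols.

Three protocols are provided, all reporting per-round out-of-fold metrics
summarized as median +/- deviation across rounds:

* ``repeated_cv`` — standard repeated k-fold CV with the imputer and the
  min-max normalizer refit inside every training fold;
* ``early_enriched_cv`` — folds partition only the early-pregnancy subset;
  each training fold is nine tenths of the early data plus *all* non-early
  data, and testing is always on early records;
* ``augmented_real_test_cv`` — oversampled minority records are mixed in
  before splitting (deliberately reproducing the leakage this protocol is
  designed to expose) and each round is scored twice: once on all held-out
  records and once on the held-out *real* records only.

The round summary uses the lower-middle order statistic as the median and
the median absolute deviation about it as the spread.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .encoding import EncodedMatrix, MinMaxNormalizer, encode
from .imputation import ImputerConfig, fit_imputer, impute_test, impute_train

logger = logging.getLogger(__name__)

__all__ = [
    "median_low",
    "median_abs_deviation",
    "f1_from_counts",
    "MetricsBundle",
    "compute_metrics",
    "RepeatedCVResult",
    "repeated_cv",
    "early_enriched_cv",
    "augmented_real_test_cv",
    "round_folds",
    "prepare_fold",
]

METRIC_NAMES = (
    "error_rate",
    "tpr",
    "fpr",
    "tnr",
    "fnr",
    "precision",
    "f1",
    "auc_roc",
    "auc_prc",
)


def median_low(values) -> float:
    """Lower-middle order statistic: element at rank ceil(n/2), 1-based."""
    vals = sorted(float(v) for v in values)
    if not vals:
        raise ValueError("median of empty sequence")
    return vals[(len(vals) - 1) // 2]


def median_abs_deviation(values) -> float:
    """Median absolute deviation about the (lower-middle) median."""
    center = median_low(values)
    return float(np.median([abs(float(v) - center) for v in values]))


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@dataclass
class MetricsBundle:
    """Confusion-derived rates at a threshold plus threshold-free AUCs.

    For a single evaluation micro-F1 and macro-F1 both collapse to the plain
    F1; they diverge only when aggregated across CV rounds (see
    :meth:`RepeatedCVResult.micro_f1` / ``macro_f1``).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    error_rate: float
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    precision: float
    f1: float
    micro_f1: float
    macro_f1: float
    auc_roc: float
    auc_prc: float
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "tp", "fp", "tn", "fn", "error_rate", "tpr", "fpr", "tnr",
                "fnr", "precision", "f1", "micro_f1", "macro_f1", "auc_roc",
                "auc_prc", "threshold",
            )
        }


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsBundle:
    """Score binary labels against risk scores at a decision threshold.

    A call is positive iff score >= threshold. AUCs are threshold-free; with
    single-class labels they are undefined and reported as NaN with a
    warning.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("cannot compute metrics on zero records")
    if y.size != s.size:
        raise ValueError("labels and scores length mismatch")
    calls = s >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    tn = int(np.sum(~calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    pos, neg = tp + fn, fp + tn
    tpr = tp / pos if pos else 0.0
    fpr = fp / neg if neg else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = f1_from_counts(tp, fp, fn)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: AUCs are undefined (NaN)", stacklevel=2)
        auc_roc = auc_prc = float("nan")
    else:
        auc_roc = float(roc_auc_score(y, s))
        auc_prc = float(average_precision_score(y, s))
    return MetricsBundle(
        tp=tp, fp=fp, tn=tn, fn=fn,
        error_rate=(fp + fn) / y.size,
        tpr=tpr, fpr=fpr, tnr=1.0 - fpr, fnr=1.0 - tpr,
        precision=precision, f1=f1, micro_f1=f1, macro_f1=f1,
        auc_roc=auc_roc, auc_prc=auc_prc,
        threshold=float(threshold),
    )


@dataclass
class RepeatedCVResult:
    per_round: list[MetricsBundle]
    protocol: str
    rounds: int
    folds: int
    seed: int
    threshold: float

    def __post_init__(self) -> None:
        if len(self.per_round) != self.rounds:
            raise ValueError("per_round length must equal rounds")

    def metric_values(self, name: str) -> list[float]:
        return [getattr(b, name) for b in self.per_round]

    def summary(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            vals = self.metric_values(name)
            out[name] = {
                "median": median_low(vals),
                "deviation": median_abs_deviation(vals),
            }
        out["micro_f1"] = {"value": self.micro_f1()}
        out["macro_f1"] = {"value": self.macro_f1()}
        return out

    def micro_f1(self) -> float:
        """F1 of the round-averaged confusion matrix."""
        tp = np.mean([b.tp for b in self.per_round])
        fp = np.mean([b.fp for b in self.per_round])
        fn = np.mean([b.fn for b in self.per_round])
        denom = 2 * tp + fp + fn
        return float(2 * tp / denom) if denom else 0.0

    def macro_f1(self) -> float:
        """Harmonic mean of round-averaged precision and recall."""
        p = float(np.mean([b.precision for b in self.per_round]))
        r = float(np.mean([b.tpr for b in self.per_round]))
        return 2 * p * r / (p + r) if p + r else 0.0

    def median(self, name: str) -> float:
        return median_low(self.metric_values(name))

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "rounds": self.rounds,
            "folds": self.folds,
            "seed": self.seed,
            "threshold": self.threshold,
            "summary": self.summary(),
            "per_round": [b.to_dict() for b in self.per_round],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def per_round_frame(self) -> pd.DataFrame:
        return pd.DataFrame([b.to_dict() for b in self.per_round])


# ---------------------------------------------------------------------------
# fold machinery shared with the threshold search


def round_folds(y, folds: int, rng, stratified: bool = False,
                extra_labels=None, require_real=None, max_tries: int = 100):
    """Draw a fold partition whose every training side holds both classes.

    ``extra_labels`` are labels of records joined to every training fold
    (early-enriched protocol); ``require_real`` is a boolean mask forcing
    each test fold to retain at least one flagged record (augmentation
    protocol). Degenerate assignments are resampled with a log message.
    """
    y = np.asarray(y)
    n = len(y)
    if n < folds:
        raise ValueError(f"cannot split {n} records into {folds} folds")
    extra = np.asarray(extra_labels) if extra_labels is not None else np.empty(0, int)
    for _ in range(max_tries):
        state = int(rng.integers(0, 2**31 - 1))
        cls = StratifiedKFold if stratified else KFold
        kf = cls(n_splits=folds, shuffle=True, random_state=state)
        splits = list(kf.split(np.zeros(n), y) if stratified else kf.split(np.zeros(n)))
        ok = all(
            len(np.unique(np.concatenate([y[tr], extra]))) == 2 for tr, _ in splits
        )
        if ok and require_real is not None:
            ok = all(require_real[te].any() for _, te in splits)
        if ok:
            return splits
        logger.info("degenerate fold assignment; resampled")
    raise RuntimeError("could not draw a valid fold assignment")


def prepare_fold(train: EncodedMatrix, test: EncodedMatrix,
                 imputer_config: ImputerConfig | None = None):
    """Fit imputer + normalizer on the training fold and transform both sides.

    Returns complete, normalized (X_train, y_train, X_test) with no
    information flowing from the test fold into the fitted preprocessing.
    """
    imp = fit_imputer(train, imputer_config)
    train_i = impute_train(train, imp)
    test_i = impute_test(test, imp)
    norm = MinMaxNormalizer().fit(train_i.frame)
    x_tr = norm.transform(train_i.frame, clip=False)
    x_te = norm.transform(test_i.frame, clip=True)
    return x_tr, train_i.labels.to_numpy(), x_te


def _as_encoded(data) -> EncodedMatrix:
    if isinstance(data, EncodedMatrix):
        return data
    return encode(data)


def _concat_encoded(a: EncodedMatrix, b: EncodedMatrix) -> EncodedMatrix:
    return EncodedMatrix(
        frame=pd.concat([a.frame, b.frame], ignore_index=True),
        labels=pd.concat([a.labels, b.labels], ignore_index=True),
    )


def _protocol_rounds(enc, extra, config, rounds, folds, threshold, seed,
                     imputer_config, stratified, protocol):
    from .prediction import train_model  # local import avoids a cycle

    y = enc.labels.to_numpy()
    rng = np.random.default_rng(seed)
    bundles = []
    for _ in range(rounds):
        splits = round_folds(
            y, folds, rng, stratified=stratified,
            extra_labels=None if extra is None else extra.labels.to_numpy(),
        )
        oof = np.empty(len(y))
        for tr, te in splits:
            train = enc.subset(tr)
            if extra is not None and len(extra):
                train = _concat_encoded(train, extra)
            x_tr, y_tr, x_te = prepare_fold(train, enc.subset(te), imputer_config)
            model = train_model(x_tr, y_tr, config)
            oof[te] = model.scores(x_te)
        bundles.append(compute_metrics(y, oof, threshold))
    return RepeatedCVResult(
        per_round=bundles, protocol=protocol, rounds=rounds,
        folds=folds, seed=seed, threshold=threshold,
    )


def repeated_cv(data, config=None, rounds: int = 10, folds: int = 10,
                threshold: float = 0.5, seed: int = 0,
                imputer_config: ImputerConfig | None = None,
                stratified: bool = False) -> RepeatedCVResult:
    """Repeated k-fold CV with per-fold preprocessing refits.

    ``data`` is a labelled raw cohort table or an already-encoded matrix.
    Per round, out-of-fold scores are pooled over all folds and scored once.
    """
    from .prediction import PredictorConfig

    if rounds < 1 or folds < 2:
        raise ValueError("need rounds >= 1 and folds >= 2")
    enc = _as_encoded(data)
    if enc.labels is None:
        raise ValueError("repeated_cv requires labelled data")
    return _protocol_rounds(
        enc, None, config or PredictorConfig(), rounds, folds, threshold,
        seed, imputer_config, stratified, "standard",
    )


def early_enriched_cv(early, non_early, config=None, rounds: int = 10,
                      folds: int = 10, threshold: float = 0.5, seed: int = 0,
                      imputer_config: ImputerConfig | None = None,
                      stratified: bool = False) -> RepeatedCVResult:
    """Modified CV for early-pregnancy prediction.

    Folds partition only the early set; every training fold is its
    nine-tenths complement joined with *all* non-early records, and every
    test fold is early data. With an empty non-early set this reduces
    exactly to :func:`repeated_cv` on the early data at the same seed.
    """
    from .prediction import PredictorConfig

    if rounds < 1 or folds < 2:
        raise ValueError("need rounds >= 1 and folds >= 2")
    enc_early = _as_encoded(early)
    if enc_early.labels is None:
        raise ValueError("early_enriched_cv requires labelled early data")
    enc_extra = None
    if non_early is not None and len(non_early):
        enc_extra = _as_encoded(non_early)
        if enc_extra.labels is None:
            raise ValueError("non-early data must be labelled")
    return _protocol_rounds(
        enc_early, enc_extra, config or PredictorConfig(), rounds, folds,
        threshold, seed, imputer_config, stratified, "early_enriched",
    )


def augmented_real_test_cv(real, augmenter, config=None, rounds: int = 10,
                           folds: int = 10, threshold: float = 0.5,
                           seed: int = 0,
                           imputer_config: ImputerConfig | None = None,
                           augment_within_train: bool = False):
    """CV over real + oversampled data, scored on all vs. real-only test rows.

    The default follows the leaky protocol under scrutiny: the augmenter runs
    once on the full preprocessed real data and the fold split happens
    afterwards, so interpolated neighbors of test records can sit in the
    training side. Each round returns two bundles from the *same* folds —
    metrics over every held-out record, and metrics over held-out real
    records only. ``augment_within_train=True`` switches to the
    leakage-safe variant that augments inside each training fold and tests
    on real records only (both bundles then coincide).

    Returns ``(result_on_all_test_rows, result_on_real_test_rows)``.
    """
    from .prediction import PredictorConfig, train_model

    if rounds < 1 or folds < 2:
        raise ValueError("need rounds >= 1 and folds >= 2")
    config = config or PredictorConfig()
    enc = _as_encoded(real)
    if enc.labels is None:
        raise ValueError("augmented_real_test_cv requires labelled real data")

    # whole-set preprocessing mirrors the published protocol: oversampling
    # needs one complete numeric matrix before any split exists
    imp = fit_imputer(enc, imputer_config)
    full = impute_train(enc, imp)
    norm = MinMaxNormalizer().fit(full.frame)
    x_real = norm.transform(full.frame, clip=False).to_numpy(dtype=float)
    y_real = full.labels.to_numpy()

    rng = np.random.default_rng(seed)
    if augment_within_train:
        x_all, y_all = x_real, y_real
        origin_real = np.ones(len(y_real), bool)
    else:
        x_all, y_all, origin = augmenter(x_real, y_real)
        origin_real = np.asarray(origin) == "real"

    bundles_all, bundles_real = [], []
    for _ in range(rounds):
        splits = round_folds(y_all, folds, rng, require_real=origin_real)
        oof = np.empty(len(y_all))
        for tr, te in splits:
            if augment_within_train:
                x_tr, y_tr, _ = augmenter(x_all[tr], y_all[tr])
            else:
                x_tr, y_tr = x_all[tr], y_all[tr]
            model = train_model(x_tr, y_tr, config)
            oof[te] = model.scores(x_all[te])
        bundles_all.append(compute_metrics(y_all, oof, threshold))
        bundles_real.append(
            compute_metrics(y_all[origin_real], oof[origin_real], threshold)
        )

    mk = lambda bundles, proto: RepeatedCVResult(
        per_round=bundles, protocol=proto, rounds=rounds, folds=folds,
        seed=seed, threshold=threshold,
    )
    return (
        mk(bundles_all, "augmented_all_test"),
        mk(bundles_real, "augmented_real_test"),
    )
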