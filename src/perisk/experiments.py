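"""End-to-end experiment drivers shaped like the published study designs.

Each experiment generates its synthetic cohorts from the run config,
executes the pipeline (encoding, per-fold imputation and normalization,
cross-platform PlGF calibration where relevant, classifier training and
repeated CV) and emits a machine-readable JSON report plus an aligned text
table. Everything is deterministic under the config's master seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import calibration as cal
from .augmentation import AugmentationConfig, make_augmenter
from .cohort import generate_calibration_set, generate_cohort
from .config import RunConfig
from .encoding import encode
from .evaluation import (
    augmented_real_test_cv,
    compute_metrics,
    early_enriched_cv,
    prepare_fold,
    repeated_cv,
)
from .imputation import ImputerConfig
from .prediction import (
    ALGORITHMS,
    PredictorConfig,
    optimize_threshold,
    train_model,
)

logger = logging.getLogger(__name__)

__all__ = ["EXPERIMENTS", "run_experiment"]

EXPERIMENTS = (
    "model_comparison",
    "bi_platform_fusion",
    "threshold_search",
    "early_prediction",
    "augmentation_study",
)


def _imputer_config(config: RunConfig) -> ImputerConfig:
    return ImputerConfig(seed=config.seed, **config.imputer)


def _predictor_config(config: RunConfig, algorithm=None) -> PredictorConfig:
    pc = dict(config.predictor)
    if algorithm is not None:
        pc["algorithm"] = algorithm
    return PredictorConfig(seed=config.seed, threshold=config.threshold, **pc)


def _calibration_model(config: RunConfig):
    pairs = generate_calibration_set(
        n=config.calibration["n_pairs"],
        transfer_params=config.transfer_params(),
        seed=config.seed * 1000 + 7,
    )
    return cal.fit_calibrators(
        pairs,
        rounds=config.calibration["rounds"],
        folds=config.calibration["folds"],
        seed=config.seed * 1000 + 8,
    )


def _calibrated(table: pd.DataFrame, model) -> pd.DataFrame:
    out = table.copy()
    out["plgf"] = cal.calibrate(
        out["plgf"].to_numpy(dtype=float), out["platform"].to_numpy(), model
    )
    return out


def _cross_platform_eval(train_table, test_table, config: RunConfig):
    """Train on one full cohort, test once on another (no CV)."""
    enc_tr, enc_te = encode(train_table), encode(test_table)
    x_tr, y_tr, x_te = prepare_fold(enc_tr, enc_te, _imputer_config(config))
    model = train_model(x_tr, y_tr, _predictor_config(config))
    scores = model.scores(x_te)
    return compute_metrics(enc_te.labels.to_numpy(), scores, config.threshold)


def _summary_cells(result):
    s = result.summary()
    return {
        name: {"median": s[name]["median"], "deviation": s[name]["deviation"]}
        for name in ("error_rate", "tpr", "fpr", "f1", "auc_roc", "auc_prc")
    } | {"micro_f1": s["micro_f1"]["value"], "macro_f1": s["macro_f1"]["value"]}


def _bundle_cells(bundle):
    return {
        name: {"median": getattr(bundle, name), "deviation": None}
        for name in ("error_rate", "tpr", "fpr", "f1", "auc_roc", "auc_prc")
    } | {"micro_f1": bundle.micro_f1, "macro_f1": bundle.macro_f1}


# ---------------------------------------------------------------------------
# experiment bodies


def _exp_model_comparison(config: RunConfig) -> dict:
    table = generate_cohort(config.cohort_spec("simoa"))
    rows = {}
    for algo in ALGORITHMS:
        result = repeated_cv(
            table,
            _predictor_config(config, algo),
            rounds=config.rounds,
            folds=config.folds,
            threshold=config.threshold,
            seed=config.seed,
            imputer_config=_imputer_config(config),
        )
        rows[algo] = _summary_cells(result)
    return {"design": "per-algorithm repeated CV on the SiMoA-shaped cohort",
            "rows": rows}


def _exp_bi_platform_fusion(config: RunConfig) -> dict:
    calib = _calibration_model(config)
    simoa = generate_cohort(config.cohort_spec("simoa"))
    elecsys = generate_cohort(config.cohort_spec("elecsys"))
    simoa_c, elecsys_c = _calibrated(simoa, calib), _calibrated(elecsys, calib)
    fused = pd.concat([simoa_c, elecsys_c], ignore_index=True)

    frame, labels = fused_complete(fused, config)
    search = optimize_threshold(
        frame,
        labels,
        config=_predictor_config(config),
        rounds=max(2, config.rounds // 2),
        folds=config.folds,
        grid_step=config.grid_step,
        seed=config.seed,
    )
    columns = {
        "simoa_trained": _bundle_cells(
            _cross_platform_eval(simoa_c, elecsys_c, config)
        ),
        "elecsys_trained": _bundle_cells(
            _cross_platform_eval(elecsys_c, simoa_c, config)
        ),
        "fusion_cv_default_threshold": _summary_cells(
            repeated_cv(
                fused, _predictor_config(config), rounds=config.rounds,
                folds=config.folds, threshold=config.threshold,
                seed=config.seed, imputer_config=_imputer_config(config),
            )
        ),
        "fusion_cv_optimal_threshold": _summary_cells(
            repeated_cv(
                fused, _predictor_config(config), rounds=config.rounds,
                folds=config.folds, threshold=search.median,
                seed=config.seed + 1, imputer_config=_imputer_config(config),
            )
        ),
    }
    return {
        "design": "mono-platform cross-tests vs. fusion-trained CV at the "
        "default and searched thresholds",
        "calibration": {
            "direction": calib.direction,
            "reference_platform": calib.reference_platform,
            "selected_mse_forward": calib.mse_forward,
            "selected_mse_backward": calib.mse_backward,
        },
        "optimal_threshold": {
            "median": search.median,
            "deviation": search.deviation,
        },
        "columns": columns,
    }


def fused_complete(fused: pd.DataFrame, config: RunConfig):
    """Impute + normalize the fused table once (threshold search input)."""
    from .encoding import MinMaxNormalizer
    from .imputation import fit_imputer, impute_train

    enc = encode(fused)
    imp = fit_imputer(enc, _imputer_config(config))
    full = impute_train(enc, imp)
    norm = MinMaxNormalizer().fit(full.frame)
    return norm.transform(full.frame, clip=False), full.labels


def _exp_threshold_search(config: RunConfig) -> dict:
    calib = _calibration_model(config)
    simoa = generate_cohort(config.cohort_spec("simoa"))
    elecsys = generate_cohort(config.cohort_spec("elecsys"))
    fused = pd.concat(
        [_calibrated(simoa, calib), _calibrated(elecsys, calib)], ignore_index=True
    )
    frame, labels = fused_complete(fused, config)
    search = optimize_threshold(
        frame,
        labels,
        config=_predictor_config(config),
        rounds=config.rounds,
        folds=config.folds,
        grid_step=config.grid_step,
        seed=config.seed,
    )
    return {
        "design": "F1-optimal output threshold under repeated CV on the "
        "fused cohort",
        "optimal_threshold": search.summary(),
        "per_round_f1": search.per_round_f1,
    }


def _exp_early_prediction(config: RunConfig) -> dict:
    early = generate_cohort(config.cohort_spec("first_trimester"))
    simoa = generate_cohort(config.cohort_spec("simoa"))
    elecsys = generate_cohort(config.cohort_spec("elecsys"))
    calib = _calibration_model(config)
    pool = pd.concat(
        [_calibrated(simoa, calib), _calibrated(elecsys, calib)], ignore_index=True
    )
    gest_day = 7 * pool["gestational_weeks"] + pool["gestational_days"]
    non_early = pool[gest_day > 97].reset_index(drop=True)
    early_c = _calibrated(early, calib)

    pc = _predictor_config(config)
    imp = _imputer_config(config)
    kw = dict(rounds=config.rounds, folds=config.folds, seed=config.seed,
              imputer_config=imp, threshold=config.threshold)
    return {
        "design": "early-only repeated CV vs. early folds enriched with all "
        "non-early data",
        "rows": {
            "early_only": _summary_cells(repeated_cv(early_c, pc, **kw)),
            "early_enriched": _summary_cells(
                early_enriched_cv(early_c, non_early, pc, **kw)
            ),
        },
        "n_non_early": int(len(non_early)),
    }


def _exp_augmentation_study(config: RunConfig) -> dict:
    table = generate_cohort(config.cohort_spec("elecsys"))
    pc = _predictor_config(config)
    imp = _imputer_config(config)
    augmenter = make_augmenter(
        AugmentationConfig(seed=config.seed, **config.augmentation)
    )
    real_cv = repeated_cv(
        table, pc, rounds=config.rounds, folds=config.folds,
        threshold=config.threshold, seed=config.seed, imputer_config=imp,
    )
    on_all, on_real = augmented_real_test_cv(
        table, augmenter, pc, rounds=config.rounds, folds=config.folds,
        threshold=config.threshold, seed=config.seed, imputer_config=imp,
    )
    return {
        "design": "real-only CV vs. CV over real+augmented data scored on "
        "all and on real-only test partitions",
        "rows": {
            "real_train_real_test": _summary_cells(real_cv),
            "augmented_train_augmented_test": _summary_cells(on_all),
            "augmented_train_real_test": _summary_cells(on_real),
        },
    }


_BODIES = {
    "model_comparison": _exp_model_comparison,
    "bi_platform_fusion": _exp_bi_platform_fusion,
    "threshold_search": _exp_threshold_search,
    "early_prediction": _exp_early_prediction,
    "augmentation_study": _exp_augmentation_study,
}


# ---------------------------------------------------------------------------
# rendering and entry point


def _round_floats(obj, ndigits: int = 10):
    """Round every float in a nested report so serialized output is stable
    against last-bit optimizer variation."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _fmt(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, dict):
        if v.get("deviation") is None:
            return f"{v['median']:.4f}"
        return f"{v['median']:.4f} ± {v['deviation']:.4f}"
    if isinstance(v, float):
        return f"{v:.4f}"
    return str(v)


def _render_rows(title: str, rows: dict) -> str:
    metric_names = list(next(iter(rows.values())).keys())
    header = ["", *metric_names]
    lines = [[name, *[_fmt(cells[m]) for m in metric_names]] for name, cells in rows.items()]
    widths = [max(len(r[i]) for r in [header, *lines]) for i in range(len(header))]
    fmt_row = lambda r: "  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip()
    return "\n".join([title, fmt_row(header), *[fmt_row(r) for r in lines], ""])


def render_report(name: str, report: dict) -> str:
    parts = [f"experiment: {name}", f"design: {report['body'].get('design', '')}", ""]
    body = report["body"]
    if "rows" in body:
        parts.append(_render_rows("per-row metrics", body["rows"]))
    if "columns" in body:
        parts.append(_render_rows("per-column metrics", body["columns"]))
    if "optimal_threshold" in body:
        parts.append(f"optimal threshold: {json.dumps(body['optimal_threshold'])}")
    if "calibration" in body:
        parts.append(f"calibration: {json.dumps(body['calibration'], sort_keys=True)}")
    return "\n".join(parts) + "\n"


def run_experiment(
    name: str,
    config: RunConfig | None = None,
    out_dir=None,
    dry_run: bool = False,
) -> dict:
    """Run one named experiment; write ``<name>.json`` and ``<name>.txt``.

    The JSON report embeds the fully resolved config and master seed, so a
    rerun with an identical config is byte-identical. ``dry_run`` only lists
    the planned stages.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    config = config or RunConfig()
    if dry_run:
        return {"experiment": name, "planned": True, "config": config.to_dict()}

    logger.info("stage=generate experiment=%s", name)
    body = _round_floats(_BODIES[name](config))
    report = {"experiment": name, "config": config.to_dict(), "body": body}

    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{name}.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / f"{name}.txt").write_text(render_report(name, report))
    logger.info("stage=report experiment=%s dir=%s", name, out_dir)
    return report
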