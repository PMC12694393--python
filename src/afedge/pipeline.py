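"""End-to-end orchestration: cohort -> datasets -> training -> evaluation.

One call runs the full study design on an RR store: shared subject-wise
fold partition, per-fold float32 training with an 80/20 stratified
train/validation split, INT8 conversion calibrated on training windows,
evaluation of both precisions on the held-out test subjects, Eq.-style
fold-summed confusion matrices and mean ± std summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from afedge.cnn import (
    ModelConfig,
    TrainConfig,
    TrainedModel,
    build_model,
    save_model,
    split_train_val,
    train,
)
from afedge.dataset import DatasetBundle, FoldSpec, assign_folds, build_bundle, samples_to_frame
from afedge.evaluation import (
    ConfusionMatrix,
    CrossValSummary,
    MetricsReport,
    aggregate_confusions,
    compute_confusion,
    compute_metrics,
    summarize_folds,
)
from afedge.ingest import RRSeries
from afedge.quantize import QuantizedModel, quantize_int8, save_quantized

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    """Everything measured on one fold for one window length."""

    fold_id: int
    float32: MetricsReport
    int8: MetricsReport
    cm_float32: ConfusionMatrix
    cm_int8: ConfusionMatrix
    int8_agreement: float
    stopped_epoch: int
    model: TrainedModel | None = None
    qmodel: QuantizedModel | None = None


@dataclass
class ExperimentResult:
    """Fold results plus cross-fold aggregates for one window length."""

    n: int
    folds: list[FoldResult] = field(default_factory=list)
    summary_float32: CrossValSummary | None = None
    summary_int8: CrossValSummary | None = None
    cm_total_float32: ConfusionMatrix | None = None
    cm_total_int8: ConfusionMatrix | None = None

    @property
    def mean_accuracy_float32(self) -> float:
        return self.summary_float32.mean["accuracy"]

    @property
    def mean_accuracy_int8(self) -> float:
        return self.summary_int8.mean["accuracy"]

    @property
    def mean_int8_agreement(self) -> float:
        return float(np.mean([f.int8_agreement for f in self.folds]))


def _samples_to_xy(samples) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.features for s in samples])
    y = np.asarray([s.label for s in samples], dtype=int)
    return x, y


def evaluate_model(model, x: np.ndarray, y: np.ndarray) -> tuple[MetricsReport, ConfusionMatrix, np.ndarray]:
    """Confusion matrix plus full metric set of one model on one table."""
    probs = model.predict_proba(x)
    pred = np.argmax(probs, axis=1)
    cm = compute_confusion(y, pred)
    report = compute_metrics(cm, scores=probs[:, 1], true_labels=y, probs=probs)
    return report, cm, pred


def run_fold(
    bundle: DatasetBundle,
    fold: FoldSpec,
    train_config: TrainConfig,
    keep_models: bool = False,
) -> FoldResult:
    """Train, quantize and evaluate one fold of one bundle."""
    x, y = _samples_to_xy(bundle.train_tables[fold.fold_id])
    x_test, y_test = _samples_to_xy(bundle.test_tables[fold.fold_id])
    x_tr, y_tr, x_va, y_va = split_train_val(
        x, y, val_fraction=train_config.val_fraction, seed=train_config.seed
    )
    cfg = ModelConfig(n=bundle.n)
    model = build_model(cfg, seed=train_config.seed)
    tm = train(model, (x_tr, y_tr), (x_va, y_va), train_config)
    qm = quantize_int8(tm, x_tr, seed=train_config.seed)

    rep_f32, cm_f32, pred_f32 = evaluate_model(tm, x_test, y_test)
    rep_i8, cm_i8, pred_i8 = evaluate_model(qm, x_test, y_test)
    agreement = float(np.mean(pred_f32 == pred_i8))
    logger.info(
        "N=%d fold %d: float32 acc %.4f, int8 acc %.4f, agreement %.4f (epoch %d)",
        bundle.n, fold.fold_id, rep_f32.accuracy, rep_i8.accuracy, agreement,
        tm.stopped_epoch,
    )
    return FoldResult(
        fold_id=fold.fold_id,
        float32=rep_f32,
        int8=rep_i8,
        cm_float32=cm_f32,
        cm_int8=cm_i8,
        int8_agreement=agreement,
        stopped_epoch=tm.stopped_epoch,
        model=tm if keep_models else None,
        qmodel=qm if keep_models else None,
    )


def run_experiment(
    rr_store: dict[str, list[RRSeries]],
    n_list: tuple[int, ...] = (25, 50, 100),
    n_folds: int = 5,
    test_per_fold: int = 3,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    keep_models: bool = False,
) -> dict[int, ExperimentResult]:
    """Run the full cross-validated study for every window length.

    The fold partition is drawn once and reused across window lengths so
    accuracy differences are attributable to the window length alone.
    """
    folds = assign_folds(sorted(rr_store), n_folds, test_per_fold, seed)
    results: dict[int, ExperimentResult] = {}
    for n in n_list:
        bundle = build_bundle(rr_store, n, folds, seed=seed)
        tc = train_config or TrainConfig(seed=seed)
        result = ExperimentResult(n=n)
        for fold in folds:
            result.folds.append(run_fold(bundle, fold, tc, keep_models=keep_models))
        result.summary_float32 = summarize_folds([f.float32 for f in result.folds])
        result.summary_int8 = summarize_folds([f.int8 for f in result.folds])
        result.cm_total_float32 = aggregate_confusions([f.cm_float32 for f in result.folds])
        result.cm_total_int8 = aggregate_confusions([f.cm_int8 for f in result.folds])
        results[n] = result
    return results


def write_results(results: dict[int, ExperimentResult], out_dir: str | Path) -> Path:
    """Persist per-fold metrics, summaries and aggregated confusions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc: dict = {}
    for n, res in results.items():
        doc[str(n)] = {
            "folds": [
                {
                    "fold_id": f.fold_id,
                    "stopped_epoch": f.stopped_epoch,
                    "int8_agreement": f.int8_agreement,
                    "float32": vars(f.float32),
                    "int8": vars(f.int8),
                    "cm_float32": vars(f.cm_float32),
                    "cm_int8": vars(f.cm_int8),
                }
                for f in res.folds
            ],
            "summary_float32": {"mean": res.summary_float32.mean, "std": res.summary_float32.std},
            "summary_int8": {"mean": res.summary_int8.mean, "std": res.summary_int8.std},
            "cm_total_float32": vars(res.cm_total_float32),
            "cm_total_int8": vars(res.cm_total_int8),
            "cm_total_float32_rates": res.cm_total_float32.row_normalized().tolist(),
            "cm_total_int8_rates": res.cm_total_int8.row_normalized().tolist(),
        }
    path = out_dir / "results.json"
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return path
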