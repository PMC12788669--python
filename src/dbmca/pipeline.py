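"""End-to-end orchestration: phantom -> preprocess -> segment -> features ->
train all models on both modalities -> cross-validate -> compare.

One :class:`ExperimentConfig` (a single seed governs every stochastic stage)
produces an :class:`ExperimentReport` whose tables mirror the published
layout: a models-by-metrics summary, per-fold accuracies, and a pairwise
comparison table (Comparison, Mean Diff, Std Dev, t-statistic, p-value).
All folds are shared across models so the comparisons are genuinely paired.

The DNN/mask branch consumes watershed-derived gated masks by default
(``mask_source="watershed"``); set ``"truth"`` to feed the generating masks
instead.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import CVResult, make_folds, nn_fit_predict, run_cv, svm_fit_predict
from .features import region_features
from .io import _config_hash, write_features_csv
from .models import (
    SvmConfig,
    TrainConfig,
    build_dbmca,
    predict,
    small_cnn_branch,
    small_dnn_branch,
)
from .phantom import PhantomConfig, generate_phantom, scaled_config
from .preprocess import PreprocessConfig, preprocess_image
from .segmentation import center_on_mask, segment_image
from .stats import PairedComparison, paired_t_from_folds

logger = logging.getLogger("dbmca")

MODEL_COLUMNS = (
    "dbmca",
    "cnn_image",
    "cnn_mask",
    "dnn_image",
    "dnn_mask",
    "svm_image",
    "svm_mask",
)

DISPLAY_NAMES = {
    "dbmca": "DbMCA",
    "cnn_image": "CNN-Image",
    "cnn_mask": "CNN-Mask",
    "dnn_image": "DNN-Image",
    "dnn_mask": "DNN-Mask",
    "svm_image": "SVM-Image",
    "svm_mask": "SVM-Mask",
}


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=lambda: scaled_config(300))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    threshold_quantile: float = 0.90
    min_distance_px: int = 10
    min_diameter_mm: float = 3.0
    train: TrainConfig = field(default_factory=TrainConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    k: int = 5
    seed: int = 0
    models: tuple[str, ...] = MODEL_COLUMNS
    mask_source: str = "watershed"  # "watershed" | "truth"
    center_regions: bool = True  # recentre each slice on its mask centroid

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.mask_source not in ("watershed", "truth"):
            raise ValueError(f"unknown mask source {self.mask_source!r}")

    def summary(self) -> dict:
        return {
            "phantom": self.phantom.summary(),
            "denoise": [self.preprocess.denoise_method, self.preprocess.denoise_radius],
            "gabor_frequencies": list(self.preprocess.gabor.frequencies),
            "gabor_orientations": [float(t) for t in self.preprocess.gabor.orientations],
            "threshold_quantile": self.threshold_quantile,
            "min_distance_px": self.min_distance_px,
            "min_diameter_mm": self.min_diameter_mm,
            "center_regions": self.center_regions,
            "k": self.k,
            "seed": self.seed,
            "models": list(self.models),
            "mask_source": self.mask_source,
            "max_epochs": self.train.max_epochs,
            "patience": self.train.early_stopping_patience,
        }


@dataclass
class ExperimentReport:
    summaries: dict[str, dict]  # model -> metric means over folds
    fold_accuracies: dict[str, list[float]]
    comparisons: dict[str, PairedComparison]
    provenance: dict
    features: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        metrics = ["accuracy", "f1", "recall", "precision"]
        data = {
            DISPLAY_NAMES[m]: [self.summaries[m][met] for met in metrics]
            for m in self.summaries
        }
        return pd.DataFrame(data, index=["Accuracy", "F1 Score", "Recall", "Precision"])


def _model_seed(base: int, model: str, salt: int = 0) -> int:
    return (base * 131 + MODEL_COLUMNS.index(model) * 17 + salt) % (2**31 - 1)


def _cv_for_model(
    name: str,
    images: np.ndarray,
    masks: np.ndarray,
    labels: np.ndarray,
    folds,
    cfg: ExperimentConfig,
) -> CVResult:
    h = images.shape[1]
    small = h <= 128
    cnn = small_cnn_branch() if small else None
    dnn = small_dnn_branch() if small else None
    if cnn is None:
        from .models import default_cnn_branch, default_dnn_branch

        cnn, dnn = default_cnn_branch(), default_dnn_branch()

    tc = TrainConfig(
        max_epochs=cfg.train.max_epochs,
        steps_per_epoch=cfg.train.steps_per_epoch,
        early_stopping_patience=cfg.train.early_stopping_patience,
        batch_size=cfg.train.batch_size,
        learning_rate=cfg.train.learning_rate,
        val_fraction=cfg.train.val_fraction,
        seed=_model_seed(cfg.seed, name),
    )
    if name == "dbmca":
        spec = build_dbmca(cnn, dnn)
        fp = nn_fit_predict(spec, (images, masks), tc)
        inputs = (images, masks)
    elif name in ("cnn_image", "cnn_mask"):
        arr = images if name.endswith("image") else masks
        fp = nn_fit_predict(cnn, arr, tc)
        inputs = arr
    elif name in ("dnn_image", "dnn_mask"):
        arr = images if name.endswith("image") else masks
        fp = nn_fit_predict(dnn, arr, tc)
        inputs = arr
    else:  # svm
        arr = images if name.endswith("image") else masks
        vectors = arr.reshape(len(arr), -1)
        fp = svm_fit_predict(vectors, cfg.svm)
        inputs = vectors
    return run_cv(inputs, labels, fit_predict=fp, folds=folds)


def prepare_modalities(
    dataset, config: ExperimentConfig
) -> tuple[np.ndarray, np.ndarray, list]:
    """Preprocess + segment every slice; returns the two model inputs
    (image stack, mask stack) and the extracted region features.

    The mask stack comes from watershed segmentation (or the generating
    truth masks, per ``config.mask_source``); when ``center_regions`` is on,
    each image/mask pair is translated so the mask centroid sits at the grid
    center before modeling.
    """
    t1 = time.perf_counter()
    images, masks, all_features = [], [], []
    for img, truth_mask, label in zip(dataset.images, dataset.masks, dataset.labels):
        channels = preprocess_image(img, config.preprocess)
        _, regions, gated = segment_image(
            channels["intensity"],
            threshold_quantile=config.threshold_quantile,
            min_distance_px=config.min_distance_px,
            min_diameter_mm=config.min_diameter_mm,
        )
        for region in regions:
            all_features.append((region_features(region, img), label))
        mask = gated.pixels if config.mask_source == "watershed" else truth_mask.pixels
        if config.center_regions:
            img_px, mask = center_on_mask(img.pixels, mask)
        else:
            img_px = img.pixels
        images.append(img_px)
        masks.append(mask.astype(np.float64))
    logger.info("preprocess+segment: %.1fs", time.perf_counter() - t1)
    return np.stack(images), np.stack(masks), all_features


def comparison_train_config(seed: int = 0) -> TrainConfig:
    """Converged training protocol for model comparison: past-40-epoch
    regimen with early stopping, generous patience (the fused model matures
    late), and a capped iteration count per epoch."""
    return TrainConfig(
        max_epochs=200,
        steps_per_epoch=13,
        early_stopping_patience=30,
        seed=seed,
    )


def comparison_config(n_samples: int = 600, seed: int = 0) -> ExperimentConfig:
    """Canonical desk-scale model-comparison conditions."""
    return ExperimentConfig(
        phantom=scaled_config(n_samples, seed=seed),
        train=comparison_train_config(seed),
        seed=seed,
    )


def run_comparison(
    config: ExperimentConfig, test_fraction: float = 0.2
) -> dict[str, dict]:
    """Train and evaluate every configured model on one stratified
    train/test split (the 80-20 protocol).

    The k-fold machinery in :func:`run_experiment` gives fold-wise paired
    statistics at smoke scale; this single-split path is the budget-friendly
    protocol for the converged model comparison.  Returns
    ``{model: metrics dict}`` with the held-out accuracy and macro metrics.
    """
    from sklearn.model_selection import train_test_split

    from .evaluation import compute_metrics
    from .models import train_model, train_svm

    dataset = generate_phantom(config.phantom)
    images, masks, _ = prepare_modalities(dataset, config)
    labels = dataset.label_array()
    idx = np.arange(len(labels))
    tr, te = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=config.seed
    )
    h = images.shape[1]
    cnn = small_cnn_branch() if h <= 128 else None
    dnn = small_dnn_branch() if h <= 128 else None
    if cnn is None:
        from .models import default_cnn_branch, default_dnn_branch

        cnn, dnn = default_cnn_branch(), default_dnn_branch()

    results: dict[str, dict] = {}
    for name in config.models:
        t0 = time.perf_counter()
        tc = TrainConfig(
            max_epochs=config.train.max_epochs,
            steps_per_epoch=config.train.steps_per_epoch,
            early_stopping_patience=config.train.early_stopping_patience,
            batch_size=config.train.batch_size,
            learning_rate=config.train.learning_rate,
            weight_decay=config.train.weight_decay,
            val_fraction=config.train.val_fraction,
            seed=_model_seed(config.seed, name),
        )
        if name == "dbmca":
            fitted = train_model(build_dbmca(cnn, dnn), (images[tr], masks[tr]), labels[tr], tc)
            y_pred, _ = predict(fitted, (images[te], masks[te]))
        elif name.startswith("svm"):
            arr = images if name.endswith("image") else masks
            vec = arr.reshape(len(arr), -1)
            fitted = train_svm(vec[tr], labels[tr], config.svm)
            y_pred, _ = predict(fitted, vec[te])
        else:
            arr = images if name.endswith("image") else masks
            spec = cnn if name.startswith("cnn") else dnn
            fitted = train_model(spec, arr[tr], labels[tr], tc)
            y_pred, _ = predict(fitted, arr[te])
        rep = compute_metrics(labels[te], y_pred)
        results[name] = {
            "accuracy": rep.accuracy,
            "f1": rep.f1,
            "recall": rep.recall,
            "precision": rep.precision,
        }
        logger.info("comparison %s: acc=%.3f (%.1fs)", name, rep.accuracy,
                    time.perf_counter() - t0)
    return results


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentReport:
    """Run the full pipeline under ``config``; deterministic given its seed.

    When ``out_dir`` is given, writes summary.csv, folds.csv,
    comparisons.csv, features.csv and provenance.json.
    """
    t0 = time.perf_counter()
    dataset = generate_phantom(config.phantom)
    logger.info("phantom: %d samples in %.1fs", len(dataset), time.perf_counter() - t0)

    images, masks, all_features = prepare_modalities(dataset, config)
    labels = dataset.label_array()

    folds = make_folds(labels, k=config.k, seed=config.seed)
    summaries: dict[str, dict] = {}
    fold_accs: dict[str, list[float]] = {}
    for name in config.models:
        t2 = time.perf_counter()
        cv = _cv_for_model(name, images, masks, labels, folds, config)
        summaries[name] = {
            "accuracy": cv.mean_metric("accuracy"),
            "f1": cv.mean_metric("f1"),
            "recall": cv.mean_metric("recall"),
            "precision": cv.mean_metric("precision"),
            "f1_weighted": cv.mean_metric("f1_weighted"),
            "min_accuracy": cv.min_accuracy,
            "max_accuracy": cv.max_accuracy,
        }
        fold_accs[name] = cv.fold_accuracies
        logger.info("model %s: acc=%.3f (%.1fs)", name, cv.mean_accuracy,
                    time.perf_counter() - t2)

    comparisons: dict[str, PairedComparison] = {}
    if "dbmca" in fold_accs:
        for name in config.models:
            if name == "dbmca":
                continue
            comparisons[f"DbMCA vs {DISPLAY_NAMES[name]}"] = paired_t_from_folds(
                fold_accs["dbmca"], fold_accs[name]
            )

    provenance = {
        "config": config.summary(),
        "config_hash": _config_hash(config.summary()),
        "seed": config.seed,
        "package_version": __version__,
    }
    report = ExperimentReport(
        summaries=summaries,
        fold_accuracies=fold_accs,
        comparisons=comparisons,
        provenance=provenance,
        features=all_features,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: ExperimentReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary_frame().to_csv(out / "summary.csv", float_format="%.6f")
    rows = [
        {"model": DISPLAY_NAMES[m], "fold": i, "accuracy": acc}
        for m, accs in report.fold_accuracies.items()
        for i, acc in enumerate(accs)
    ]
    pd.DataFrame(rows).to_csv(out / "folds.csv", index=False, float_format="%.6f")
    comp_rows = [
        {
            "Comparison": name,
            "Mean Diff": c.mean_diff,
            "Std Dev": c.sd_diff,
            "t-statistic": c.t,
            "p-value": c.p_band,
        }
        for name, c in report.comparisons.items()
    ]
    pd.DataFrame(
        comp_rows, columns=["Comparison", "Mean Diff", "Std Dev", "t-statistic", "p-value"]
    ).to_csv(out / "comparisons.csv", index=False, float_format="%.6f")
    write_features_csv(
        [f for f, _ in report.features], out / "features.csv",
        labels=[lab for _, lab in report.features],
    )
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2, sort_keys=True))
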