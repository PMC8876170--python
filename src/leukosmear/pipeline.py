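"""End-to-end orchestration of the three system variants.

``handcrafted``      enhance -> region growing -> ROI -> LBP+GLCM+FCH fusion
                     -> MLP (ann/ffnn preset) or max-margin classifier
``cnn``              enhance -> micro CNN trained end to end (softmax head)
``hybrid_cnn_svm``   enhance -> micro CNN as feature extractor -> max-margin
                     classifier on the tap-layer features

Records are streamed: each image is loaded, processed to its feature row and
released, so dataset size is bounded by the feature table, not the images.
Identical config + seed produce byte-identical report JSON.  The global seed
fans out to per-stage seeds through a stable hash of the stage name, so a
stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from . import classify, data, evaluate, features, segment
from .cnn import MicroCNN, MicroCNNSpec
from .enhance import EnhancementConfig, enhance
from .raster import ImageRecord, read_image, read_manifest, to_grayscale, normalize_channels
from .synth import SmearSynthParams, generate_smear

__all__ = ["RunConfig", "LazyRecord", "run_pipeline",
           "dataset_from_manifest", "dataset_from_synthetic", "stage_seed"]

logger = logging.getLogger(__name__)

MODES = ("handcrafted", "cnn", "hybrid_cnn_svm")
CLASSIFIERS = ("ffnn", "ann", "svm")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed mixed with a stable hash of the stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class RunConfig:
    """Validated parameter blocks for one pipeline run."""

    mode: str = "handcrafted"
    classifier: str = "ffnn"
    seed: int = 0
    color_normalize: bool = True
    enhancement: EnhancementConfig = EnhancementConfig()
    segmentation: segment.SegmentationParams = segment.SegmentationParams()
    lbp: features.LBPParams = features.LBPParams()
    glcm: features.GLCMParams = features.GLCMParams()
    fch: features.FCHParams = features.FCHParams()
    train: classify.TrainConfig = classify.TrainConfig()
    split: data.SplitSpec = data.SplitSpec()
    augment_factors: dict = field(default_factory=dict)  # empty = no augmentation
    cnn_spec: MicroCNNSpec = MicroCNNSpec()
    cnn_epochs: int = 100
    cnn_learning_rate: float = 0.05
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")

    def digest(self) -> str:
        blob = repr(self.to_dict()).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: conv(getattr(v, k)) for k in sorted(
                    f.name for f in dataclasses.fields(v))}
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(v[k]) for k in sorted(v)}
            if isinstance(v, (tuple, list)):
                return [conv(x) for x in v]
            return v
        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class LazyRecord:
    """A dataset entry whose pixels are loaded on demand."""

    source_id: str
    label: str
    loader: Callable[[], np.ndarray]


def dataset_from_manifest(manifest_path: str | Path) -> list[LazyRecord]:
    """Lazy records from a manifest CSV with columns source_id, path, label."""
    df = read_manifest(manifest_path)
    return [LazyRecord(row.source_id, row.label,
                       loader=(lambda p: (lambda: read_image(p)))(row.path))
            for row in df.itertuples()]


def dataset_from_synthetic(n_per_class: int, params: SmearSynthParams,
                           seed: int) -> list[LazyRecord]:
    """Lazy records regenerated on demand from the synthetic-smear generator."""
    records = []
    idx = 0
    for label in ("leukemia", "normal"):
        for _ in range(n_per_class):
            sample_seed = seed * 100000 + idx
            records.append(LazyRecord(
                f"synth_{label}_{idx:04d}", label,
                loader=(lambda s, l: (lambda: generate_smear(params, s, l).image))(
                    sample_seed, label)))
            idx += 1
    return records


def _prepare_image(img: np.ndarray, config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """(color image for segmentation/FCH, enhanced image for texture features)."""
    if img.ndim == 3 and config.color_normalize:
        img = normalize_channels(img)
    enhanced = enhance(img, config.enhancement)
    return img, enhanced


def _handcrafted_row(img: np.ndarray, config: RunConfig) -> np.ndarray:
    """One fused 232-entry feature row for a color image.

    Region growing runs on the luminance of the (normalized) input image —
    its noise statistics are stable, unlike the Laplacian-sharpened image —
    while all descriptors are computed on the enhanced image inside the
    refined ROI.
    """
    color, enhanced = _prepare_image(img, config)
    label_map = segment.region_grow(to_grayscale(color), config.segmentation)
    roi = segment.select_roi(label_map, color, config.segmentation)
    roi = segment.morphological_refine(roi)
    gray_enh = to_grayscale(enhanced)
    fused = features.extract_fused(
        enhanced if enhanced.ndim == 3 else np.dstack([enhanced] * 3),
        gray_enh, roi, config.lbp, config.glcm, config.fch)
    return fused.values


def _cnn_input(img: np.ndarray, config: RunConfig) -> np.ndarray:
    """Enhanced luminance resized to the micro CNN input grid, scaled to [0, 1]."""
    _, enhanced = _prepare_image(img, config)
    gray = to_grayscale(enhanced)
    size = config.cnn_spec.input_size
    return sktransform.resize(gray, (size, size), preserve_range=True,
                              anti_aliasing=True) / 255.0


def run_pipeline(config: RunConfig, dataset: list[LazyRecord],
                 out_dir: str | Path | None = None) -> evaluate.EvaluationReport:
    """Execute the configured variant over the dataset and assemble the report.

    When ``out_dir`` is given, writes ``features.csv``, ``report.json`` and a
    reproducibility record (config, seed, dataset digest).
    """
    if not dataset:
        raise ValueError("dataset is empty")
    split_spec = dataclasses.replace(config.split, seed=stage_seed(config.seed, "split"))
    parts = data.split(dataset, split_spec)

    # Optional class-balanced augmentation of the training partition only.
    work: list[tuple[str, str, str, Callable[[], np.ndarray]]] = []
    aug_spec = (data.AugmentationSpec(factors=config.augment_factors,
                                      seed=stage_seed(config.seed, "augment"))
                if config.augment_factors else None)
    for rec, part in zip(dataset, parts):
        work.append((rec.source_id, rec.label, part, rec.loader))
    n_augmented = 0

    rows: list[np.ndarray] = []
    row_meta: list[tuple[str, str, str]] = []  # (source_id, label, partition)
    extract = _handcrafted_row if config.mode == "handcrafted" else _cnn_input
    for source_id, label, part, loader in work:
        img = loader()
        variants = [(source_id, img)]
        if aug_spec is not None and part == "train":
            base = ImageRecord(image=img, label=label, source_id=source_id)
            variants = [(r.source_id, r.image) for r in data.augment([base], aug_spec)]
            n_augmented += len(variants) - 1
        for vid, vimg in variants:
            try:
                rows.append(extract(vimg, config))
            except Exception as exc:
                raise RuntimeError(
                    f"stage {'features' if config.mode == 'handcrafted' else 'cnn-input'}"
                    f" failed on record {vid}") from exc
            row_meta.append((vid, label, part))
        logger.debug("processed %s (%s, %s)", source_id, label, part)

    x = np.stack(rows)
    labels = np.array([1 if m[1] == "leukemia" else 0 for m in row_meta])
    partitions = np.array([m[2] for m in row_meta])
    train_mask = partitions == "train"
    test_mask = partitions == "test"
    logger.info("feature matrix %s; train/val/test = %d/%d/%d (+%d augmented)",
                x.shape, train_mask.sum(), (partitions == "validation").sum(),
                test_mask.sum(), n_augmented)

    trace = None
    if config.mode == "handcrafted":
        feature_source = "fused:lbp+glcm+fch"
        if config.classifier == "svm":
            model = classify.train_max_margin(x[train_mask], labels[train_mask],
                                              C=config.svm_c)
            classifier_name = "max_margin"
        else:
            objective = "mse" if config.classifier == "ann" else "cross_entropy"
            train_cfg = dataclasses.replace(
                config.train, objective=objective,
                seed=stage_seed(config.seed, "train_mlp"))
            model, trace = classify.train_mlp(x, labels, partitions, train_cfg)
            classifier_name = f"mlp_{config.classifier}"
        y_pred, scores = classify.predict(model, x[test_mask])
    else:
        imgs = x.reshape(x.shape[0], config.cnn_spec.input_size, config.cnn_spec.input_size)
        # Center on the training-partition mean: the raw [0, 1] planes sit
        # near 0.8 (pale background), and an uncentered input destabilizes
        # the first training steps.
        imgs = imgs - imgs[train_mask].mean()
        net = MicroCNN(config.cnn_spec, seed=stage_seed(config.seed, "cnn"))
        net.fit(imgs[train_mask], labels[train_mask], epochs=config.cnn_epochs,
                learning_rate=config.cnn_learning_rate)
        if config.mode == "cnn":
            probs = net.predict_proba(imgs[test_mask])
            y_pred, scores = probs.argmax(axis=1), probs[:, 1]
            feature_source, classifier_name = "cnn:softmax", "micro_cnn"
        else:
            deep_train = net.features(imgs[train_mask])
            deep_test = net.features(imgs[test_mask])
            model = classify.train_max_margin(deep_train, labels[train_mask],
                                              C=config.svm_c)
            y_pred, scores = classify.predict(model, deep_test)
            feature_source, classifier_name = "cnn:tap", "max_margin"

    report = evaluate.evaluate_scores(labels[test_mask], y_pred, scores)
    report.extras = {
        "mode": config.mode,
        "feature_source": feature_source,
        "classifier": classifier_name,
        "seed": int(config.seed),
        "config_digest": config.digest(),
        "n_train": int(train_mask.sum()),
        "n_validation": int((partitions == "validation").sum()),
        "n_test": int(test_mask.sum()),
        "n_augmented": int(n_augmented),
    }
    if trace is not None:
        report.extras["train_trace"] = {
            "best_epoch": trace.best_epoch,
            "stopped_epoch": trace.stopped_epoch,
            "final_train_loss": trace.train_loss[-1],
            "final_val_loss": trace.val_loss[-1],
        }

    if out_dir is not None:
        _write_artifacts(Path(out_dir), config, dataset, x, row_meta, report)
    return report


def report_to_dict(report: evaluate.EvaluationReport) -> dict:
    cm = report.confusion
    return {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "accuracy": report.accuracy,
        "precision": report.precision,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "auc": report.auc,
        "roc_points": report.roc_points.tolist(),
        "error_histogram": {
            "edges": report.error_bin_edges.tolist(),
            "counts": report.error_bin_counts.tolist(),
        },
        "regression_r": report.regression_r,
        **{k: v for k, v in sorted(report.extras.items())},
    }


def _write_artifacts(out_dir: Path, config: RunConfig, dataset: list,
                     x: np.ndarray, row_meta: list, report) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.mode == "handcrafted":
        cols = list(features.feature_names())
        df = pd.DataFrame(x, columns=cols)
        df.insert(0, "partition", [m[2] for m in row_meta])
        df.insert(0, "label", [m[1] for m in row_meta])
        df.insert(0, "source_id", [m[0] for m in row_meta])
        df.to_csv(out_dir / "features.csv", index=False)
    (out_dir / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True))
    repro = {
        "config": config.to_dict(),
        "seed": int(config.seed),
        "dataset_digest": hashlib.sha256(
            ",".join(r.source_id for r in dataset).encode()).hexdigest()[:16],
        "n_records": len(dataset),
    }
    (out_dir / "reproducibility.json").write_text(json.dumps(repro, indent=2, sort_keys=True))
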