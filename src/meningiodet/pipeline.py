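"""End-to-end orchestration: config, training, evaluation, segmentation runs.

The pipeline wires the stages together in the order the method prescribes:
ridgelet decomposition -> intensity features -> hybrid CNN + SFCM classifier,
then the probability-based morphological segmenter on slices labelled
meningioma. Everything is driven by a single validated configuration that
round-trips through YAML, and every run is reproducible from its master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, field_validator

from . import hcnn
from .features import FEATURE_NAMES
from .image_io import (
    MENINGIOMA,
    ValidationError,
    load_image,
    load_manifest,
    load_mask,
    save_mask,
)
from .metrics import aggregate_reports, compute_metrics, confusion_counts, MetricsReport
from .segmentation import SegmentationMask, StructuringElement, segment

log = logging.getLogger("meningiodet")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; round-trips losslessly through YAML."""

    # classifier architecture / training (see HCNNConfig for semantics)
    conv1_filters: int = 512
    conv1_kernel: int = 5
    conv2_filters: int = 1024
    conv2_kernel: int = 7
    pool_size: int = 2
    pool_mode: str = "max"
    fuzzifier_m: float = 2.0
    spatial_p: float = 1.0
    spatial_q: float = 1.0
    neighborhood_radius: int = 1
    max_iter: int = 100
    tol: float = 1.0e-5
    train_filters: str = "backprop"
    embed_dim: int = 16
    epochs: int = 12
    batch_size: int = 16
    learning_rate: float = 1.0e-3
    center_loss_weight: float = 0.1
    # ridgelet / feature front end
    wavelet: str = "haar"
    block: int = 8
    stride: int = 4
    features: tuple = FEATURE_NAMES
    # segmentation
    se_radius: int = 3
    min_area: int = 30
    delta_floor: float = 5.0
    # evaluation
    metrics_convention: str = "standard"
    segment_only_positive_calls: bool = True
    # reproducibility
    seed: int = 0

    @field_validator("features", mode="before")
    @classmethod
    def _tuple_features(cls, v):
        return tuple(v)

    @field_validator("metrics_convention")
    @classmethod
    def _known_convention(cls, v):
        if v not in ("standard", "paper_literal"):
            raise ValueError(f"unknown metrics convention {v!r}")
        return v

    def hcnn_config(self) -> hcnn.HCNNConfig:
        return hcnn.HCNNConfig(
            conv1_filters=self.conv1_filters,
            conv1_kernel=self.conv1_kernel,
            conv2_filters=self.conv2_filters,
            conv2_kernel=self.conv2_kernel,
            pool_size=self.pool_size,
            pool_mode=self.pool_mode,
            fuzzifier_m=self.fuzzifier_m,
            spatial_p=self.spatial_p,
            spatial_q=self.spatial_q,
            neighborhood_radius=self.neighborhood_radius,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
            wavelet=self.wavelet,
            block=self.block,
            stride=self.stride,
            features=self.features,
            train_filters=self.train_filters,
            embed_dim=self.embed_dim,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            center_loss_weight=self.center_loss_weight,
        )

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


def _setup_run_logging(out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    if not any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", "").startswith(os.path.abspath(out_dir))
        for h in log.handlers
    ):
        handler = logging.FileHandler(os.path.join(out_dir, "run.log"))
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.INFO)


def run_train(
    config: PipelineConfig, manifest_path: str, out_dir: str
) -> str:
    """Train the classifier on the manifest's training split.

    Writes ``model.zip`` (deterministic archive) and ``training_log.txt``
    (one line per epoch) into ``out_dir``; returns the model path.
    """
    _setup_run_logging(out_dir)
    t0 = time.time()
    manifest = load_manifest(manifest_path)
    log.info("train: config digest %s seed %d", config.digest(), config.seed)
    model = hcnn.train(manifest, config.hcnn_config())
    model_path = os.path.join(out_dir, "model.zip")
    hcnn.save_model(model, model_path)
    with open(os.path.join(out_dir, "training_log.txt"), "w") as fh:
        for epoch, loss in enumerate(model.training_loss, start=1):
            fh.write(f"epoch {epoch} loss {loss:.6f}\n")
    log.info("train: finished in %.1fs -> %s", time.time() - t0, model_path)
    return model_path


def _classification_counts(records, predictions) -> "tuple[int, int, int, int]":
    A = B = C = D = 0
    for rec, pred in zip(records, predictions):
        truth_pos = rec.label == MENINGIOMA
        pred_pos = pred == MENINGIOMA
        if truth_pos and pred_pos:
            D += 1
        elif truth_pos:
            C += 1
        elif pred_pos:
            B += 1
        else:
            A += 1
    return A, B, C, D


def run_evaluate(
    config: PipelineConfig,
    manifest_path: str,
    model_path: str,
    out_dir: str,
) -> dict:
    """Classify the test split, segment predicted-positive slices, score both.

    Writes ``report.csv`` (one row per test image plus an Average row) and
    ``report.json``; returns the summary dict.
    """
    _setup_run_logging(out_dir)
    manifest = load_manifest(manifest_path)
    test = manifest.subset("test")
    if not len(test):
        raise ValidationError("manifest has no test split")
    model = hcnn.load_model(model_path)
    se = StructuringElement(radius=config.se_radius)

    rows = []
    seg_reports = []
    predictions = []
    for rec in test.records:
        image = load_image(rec.image_path)
        result = hcnn.classify(image, model)
        predictions.append(result.label)
        row = {
            "source_id": image.source_id,
            "label": rec.label,
            "predicted": result.label,
            "membership": round(result.memberships[result.label], 6),
        }
        wants_segmentation = (
            result.label == MENINGIOMA
            if config.segment_only_positive_calls
            else rec.label == MENINGIOMA
        )
        if wants_segmentation:
            mask = segment(
                image, se, min_area=config.min_area, delta_floor=config.delta_floor
            )
            if rec.mask_path:
                truth = SegmentationMask(load_mask(rec.mask_path))
                report = compute_metrics(
                    confusion_counts(mask, truth), config.metrics_convention
                )
                seg_reports.append(report)
                for name in MetricsReport.METRIC_NAMES:
                    value = getattr(report, name)
                    row[name] = None if value is None else round(value, 4)
            else:
                log.warning(
                    "no ground-truth mask for %s; classification-only row",
                    rec.image_path,
                )
        rows.append(row)

    A, B, C, D = _classification_counts(test.records, predictions)
    cls_report = compute_metrics(
        confusion_counts(
            np.array([[p == MENINGIOMA for p in predictions]]),
            np.array([[r.label == MENINGIOMA for r in test.records]]),
        ),
        config.metrics_convention,
    )
    summary = {
        "n_test": len(test),
        "classification_accuracy": (A + D) / len(test),
        "classification_sensitivity": cls_report.sensitivity,
        "classification_specificity": cls_report.specificity,
        "confusion": {"A": A, "B": B, "C": C, "D": D},
    }
    if seg_reports:
        average = aggregate_reports(seg_reports)
        avg_row = {"source_id": "Average", "label": "", "predicted": "", "membership": np.nan}
        for name in MetricsReport.METRIC_NAMES:
            value = getattr(average, name)
            avg_row[name] = np.nan if value is None else round(value, 4)
            summary[f"segmentation_mean_{name}"] = value
        rows.append(avg_row)
    df = pd.DataFrame(rows)

    os.makedirs(out_dir, exist_ok=True)
    df.to_csv(os.path.join(out_dir, "report.csv"), index=False)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("evaluate: accuracy %.3f on %d test images", summary["classification_accuracy"], len(test))
    return summary


def run_segment_only(
    config: PipelineConfig,
    image_path: str,
    out_path: str,
    overlay_path: Optional[str] = None,
) -> SegmentationMask:
    """Segment a single slice without any trained model."""
    image = load_image(image_path)
    mask = segment(
        image,
        StructuringElement(radius=config.se_radius),
        min_area=config.min_area,
        delta_floor=config.delta_floor,
    )
    save_mask(mask, out_path)
    if overlay_path:
        _save_overlay(image, mask, overlay_path)
    return mask


def _save_overlay(image, mask: SegmentationMask, path: str) -> None:
    from PIL import Image as PILImage

    rgb = np.stack([image.pixels] * 3, axis=-1).astype(np.uint8)
    rgb[mask.mask, 0] = 255  # tumor outline channel
    rgb[mask.mask, 1] = rgb[mask.mask, 1] // 2
    rgb[mask.mask, 2] = rgb[mask.mask, 2] // 2
    PILImage.fromarray(rgb, mode="RGB").save(path, format="PNG")


def run_ablation(
    config: PipelineConfig,
    manifest_path: str,
    out_dir: str,
    feature_sets: Optional[Sequence[Sequence[str]]] = None,
) -> pd.DataFrame:
    """Train/evaluate the classifier once per feature subset.

    Defaults to the full set plus each single feature, mirroring the
    feature-combination study design. Writes ``ablation.csv``.
    """
    _setup_run_logging(out_dir)
    manifest = load_manifest(manifest_path)
    test = manifest.subset("test")
    if feature_sets is None:
        feature_sets = [FEATURE_NAMES] + [(f,) for f in FEATURE_NAMES]
    rows = []
    for features in feature_sets:
        cfg = config.model_copy(update={"features": tuple(features)})
        model = hcnn.train(manifest, cfg.hcnn_config())
        correct = sum(
            hcnn.classify(load_image(r.image_path), model).label == r.label
            for r in test.records
        )
        acc = correct / len(test)
        rows.append({"features": "+".join(features), "test_accuracy": acc})
        log.info("ablation %-24s accuracy %.3f", "+".join(features), acc)
    df = pd.DataFrame(rows)
    os.makedirs(out_dir, exist_ok=True)
    df.to_csv(os.path.join(out_dir, "ablation.csv"), index=False)
    return df
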