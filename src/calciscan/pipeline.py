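"""End-to-end orchestration: extract -> featurize -> classify -> score.

Also hosts the fully synthetic detection experiment (train a model and an
atlas on one set of phantoms, evaluate on held-out phantoms) that the test
suite and the reproduction script both run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .detection import (
    Atlas,
    AffineTransform,
    ClassifierModel,
    DetectionConfig,
    build_atlas,
    classify,
    featurize,
    fov_transform,
    train_classifier,
)
from .extraction import Candidate, ExtractionConfig, extract_candidates
from .phantom import generate_phantom, random_phantom_config
from .scoring import ScoreConfig, ScoreRecord, score_scan
from .volume import CTVolume

logger = logging.getLogger("calciscan")

__all__ = [
    "RunConfig",
    "label_candidates_by_mask",
    "score_volume",
    "run_pipeline",
    "DetectionExperiment",
    "run_detection_experiment",
]


@dataclass
class RunConfig:
    """Paths and parameters for a batch scoring run."""

    volume_paths: list[Path]
    model_path: Path
    atlas_path: Path
    out_csv: Path
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    scoring: ScoreConfig = field(default_factory=ScoreConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    seed: int = 0


def label_candidates_by_mask(
    candidates: list[Candidate], mask: np.ndarray, min_overlap: float = 0.5
) -> np.ndarray:
    """Binary truth labels: 1 where a candidate overlaps the coronary mask.

    A candidate counts as coronary when at least ``min_overlap`` of its
    voxels lie inside the ground-truth mask (noise can append a few
    off-mask voxels to a true lesion).
    """
    labels = np.zeros(len(candidates), dtype=int)
    for i, cand in enumerate(candidates):
        inside = mask[cand.voxels[:, 0], cand.voxels[:, 1], cand.voxels[:, 2]]
        if inside.mean() >= min_overlap:
            labels[i] = 1
    return labels


def score_volume(
    volume: CTVolume,
    model: ClassifierModel,
    atlas: Atlas,
    transform: AffineTransform | None = None,
    extraction: ExtractionConfig | None = None,
    scoring: ScoreConfig | None = None,
) -> tuple[ScoreRecord, list[Candidate]]:
    """Score one scan: extract candidates, classify them, quantify calcium."""
    extraction = extraction or ExtractionConfig()
    if scoring is None:
        thickness = volume.meta.get("slice_thickness_mm", 3.1)
        scoring = ScoreConfig(thickness_factor=thickness / 3.0)
    transform = transform or fov_transform(volume)
    candidates = extract_candidates(volume, extraction)
    features = featurize(candidates, volume, atlas, transform, model.config)
    labels, _ = classify(model, features)
    for cand, lab in zip(candidates, labels):
        cand.label = "coronary" if lab == 1 else "non-coronary"
    return score_scan(candidates, scoring, scan_id=volume.scan_id), candidates


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Batch scoring over volume files; one row per scan, failures logged.

    Writes the score table CSV to ``config.out_csv``; raises only if every
    scan fails.  Deterministic given the model, atlas and inputs.
    """
    model = cio.load_model(config.model_path)
    atlas, transform = cio.load_atlas(config.atlas_path)
    records, failures = [], []
    for path in config.volume_paths:
        try:
            volume = cio.read_volume(path)
            record, _ = score_volume(
                volume, model, atlas, transform, config.extraction, config.scoring
            )
            records.append(record)
        except Exception as exc:  # per-scan robustness is the contract here
            logger.warning("scan %s failed: %s", path, exc)
            failures.append((path, exc))
    if not config.volume_paths:
        logger.warning("no input volumes")
    if failures and not records:
        raise RuntimeError(f"all {len(failures)} scans failed; first: {failures[0][1]}")
    cio.write_score_table(records, config.out_csv)
    return cio.read_score_table(config.out_csv)


@dataclass
class DetectionExperiment:
    """Results of the synthetic train/held-out-evaluate experiment."""

    candidate_accuracy: float
    n_candidates: int
    truth_records: list[ScoreRecord]
    auto_records: list[ScoreRecord]
    model: ClassifierModel
    atlas: Atlas


def run_detection_experiment(
    seed: int = 0,
    n_train: int = 50,
    n_test: int = 50,
    noise_sd_hu: float = 20.0,
    shape: tuple[int, int, int] = (32, 80, 80),
    atlas_smoothing: float = 0.5,
    detection: DetectionConfig | None = None,
) -> DetectionExperiment:
    """Train and evaluate the detector entirely on seeded phantoms.

    ``n_train`` phantoms provide the atlas (from their ground-truth masks)
    and the classifier training set (candidates labelled by mask overlap);
    ``n_test`` independent phantoms are extracted, classified and scored.
    Per-candidate accuracy and the paired truth/automated score tables are
    returned for downstream agreement analysis.
    """
    detection = detection or DetectionConfig()
    rng = np.random.default_rng(seed)
    train_seeds = rng.integers(0, 2**31 - 1, size=n_train)
    test_seeds = rng.integers(0, 2**31 - 1, size=n_test)

    train_masks, train_transforms = [], []
    train_data = []  # (volume, truth, candidates)
    for s in train_seeds:
        cfg = random_phantom_config(int(s), shape=shape, noise_sd_hu=noise_sd_hu)
        volume, truth = generate_phantom(cfg)
        train_masks.append((truth.mask, volume.spacing, volume.origin))
        train_transforms.append(fov_transform(volume))
        train_data.append((volume, truth))
    atlas = build_atlas(train_masks, train_transforms, smoothing=atlas_smoothing)

    feats, labels = [], []
    for volume, truth in train_data:
        candidates = extract_candidates(volume)
        if not candidates:
            continue
        feats.append(featurize(candidates, volume, atlas, fov_transform(volume), detection))
        labels.append(label_candidates_by_mask(candidates, truth.mask))
    features = np.vstack(feats)
    labels = np.concatenate(labels)
    model = train_classifier(features, labels, detection, seed=seed)

    n_correct = n_total = 0
    truth_records, auto_records = [], []
    for s in test_seeds:
        cfg = random_phantom_config(int(s), shape=shape, noise_sd_hu=noise_sd_hu)
        volume, truth = generate_phantom(cfg)
        record, candidates = score_volume(volume, model, atlas)
        true_labels = label_candidates_by_mask(candidates, truth.mask)
        pred = np.array([1 if c.label == "coronary" else 0 for c in candidates])
        n_correct += int((pred == true_labels).sum())
        n_total += len(candidates)
        truth_records.append(truth.score)
        auto_records.append(record)
    return DetectionExperiment(
        candidate_accuracy=n_correct / max(n_total, 1),
        n_candidates=n_total,
        truth_records=truth_records,
        auto_records=auto_records,
        model=model,
        atlas=atlas,
    )
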