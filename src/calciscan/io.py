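"""Readers and writers for volumes, masks, tables, models and reports.

Volumes and masks travel as NIfTI (``.nii``/``.nii.gz``) or MetaImage
(``.mha``/``.mhd``); ITK stores spacing/origin in (x, y, z) order, which is
reversed to this package's (z, y, x) convention on the way in and out.
Score tables are CSV with the fixed header
``scan_id,agatston,volume_mm3,n_lesions,category``.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .detection import AffineTransform, Atlas, ClassifierModel
from .extraction import Candidate
from .scoring import ScoreRecord
from .volume import CTVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_score_table",
    "read_score_table",
    "write_candidates_json",
    "write_candidate_labelmap",
    "save_model",
    "load_model",
    "save_atlas",
    "load_atlas",
]

SCORE_COLUMNS = ["scan_id", "agatston", "volume_mm3", "n_lesions", "category"]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(f"unsupported volume format: {path.name} (use .nii[.gz], .mha, .mhd)")


def _check_metaimage_spacing(path: Path) -> None:
    """MetaImage headers may omit ElementSpacing, which ITK silently maps to
    1 mm.  Scoring depends on spacing, so that silence is an error here."""
    header = b""
    with open(path, "rb") as fh:
        while b"ElementDataFile" not in header and len(header) < 65536:
            chunk = fh.readline()
            if not chunk:
                break
            header += chunk
    text = header.decode("latin-1", errors="replace")
    if "ElementSpacing" not in text and "ElementSize" not in text:
        raise ValueError(f"{path}: no ElementSpacing in MetaImage header; refusing to assume 1 mm")


def read_volume(path) -> CTVolume:
    """Read a CT volume (NIfTI or MetaImage) into a :class:`CTVolume`."""
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".mha", ".mhd"):
        _check_metaimage_spacing(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"{path}: invalid voxel spacing {spacing}")
    meta = {}
    if img.HasMetaDataKey("slice_thickness_mm"):
        meta["slice_thickness_mm"] = float(img.GetMetaData("slice_thickness_mm"))
    return CTVolume(arr.astype(float), spacing, origin, scan_id=path.name.split(".")[0], meta=meta)


def write_volume(volume: CTVolume, path) -> Path:
    """Write a volume with spacing/origin metadata; format from the suffix."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.asarray(volume.hu, dtype=np.float32))
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    if "slice_thickness_mm" in volume.meta:
        img.SetMetaData("slice_thickness_mm", str(volume.meta["slice_thickness_mm"]))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def write_mask(mask: np.ndarray, like: CTVolume, path) -> Path:
    """Write a binary mask on the grid of ``like``."""
    return write_volume(
        CTVolume(mask.astype(np.uint8), like.spacing, like.origin, scan_id=like.scan_id), path
    )


def read_mask(path) -> tuple[np.ndarray, CTVolume]:
    vol = read_volume(path)
    return vol.hu > 0, vol


def write_score_table(records: list[ScoreRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([r.to_dict() for r in records], columns=SCORE_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing score columns {sorted(missing)}")
    return df


def write_candidates_json(candidates: list[Candidate], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([c.to_dict() for c in candidates], indent=1))
    return path


def write_candidate_labelmap(candidates: list[Candidate], like: CTVolume, path) -> Path:
    """Labeled mask volume with 1-based candidate ids as voxel values."""
    labels = np.zeros(like.shape, dtype=np.uint16)
    for i, cand in enumerate(candidates, start=1):
        labels[cand.voxels[:, 0], cand.voxels[:, 1], cand.voxels[:, 2]] = i
    return write_volume(CTVolume(labels, like.spacing, like.origin), path)


def save_model(model: ClassifierModel, path) -> Path:
    """Persist a fitted classifier (single joblib archive)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)
    return path


def load_model(path) -> ClassifierModel:
    return joblib.load(path)


def save_atlas(atlas: Atlas, path, transform: AffineTransform | None = None) -> Path:
    """Atlas probability map as a volume, with frame metadata in a sidecar JSON."""
    path = Path(path)
    write_volume(
        CTVolume(atlas.prob, tuple(atlas.ref_spacing), tuple(atlas.ref_origin)), path
    )
    sidecar = {
        "smoothing": atlas.smoothing,
        "n_training": atlas.n_training,
        "transform": transform.to_dict() if transform else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_atlas(path) -> tuple[Atlas, AffineTransform | None]:
    path = Path(path)
    vol = read_volume(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    smoothing, n_training, transform = 0.0, 0, None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        smoothing = sidecar.get("smoothing", 0.0)
        n_training = sidecar.get("n_training", 0)
        if sidecar.get("transform"):
            transform = AffineTransform.from_dict(sidecar["transform"])
    atlas = Atlas(
        prob=np.clip(vol.hu, 0.0, 1.0),
        ref_spacing=np.asarray(vol.spacing),
        ref_origin=np.asarray(vol.origin),
        smoothing=smoothing,
        n_training=n_training,
    )
    return atlas, transform
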