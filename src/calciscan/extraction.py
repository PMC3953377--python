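"""Calcification candidate extraction.

A candidate is any 3D connected component of voxels at or above the
calcium attenuation threshold (130 HU by convention).  Candidates are the
unit that the detection stage classifies as coronary calcification or not,
and that the scoring stage quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "CALCIUM_THRESHOLD_HU",
    "Candidate",
    "ExtractionConfig",
    "SliceStat",
    "threshold_mask",
    "label_components",
    "extract_candidates",
    "candidate_from_voxels",
]

#: Standard attenuation threshold for calcified plaque, inclusive.
CALCIUM_THRESHOLD_HU = 130.0

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SliceStat:
    """Per-slice geometry of a candidate: axial area and peak attenuation."""

    z: int
    area_mm2: float
    max_hu: float


@dataclass
class Candidate:
    """One connected component of above-threshold voxels.

    ``voxels`` is an ``(n, 3)`` integer array of (z, y, x) indices.  The
    ``label`` starts as ``"unclassified"`` and is set by the classifier to
    ``"coronary"`` or ``"non-coronary"``.
    """

    voxels: np.ndarray
    centroid_mm: np.ndarray
    bbox: tuple[tuple[int, int, int], tuple[int, int, int]]
    volume_mm3: float
    max_hu: float | None = None
    slices: list[SliceStat] = field(default_factory=list)
    label: str = "unclassified"
    oversize: bool = False

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def to_dict(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "centroid_mm": [float(c) for c in self.centroid_mm],
            "bbox": [list(map(int, b)) for b in self.bbox],
            "volume_mm3": float(self.volume_mm3),
            "max_hu": None if self.max_hu is None else float(self.max_hu),
            "slices": [
                {"z": s.z, "area_mm2": s.area_mm2, "max_hu": s.max_hu} for s in self.slices
            ],
            "label": self.label,
            "oversize": self.oversize,
        }


@dataclass
class ExtractionConfig:
    """Parameters of the thresholding / connected-component stage.

    ``min_volume_mm3`` drops tiny specks before classification (default 0:
    keep everything).  Components above ``max_volume_mm3`` (typically bone)
    are flagged ``oversize`` but never dropped — rejecting them is the
    classifier's job.
    """

    threshold_hu: float = CALCIUM_THRESHOLD_HU
    connectivity: int = 26
    min_volume_mm3: float = 0.0
    max_volume_mm3: float = math.inf

    def __post_init__(self) -> None:
        if self.threshold_hu < 0:
            raise ValueError("threshold must be >= 0 HU")
        if self.connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")


def threshold_mask(volume: CTVolume, threshold_hu: float = CALCIUM_THRESHOLD_HU) -> np.ndarray:
    """Binary mask of voxels with HU >= ``threshold_hu`` (inclusive)."""
    return volume.hu >= threshold_hu


def _candidate_stats(
    voxels: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    hu: np.ndarray | None,
) -> Candidate:
    spacing_arr = np.asarray(spacing)
    centroid = np.asarray(origin) + voxels.mean(axis=0) * spacing_arr
    bbox = (tuple(int(v) for v in voxels.min(axis=0)), tuple(int(v) for v in voxels.max(axis=0)))
    voxel_volume = float(np.prod(spacing_arr))
    pixel_area = float(spacing_arr[1] * spacing_arr[2])
    cand = Candidate(
        voxels=voxels,
        centroid_mm=centroid,
        bbox=bbox,
        volume_mm3=voxels.shape[0] * voxel_volume,
    )
    if hu is not None:
        values = hu[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        cand.max_hu = float(values.max())
        for z in np.unique(voxels[:, 0]):
            in_slice = voxels[:, 0] == z
            cand.slices.append(
                SliceStat(
                    z=int(z),
                    area_mm2=float(in_slice.sum() * pixel_area),
                    max_hu=float(values[in_slice].max()),
                )
            )
    return cand


def label_components(
    mask: np.ndarray,
    connectivity: int = 26,
    volume: CTVolume | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> list[Candidate]:
    """3D connected-component labeling of a binary mask.

    Components are maximal connected sets under the 6-, 18- or
    26-neighbourhood, returned in deterministic order of their bounding-box
    minimum corner ``(z, y, x)``.  When ``volume`` is given, intensity and
    per-slice statistics are filled in; otherwise only geometry.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    if volume is not None:
        spacing = volume.spacing
        origin = volume.origin
        hu = volume.hu
    else:
        spacing = spacing or (1.0, 1.0, 1.0)
        origin = (0.0, 0.0, 0.0)
        hu = None
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    candidates = []
    for component in ndimage.value_indices(labeled, ignore_value=0).values():
        voxels = np.stack(component, axis=1).astype(np.intp)
        candidates.append(_candidate_stats(voxels, spacing, origin, hu))
    candidates.sort(key=lambda c: c.bbox[0])
    return candidates


def extract_candidates(volume: CTVolume, config: ExtractionConfig | None = None) -> list[Candidate]:
    """Threshold a CT volume and label its connected components.

    Composition of :func:`threshold_mask` and :func:`label_components`,
    followed by the minimum-volume filter and oversize flagging from the
    config.
    """
    config = config or ExtractionConfig()
    mask = threshold_mask(volume, config.threshold_hu)
    candidates = label_components(mask, config.connectivity, volume=volume)
    kept = [c for c in candidates if c.volume_mm3 >= config.min_volume_mm3]
    for c in kept:
        c.oversize = c.volume_mm3 > config.max_volume_mm3
    return kept


def candidate_from_voxels(voxels: np.ndarray, volume: CTVolume) -> Candidate:
    """Build a fully-populated candidate from an explicit voxel index set.

    Used to score ground-truth lesion geometry directly, bypassing
    thresholding.
    """
    voxels = np.asarray(voxels, dtype=np.intp)
    if voxels.ndim != 2 or voxels.shape[1] != 3 or voxels.shape[0] == 0:
        raise ValueError("voxels must be a nonempty (n, 3) index array")
    return _candidate_stats(voxels, volume.spacing, volume.origin, volume.hu)
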