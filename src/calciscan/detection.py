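"""Coronary calcium detection: spatial atlas, features, kNN+SVM classifier.

Candidates from the extraction stage are described by size, spatial and
texture characteristics.  The spatial feature is the value of a coronary
calcium atlas — a voxelwise prior probability of coronary calcification in
a spatially normalised reference frame — at the candidate centroid.
Texture features are Gaussian scale-space measurements (smoothed intensity,
gradient magnitude, Laplacian) at multiple scales, computed in millimetre
units so anisotropic voxels are handled correctly.

Classification is a two-stage supervised system: a k-nearest-neighbour
classifier produces a posterior for every candidate; candidates whose
posterior falls inside an uncertainty band are re-decided by an RBF
support-vector machine trained on the same data.  Both degenerate
single-stage modes are reachable: band ``(0.5, 0.5)`` is pure kNN (with odd
k the posterior never hits 0.5 exactly), band ``(0, 1)`` is pure SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .extraction import Candidate
from .volume import CTVolume

__all__ = [
    "AffineTransform",
    "Atlas",
    "DetectionConfig",
    "ClassifierModel",
    "moment_transform",
    "fov_transform",
    "build_atlas",
    "spatial_probability",
    "texture_features",
    "featurize",
    "train_classifier",
    "classify",
]


@dataclass
class AffineTransform:
    """Axis-aligned affine into the atlas reference frame.

    ``ref = (world - offset) / scale`` per axis (z, y, x).  This is the
    desk-scale stand-in for inter-subject spatial normalisation: offset and
    scale typically come from the first and second moments of a cardiac
    region mask.
    """

    scale: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("transform scale must be strictly positive")

    def apply(self, world_mm) -> np.ndarray:
        return (np.asarray(world_mm, dtype=float) - self.offset) / self.scale

    def invert(self, ref) -> np.ndarray:
        return np.asarray(ref, dtype=float) * self.scale + self.offset

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.ones(3), np.zeros(3))

    def to_dict(self) -> dict:
        return {"scale": self.scale.tolist(), "offset": self.offset.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["scale"]), np.asarray(d["offset"]))


def moment_transform(mask: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> AffineTransform:
    """Moment-matching normalisation from a binary region mask.

    Centres the region at the reference origin and scales each axis by the
    region's coordinate standard deviation.
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("mask is empty; cannot moment-match")
    coords = np.asarray(origin) + idx * np.asarray(spacing, dtype=float)
    centroid = coords.mean(axis=0)
    std = coords.std(axis=0)
    std[std <= 0] = 1.0
    return AffineTransform(scale=std, offset=centroid)


def fov_transform(volume: CTVolume, box_frac=((0.25, 0.75), (0.20, 0.60), (0.12, 0.45))) -> AffineTransform:
    """Normalisation derived from the field of view alone.

    Maps the cardiac-region box (given as fractions of the physical extent)
    to a centred unit frame.  Appropriate when the anatomy occupies a known
    part of the scan, as in the synthetic phantoms.
    """
    extent = volume.extent_mm
    box = np.asarray(box_frac) * extent[:, None]
    center = box.mean(axis=1)
    half = (box[:, 1] - box[:, 0]) / 2.0
    return AffineTransform(scale=half, offset=center)


@dataclass
class Atlas:
    """Voxelwise prior probability of coronary calcium in the reference frame."""

    prob: np.ndarray
    ref_spacing: np.ndarray
    ref_origin: np.ndarray
    smoothing: float = 0.0
    n_training: int = 0

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        self.ref_spacing = np.asarray(self.ref_spacing, dtype=float)
        self.ref_origin = np.asarray(self.ref_origin, dtype=float)
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("atlas probabilities must lie in [0, 1]")


def build_atlas(
    masks,
    transforms,
    smoothing: float = 0.0,
    ref_shape: tuple[int, int, int] = (32, 48, 48),
    ref_bounds: tuple[float, float] = (-3.0, 3.0),
    ref_spacing=None,
    ref_origin=None,
) -> Atlas:
    """Average spatially-normalised training masks into a probability map.

    Each training mask (paired with its transform into the reference frame)
    is resampled onto the reference grid by pulling: every reference voxel
    centre is mapped back to the mask and sampled trilinearly.  The
    voxelwise mean over training scans is Gaussian-smoothed (sigma in
    reference units) and clipped to [0, 1].

    ``masks`` is a sequence of ``(mask_array, spacing, origin)`` triples.
    By default the reference frame spans ``ref_bounds`` per axis; pass
    ``ref_spacing``/``ref_origin`` to pin it to an explicit grid (e.g. to
    keep an identity-transformed mask on its native grid).
    """
    masks = list(masks)
    transforms = list(transforms)
    if not masks:
        raise ValueError("at least one training mask is required")
    if len(masks) != len(transforms):
        raise ValueError("one transform per training mask is required")
    ref_shape = tuple(ref_shape)
    if ref_spacing is None:
        ref_spacing = np.array([(ref_bounds[1] - ref_bounds[0]) / n for n in ref_shape])
    else:
        ref_spacing = np.asarray(ref_spacing, dtype=float)
    if ref_origin is None:
        ref_origin = np.full(3, ref_bounds[0]) + ref_spacing / 2.0
    else:
        ref_origin = np.asarray(ref_origin, dtype=float)

    grid = np.stack(
        np.meshgrid(*(np.arange(n) for n in ref_shape), indexing="ij"), axis=0
    ).reshape(3, -1).T
    ref_coords = ref_origin + grid * ref_spacing

    acc = np.zeros(ref_shape, dtype=float)
    for (mask, spacing, origin), t in zip(masks, transforms):
        world = t.invert(ref_coords)
        idx = (world - np.asarray(origin, dtype=float)) / np.asarray(spacing, dtype=float)
        sampled = ndimage.map_coordinates(
            np.asarray(mask, dtype=float), idx.T, order=1, mode="constant", cval=0.0
        )
        acc += sampled.reshape(ref_shape)
    acc /= len(masks)
    if smoothing > 0:
        acc = ndimage.gaussian_filter(acc, sigma=smoothing / ref_spacing)
    return Atlas(
        prob=np.clip(acc, 0.0, 1.0),
        ref_spacing=ref_spacing,
        ref_origin=ref_origin,
        smoothing=smoothing,
        n_training=len(masks),
    )


def spatial_probability(atlas: Atlas, point_mm, transform: AffineTransform) -> float:
    """Trilinear atlas lookup at a world point; 0 outside the frame."""
    ref = transform.apply(point_mm)
    idx = (ref - atlas.ref_origin) / atlas.ref_spacing
    val = ndimage.map_coordinates(
        atlas.prob, np.asarray(idx, dtype=float).reshape(3, 1), order=1, mode="constant", cval=0.0
    )
    return float(val[0])


class _TextureBank:
    """Precomputed scale-space volumes so many candidates share the filters."""

    def __init__(self, volume: CTVolume, scales):
        spacing = np.asarray(volume.spacing)
        hu = volume.hu.astype(float)
        self.volume = volume
        self.scales = tuple(scales)
        self.smoothed, self.gradmag, self.laplacian = [], [], []
        for scale in self.scales:
            if scale <= 0:
                raise ValueError("texture scales must be > 0 mm")
            sigma_vox = scale / spacing
            self.smoothed.append(ndimage.gaussian_filter(hu, sigma_vox))
            grads = []
            lap = np.zeros_like(hu)
            for axis in range(3):
                order = [0, 0, 0]
                order[axis] = 1
                grads.append(ndimage.gaussian_filter(hu, sigma_vox, order=order) / spacing[axis])
                order[axis] = 2
                lap += ndimage.gaussian_filter(hu, sigma_vox, order=order) / spacing[axis] ** 2
            self.gradmag.append(np.sqrt(sum(g**2 for g in grads)))
            self.laplacian.append(lap)

    def sample(self, point_mm) -> np.ndarray:
        idx = self.volume.world_to_index(point_mm).reshape(3, 1)
        out = np.empty((len(self.scales), 3))
        for i in range(len(self.scales)):
            for j, vol in enumerate((self.smoothed[i], self.gradmag[i], self.laplacian[i])):
                out[i, j] = ndimage.map_coordinates(vol, idx, order=1, mode="nearest")[0]
        return out


def texture_features(volume: CTVolume, point_mm, scales=(1.0, 2.0, 4.0)) -> np.ndarray:
    """Gaussian scale-space measurements at a world point.

    Returns an ``(n_scales, 3)`` array of (smoothed intensity, gradient
    magnitude, Laplacian) per scale; sigmas and derivatives are in mm, so
    results are independent of voxel anisotropy up to discretisation.
    """
    return _TextureBank(volume, scales).sample(point_mm)


@dataclass
class DetectionConfig:
    """Feature and classifier hyperparameters."""

    scales_mm: tuple[float, ...] = (1.0, 2.0, 4.0)
    k: int = 15
    posterior_band: tuple[float, float] = (0.3, 0.7)
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"

    def __post_init__(self) -> None:
        lo, hi = self.posterior_band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("posterior band must satisfy 0 <= lo <= hi <= 1")


def featurize(
    candidates: list[Candidate],
    volume: CTVolume,
    atlas: Atlas,
    transform: AffineTransform,
    config: DetectionConfig | None = None,
) -> np.ndarray:
    """One feature vector per candidate, fixed ordering, unstandardised.

    Layout: [volume mm^3, atlas probability at centroid, normalised centroid
    (z, y, x), then per scale (intensity, gradient magnitude, Laplacian)].
    Standardisation is owned by the classifier model so train and apply use
    identical scaling.
    """
    config = config or DetectionConfig()
    n_features = 5 + 3 * len(config.scales_mm)
    if not candidates:
        return np.empty((0, n_features))
    bank = _TextureBank(volume, config.scales_mm)
    extent = volume.extent_mm
    rows = []
    for cand in candidates:
        centroid = np.asarray(cand.centroid_mm)
        row = [
            cand.volume_mm3,
            spatial_probability(atlas, centroid, transform),
            *((centroid - np.asarray(volume.origin)) / extent),
            *bank.sample(centroid).ravel(),
        ]
        rows.append(row)
    return np.asarray(rows, dtype=float)


@dataclass
class ClassifierModel:
    """Fitted two-stage candidate classifier with its standardisation."""

    knn: KNeighborsClassifier
    svm: SVC
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    posterior_band: tuple[float, float]
    config: DetectionConfig = field(default_factory=DetectionConfig)
    seed: int = 0

    @property
    def n_features(self) -> int:
        return int(self.feature_mean.shape[0])

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feature_mean) / self.feature_sd


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    config: DetectionConfig | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the kNN and SVM stages on z-scored features.

    ``labels`` are binary (1 = coronary calcification).  Both stages see
    the same standardised training data; the z-score statistics are stored
    on the model.
    """
    config = config or DetectionConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be (n, d) with one label per row")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd <= 0] = 1.0
    z = (features - mean) / sd
    knn = KNeighborsClassifier(n_neighbors=min(config.k, len(labels)))
    knn.fit(z, labels)
    svm = SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma, random_state=seed)
    svm.fit(z, labels)
    return ClassifierModel(
        knn=knn,
        svm=svm,
        feature_mean=mean,
        feature_sd=sd,
        posterior_band=config.posterior_band,
        config=config,
        seed=seed,
    )


def classify(model: ClassifierModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label candidates; returns ``(labels, knn_posteriors)``.

    The kNN posterior (fraction of positive neighbours) is computed for
    every candidate.  Posteriors strictly outside the band take the kNN
    decision; posteriors inside it are routed to the SVM.  Pure function of
    (model, features).
    """
    features = np.asarray(features, dtype=float)
    if features.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    if features.ndim != 2 or features.shape[1] != model.n_features:
        raise ValueError(
            f"expected (n, {model.n_features}) features, got {features.shape}"
        )
    z = model.standardize(features)
    proba = model.knn.predict_proba(z)
    pos_col = int(np.nonzero(model.knn.classes_ == 1)[0][0])
    posterior = proba[:, pos_col]
    labels = (posterior >= 0.5).astype(int)
    lo, hi = model.posterior_band
    uncertain = (posterior >= lo) & (posterior <= hi)
    if np.any(uncertain):
        labels[uncertain] = model.svm.predict(z[uncertain])
    return labels, posterior
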