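"""Synthetic non-gated chest-CT phantoms with known calcium ground truth.

The generator emulates the conditions of low-dose lung-screening CT as far
as calcium scoring is concerned: soft-tissue background in the 0-60 HU
range, calcified lesions at or above 130 HU spanning the four Agatston
density bands, additive Gaussian noise, optional motion unsharpness along
the anterior-posterior axis, and an anisotropic grid with 0.66 mm in-plane
pixels and slices reconstructed 3.1 mm thick at a 1.4 mm increment.

Lesions are spheres with a Gaussian radial attenuation profile whose value
crosses the 130 HU scoring threshold exactly at the nominal radius, so the
pre-noise thresholded geometry has an analytic volume oracle.  Distractor
calcifications (aortic, valvular, bone) live in fixed geometric territory
boxes — a desk-scale stand-in for anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .extraction import CALCIUM_THRESHOLD_HU, candidate_from_voxels
from .scoring import ScoreConfig, ScoreRecord, agatston_lesion, risk_category
from .volume import CTVolume

__all__ = [
    "Lesion",
    "RaterNoise",
    "PhantomConfig",
    "LesionRecord",
    "GroundTruth",
    "TERRITORY_BOXES",
    "generate_phantom",
    "random_phantom_config",
    "heart_mask",
    "simulate_rater_scores",
    "table1_fixture",
]

#: Axis-aligned territory boxes as fractions of the field of view,
#: ((zlo, zhi), (ylo, yhi), (xlo, xhi)).  Coronary and aortic territories
#: are deliberately well separated along x.
TERRITORY_BOXES = {
    "coronary": ((0.25, 0.75), (0.20, 0.60), (0.12, 0.45)),
    "aorta": ((0.20, 0.80), (0.20, 0.60), (0.58, 0.90)),
    "valve": ((0.40, 0.65), (0.70, 0.90), (0.20, 0.45)),
    "bone": ((0.05, 0.95), (0.88, 0.98), (0.05, 0.95)),
}


@dataclass
class Lesion:
    """One spherical calcification: centre in world mm (z, y, x)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_hu: float
    territory: str = "coronary"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.territory not in TERRITORY_BOXES:
            raise ValueError(f"unknown territory {self.territory!r}")
        if self.peak_hu < CALCIUM_THRESHOLD_HU:
            raise ValueError("calcified lesion peak must be >= 130 HU")


@dataclass
class RaterNoise:
    """Distortion model for simulated rater/algorithm disagreement.

    ``drop_prob``: each true lesion is independently missed with this
    probability.  ``add_prob``: Poisson rate of spurious small lesions per
    scan.  ``jitter_sd``: log-normal sd of a multiplicative score error.
    """

    drop_prob: float = 0.0
    add_prob: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.drop_prob, self.add_prob, self.jitter_sd) < 0:
            raise ValueError("rater-noise parameters must be >= 0")
        if self.drop_prob > 1:
            raise ValueError("drop_prob must be <= 1")


@dataclass
class PhantomConfig:
    """Full description of one synthetic scan.

    ``spacing`` is the stored grid (z increment 1.4 mm); the 3.1 mm
    reconstructed slice thickness is metadata consumed only by the scoring
    normalisation.
    """

    shape: tuple[int, int, int] = (32, 80, 80)
    spacing: tuple[float, float, float] = (1.4, 0.66, 0.66)
    slice_thickness_mm: float = 3.1
    background_mean_hu: float = 35.0
    background_sd_hu: float = 0.0
    noise_sd_hu: float = 0.0
    motion_blur_fwhm_mm: float = 0.0
    lesions: list[Lesion] = field(default_factory=list)
    rater_noise: RaterNoise = field(default_factory=RaterNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass
class LesionRecord:
    """Ground-truth bookkeeping for one rendered lesion."""

    lesion_id: int
    territory: str
    volume_mm3: float
    agatston: float


@dataclass
class GroundTruth:
    """Pre-noise truth for a phantom: coronary mask, per-lesion and scan scores."""

    mask: np.ndarray
    lesions: list[LesionRecord]
    score: ScoreRecord
    territory_labels: list[str]


def _render_lesion(hu: np.ndarray, volume: CTVolume, lesion: Lesion) -> np.ndarray:
    """Paint one lesion into ``hu`` in place; return its voxel index set.

    The radial profile is ``peak * exp(-r^2 / 2 sigma^2)`` with sigma chosen
    so the profile equals 130 HU at ``radius_mm``; inside the radius values
    are clamped to >= 130 so float rounding cannot push a truth voxel under
    the threshold.
    """
    center = np.asarray(lesion.center_mm)
    extent = volume.extent_mm
    if np.any(center - lesion.radius_mm < 0) or np.any(center + lesion.radius_mm > extent):
        raise ValueError(
            f"lesion at {lesion.center_mm} mm radius {lesion.radius_mm} mm "
            f"extends outside the {tuple(extent)} mm field of view"
        )
    spacing = np.asarray(volume.spacing)
    # local bounding box out to where the profile falls back under ~1 HU
    reach = lesion.radius_mm * 3.0
    lo = np.maximum(0, np.floor((center - reach) / spacing).astype(int))
    hi = np.minimum(np.asarray(volume.shape), np.ceil((center + reach) / spacing).astype(int) + 1)
    grids = np.meshgrid(
        *(np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)), indexing="ij"
    )
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    if lesion.peak_hu > CALCIUM_THRESHOLD_HU:
        sigma2 = lesion.radius_mm**2 / (2.0 * np.log(lesion.peak_hu / CALCIUM_THRESHOLD_HU))
        profile = lesion.peak_hu * np.exp(-r2 / (2.0 * sigma2))
    else:  # flat 130 HU ball, degenerate profile
        profile = np.where(r2 <= lesion.radius_mm**2, lesion.peak_hu, 0.0)
    inside = r2 <= lesion.radius_mm**2
    profile[inside] = np.maximum(profile[inside], CALCIUM_THRESHOLD_HU)
    block = hu[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(block, profile, out=block)
    zz, yy, xx = np.nonzero(inside)
    return np.stack([zz + lo[0], yy + lo[1], xx + lo[2]], axis=1)


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, GroundTruth]:
    """Render a phantom volume and its ground truth.

    Deterministic: the same config (seed included) yields bit-identical
    output.  Noise and motion blur are applied after lesion rendering;
    ground truth always reflects the pre-noise geometry.
    """
    rng = np.random.default_rng(config.seed)
    hu = np.full(config.shape, config.background_mean_hu, dtype=np.float64)
    if config.background_sd_hu > 0:
        # smooth tissue heterogeneity: low-pass filtered noise rescaled to the target sd
        rough = rng.standard_normal(config.shape)
        smooth = ndimage.gaussian_filter(rough, sigma=3.0)
        hu += smooth * (config.background_sd_hu / smooth.std())
    volume = CTVolume(
        hu,
        config.spacing,
        scan_id=f"phantom-{config.seed}",
        meta={"slice_thickness_mm": config.slice_thickness_mm, "seed": config.seed},
    )

    score_cfg = ScoreConfig(thickness_factor=config.slice_thickness_mm / 3.0)
    mask = np.zeros(config.shape, dtype=bool)
    records: list[LesionRecord] = []
    territories: list[str] = []
    for i, lesion in enumerate(config.lesions):
        voxels = _render_lesion(hu, volume, lesion)
        territories.append(lesion.territory)
        if lesion.territory == "coronary":
            mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = True
            cand = candidate_from_voxels(voxels, volume)
            records.append(
                LesionRecord(
                    lesion_id=i,
                    territory=lesion.territory,
                    volume_mm3=cand.volume_mm3,
                    agatston=agatston_lesion(cand, score_cfg),
                )
            )

    total_agatston = float(sum(r.agatston for r in records))
    truth = GroundTruth(
        mask=mask,
        lesions=records,
        score=ScoreRecord(
            scan_id=volume.scan_id,
            agatston=total_agatston,
            volume_mm3=float(sum(r.volume_mm3 for r in records)),
            n_lesions=len(records),
            category=risk_category(total_agatston, score_cfg.cutoffs),
        ),
        territory_labels=territories,
    )

    if config.noise_sd_hu > 0:
        hu += rng.normal(0.0, config.noise_sd_hu, size=config.shape)
    if config.motion_blur_fwhm_mm > 0:
        sigma_vox = config.motion_blur_fwhm_mm / 2.3548 / config.spacing[1]
        hu[:] = ndimage.gaussian_filter1d(hu, sigma=sigma_vox, axis=1)
    return volume, truth


def _box_mm(territory: str, extent: np.ndarray) -> np.ndarray:
    frac = np.asarray(TERRITORY_BOXES[territory])
    return frac * extent[:, None]


def heart_mask(config: PhantomConfig) -> np.ndarray:
    """Binary mask of the synthetic cardiac region (coronary territory box).

    Serves as the spatial-normalisation anchor when building the atlas.
    """
    extent = np.asarray(config.shape) * np.asarray(config.spacing)
    box = _box_mm("coronary", extent)
    mask = np.zeros(config.shape, dtype=bool)
    lo = np.ceil(box[:, 0] / np.asarray(config.spacing)).astype(int)
    hi = np.floor(box[:, 1] / np.asarray(config.spacing)).astype(int)
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return mask


def random_phantom_config(
    seed: int,
    shape: tuple[int, int, int] = (32, 80, 80),
    spacing: tuple[float, float, float] = (1.4, 0.66, 0.66),
    noise_sd_hu: float = 15.0,
    motion_blur_fwhm_mm: float = 0.0,
    max_coronary: int = 4,
    max_distractor: int = 2,
) -> PhantomConfig:
    """Draw a random but reproducible phantom configuration.

    Coronary lesion count is uniform on 0..max_coronary; distractor
    (aortic/valve) count uniform on 0..max_distractor.  Radii 1.5-4.5 mm and
    peaks 150-700 HU span all four Agatston density bands and all five risk
    strata at these grid sizes.
    """
    rng = np.random.default_rng(seed)
    extent = np.asarray(shape) * np.asarray(spacing)
    lesions: list[Lesion] = []

    def draw(territory: str) -> Lesion:
        radius = rng.uniform(1.5, 4.5)
        box = _box_mm(territory, extent)
        lo = np.maximum(box[:, 0], radius)
        hi = np.minimum(box[:, 1], extent - radius)
        center = rng.uniform(lo, np.maximum(hi, lo + 1e-6))
        return Lesion(tuple(center), radius, float(rng.uniform(150.0, 700.0)), territory)

    for _ in range(rng.integers(0, max_coronary + 1)):
        lesions.append(draw("coronary"))
    for _ in range(rng.integers(0, max_distractor + 1)):
        lesions.append(draw(str(rng.choice(["aorta", "valve"]))))
    return PhantomConfig(
        shape=shape,
        spacing=spacing,
        noise_sd_hu=noise_sd_hu,
        motion_blur_fwhm_mm=motion_blur_fwhm_mm,
        lesions=lesions,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_rater_scores(
    truth_table: list[ScoreRecord],
    rater_noise: RaterNoise,
    seed: int = 0,
) -> pd.DataFrame:
    """Perturb a true score table into a reference-vs-rated paired table.

    Lesion drops remove a binomial fraction of each scan's score; spurious
    additions contribute small scores; jitter multiplies what remains.  With
    zero noise the two sides are identical.  Returns a DataFrame with
    ``*_ref`` and ``*_auto`` columns for Agatston, volume, count and
    category.
    """
    if not truth_table:
        raise ValueError("truth table must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in truth_table:
        kept = (
            int(rng.binomial(rec.n_lesions, 1.0 - rater_noise.drop_prob))
            if rec.n_lesions
            else 0
        )
        frac = kept / rec.n_lesions if rec.n_lesions else 0.0
        jitter = float(np.exp(rng.normal(0.0, rater_noise.jitter_sd))) if rater_noise.jitter_sd else 1.0
        agatston = rec.agatston * frac * jitter
        vol = rec.volume_mm3 * frac * jitter
        n = kept
        for _ in range(rng.poisson(rater_noise.add_prob)):
            agatston += float(rng.uniform(1.0, 10.0))
            vol += float(rng.uniform(1.0, 10.0))
            n += 1
        rows.append(
            {
                "scan_id": rec.scan_id,
                "agatston_ref": rec.agatston,
                "agatston_auto": agatston,
                "volume_ref": rec.volume_mm3,
                "volume_auto": vol,
                "n_lesions_ref": rec.n_lesions,
                "n_lesions_auto": n,
                "category_ref": rec.category,
                "category_auto": risk_category(agatston),
            }
        )
    return pd.DataFrame(rows)


def table1_fixture():
    """The published 5x5 reference-vs-automated risk-category cross-table.

    1749 lung-screening scans cross-tabulated by Agatston stratum as scored
    by the human-corrected reference (rows) and the fully automated method
    (columns).
    """
    from .agreement import ConfusionMatrix
    from .scoring import CATEGORY_LABELS

    counts = np.array(
        [
            [401, 23, 6, 3, 0],
            [94, 88, 11, 0, 0],
            [40, 31, 275, 5, 3],
            [6, 6, 44, 243, 2],
            [4, 1, 14, 70, 379],
        ],
        dtype=np.int64,
    )
    return ConfusionMatrix(counts=counts, labels=CATEGORY_LABELS)
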