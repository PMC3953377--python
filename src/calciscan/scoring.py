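"""Agatston score, calcium volume and lesion count.

The Agatston score of a lesion is the per-slice sum of its calcified area
(mm^2) multiplied by a density weight derived from the slice's maximum
attenuation: 130-199 HU -> 1, 200-299 -> 2, 300-399 -> 3, >= 400 -> 4.
Slices with less than a minimum area (1 mm^2 classically) contribute
nothing.  The scan score is the sum over coronary lesions and maps onto the
five cardiovascular risk strata 0, 1-10, 11-100, 101-400, >400.

The classical definition assumes contiguous 3 mm slices.  Non-gated chest
reconstructions here use 3.1 mm thick slices at a 1.4 mm increment; every
reconstructed slice contributes and the sum is rescaled by
``slice_thickness / 3`` so the score stays on the conventional scale.  The
factor is configurable and the volume score is never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .extraction import CALCIUM_THRESHOLD_HU, Candidate

__all__ = [
    "CATEGORY_LABELS",
    "DEFAULT_DENSITY_BINS",
    "ScoreConfig",
    "ScoreRecord",
    "density_weight",
    "agatston_lesion",
    "volume_score",
    "risk_category",
    "score_scan",
]

#: Risk strata in increasing order; ASCII hyphens are used in labels.
CATEGORY_LABELS = ("0", "1-10", "11-100", "101-400", ">400")

#: (lower HU bound, weight) pairs; weight applies from the bound upward.
DEFAULT_DENSITY_BINS = ((130.0, 1), (200.0, 2), (300.0, 3), (400.0, 4))

#: Slice thickness the classical score is defined for, mm.
_REFERENCE_THICKNESS_MM = 3.0


@dataclass
class ScoreConfig:
    """Parameters of Agatston/volume scoring and risk stratification."""

    density_bins: tuple = DEFAULT_DENSITY_BINS
    min_area_mm2: float = 1.0
    cutoffs: tuple[float, ...] = (0.0, 10.0, 100.0, 400.0)
    #: multiplies the Agatston sum; default rescales 3.1 mm slices to the
    #: 3 mm convention.
    thickness_factor: float = 3.1 / _REFERENCE_THICKNESS_MM
    threshold_hu: float = CALCIUM_THRESHOLD_HU

    def __post_init__(self) -> None:
        weights = [w for _, w in self.density_bins]
        if sorted(weights) != weights:
            raise ValueError("density weights must be nondecreasing in HU")
        if list(self.cutoffs) != sorted(set(self.cutoffs)):
            raise ValueError("strata cutoffs must be strictly increasing")


@dataclass
class ScoreRecord:
    """Per-scan calcium quantification."""

    scan_id: str
    agatston: float
    volume_mm3: float
    n_lesions: int
    category: str = ""

    def __post_init__(self) -> None:
        if not self.category:
            self.category = risk_category(self.agatston)

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "agatston": float(self.agatston),
            "volume_mm3": float(self.volume_mm3),
            "n_lesions": int(self.n_lesions),
            "category": self.category,
        }


def density_weight(max_hu: float, bins=DEFAULT_DENSITY_BINS) -> int:
    """Agatston density weight of a slice from its maximum HU (0 below 130)."""
    weight = 0
    for lower, w in bins:
        if max_hu >= lower:
            weight = w
    return weight


def agatston_lesion(candidate: Candidate, config: ScoreConfig | None = None) -> float:
    """Agatston contribution of a single lesion.

    Per-slice ``area(mm^2) * weight(max HU)``, slices below the minimum
    area dropped, summed and multiplied by the thickness factor.
    """
    config = config or ScoreConfig()
    total = 0.0
    for s in candidate.slices:
        if s.area_mm2 < config.min_area_mm2:
            continue
        total += s.area_mm2 * density_weight(s.max_hu, config.density_bins)
    return total * config.thickness_factor


def volume_score(candidates: list[Candidate], config: ScoreConfig | None = None) -> float:
    """Total calcium volume (mm^3) of coronary-labeled candidates.

    A plain sum of voxel volumes; no thickness rescaling.
    """
    return float(sum(c.volume_mm3 for c in candidates if c.label == "coronary"))


def risk_category(agatston: float, cutoffs: tuple[float, ...] = (0.0, 10.0, 100.0, 400.0)) -> str:
    """Map an Agatston score to its risk stratum.

    Fractional automated scores fall into half-open intervals: 0 -> "0",
    (0, 10] -> "1-10", (10, 100] -> "11-100", (100, 400] -> "101-400",
    above -> ">400".
    """
    if agatston < 0:
        raise ValueError(f"Agatston score must be >= 0, got {agatston}")
    for cutoff, label in zip(cutoffs, CATEGORY_LABELS):
        if agatston <= cutoff:
            return label
    return CATEGORY_LABELS[-1]


def score_scan(
    candidates: list[Candidate],
    config: ScoreConfig | None = None,
    scan_id: str = "",
) -> ScoreRecord:
    """Aggregate classified candidates into a per-scan score record."""
    config = config or ScoreConfig()
    coronary = [c for c in candidates if c.label == "coronary"]
    agatston = float(sum(agatston_lesion(c, config) for c in coronary))
    return ScoreRecord(
        scan_id=scan_id,
        agatston=agatston,
        volume_mm3=volume_score(candidates, config),
        n_lesions=len(coronary),
        category=risk_category(agatston, config.cutoffs),
    )
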