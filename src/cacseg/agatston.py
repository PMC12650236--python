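"""Lesion extraction and Agatston calcium scoring.

A candidate calcification is a per-slice 8-connected component of the
segmentation mask restricted to voxels >= 130 HU, with projected area of
at least 1 mm^2. Each lesion contributes area (mm^2) times a density
weight derived from its peak HU (130-199 -> 1, 200-299 -> 2,
300-399 -> 3, >= 400 -> 4); the Agatston score is the sum. Scoring runs
on the original-spacing HU grid so areas reflect acquisition geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume
from .preprocess import ConfigError

__all__ = [
    "Lesion",
    "AgatstonResult",
    "extract_lesions",
    "density_weight",
    "agatston_score",
    "RISK_CATEGORIES",
]

_STRUCT_2D = np.ones((3, 3), dtype=int)

#: Standard risk strata on the total score.
RISK_CATEGORIES = ("0", "(0,10]", "(10,100]", "(100,400]", ">400")


@dataclass(frozen=True)
class Lesion:
    slice_index: int
    voxels: tuple[tuple[int, int], ...]   # (y, x) pixel coordinates
    area_mm2: float
    peak_hu: float
    artery: str | None = None

    def __post_init__(self) -> None:
        if self.peak_hu < 130:
            raise ValueError("a lesion's peak must be >= 130 HU")

    @property
    def density_weight(self) -> int:
        return density_weight(self.peak_hu)


@dataclass(frozen=True)
class AgatstonResult:
    lesion_scores: tuple[float, ...]
    total: float
    category: str

    def __post_init__(self) -> None:
        assert abs(self.total - sum(self.lesion_scores)) < 1e-6


def extract_lesions(hu: CTVolume, mask: np.ndarray,
                    min_hu: float = 130.0,
                    min_area_mm2: float = 1.0) -> list[Lesion]:
    """Per-slice connected calcified components of ``mask ∩ (hu >= min_hu)``.

    Components whose projected area (voxel count x in-plane mm^2) falls
    below ``min_area_mm2`` are discarded; the peak HU is recorded per
    lesion.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != hu.shape:
        raise ValueError(f"grid mismatch: hu {hu.shape} vs mask {mask.shape}")
    pixel_area = hu.spacing[1] * hu.spacing[2]
    candidates = mask & (hu.voxels >= min_hu)
    lesions: list[Lesion] = []
    for z in range(hu.shape[0]):
        labels, n = ndimage.label(candidates[z], structure=_STRUCT_2D)
        for i in range(1, n + 1):
            comp = labels == i
            area = float(comp.sum()) * pixel_area
            if area < min_area_mm2:
                continue
            ys, xs = np.nonzero(comp)
            peak = float(hu.voxels[z][comp].max())
            lesions.append(Lesion(
                slice_index=z,
                voxels=tuple(zip(ys.tolist(), xs.tolist())),
                area_mm2=area,
                peak_hu=peak,
            ))
    return lesions


def density_weight(peak_hu: float) -> int:
    """Standard Agatston density factor from the lesion's peak HU."""
    if peak_hu < 130:
        raise ValueError(f"density weight undefined below 130 HU, got {peak_hu}")
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


def risk_category(total: float) -> str:
    if total <= 0:
        return RISK_CATEGORIES[0]
    if total <= 10:
        return RISK_CATEGORIES[1]
    if total <= 100:
        return RISK_CATEGORIES[2]
    if total <= 400:
        return RISK_CATEGORIES[3]
    return RISK_CATEGORIES[4]


def agatston_score(lesions: list[Lesion],
                   slice_thickness_mm: float = 3.0,
                   normalize_thickness: bool = False) -> AgatstonResult:
    """Sum per-lesion area x density-weight contributions.

    With ``normalize_thickness`` each lesion is scaled by
    ``slice_thickness_mm / 3.0`` (the convention for non-3 mm protocols);
    by default the factor is 1.
    """
    if slice_thickness_mm <= 0:
        raise ConfigError("slice thickness must be positive")
    factor = slice_thickness_mm / 3.0 if normalize_thickness else 1.0
    scores = tuple(l.area_mm2 * l.density_weight * factor for l in lesions)
    total = float(sum(scores))
    return AgatstonResult(lesion_scores=scores, total=total,
                          category=risk_category(total))
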