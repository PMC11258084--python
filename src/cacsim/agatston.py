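"""Agatston calcium scoring and its calibrated mass variant.

The classic score: connected regions of voxels at or above 130 HU inside
the ROI, each weighted by its maximum HU (130-199 -> 1, 200-299 -> 2,
300-399 -> 3, >= 400 -> 4) and multiplied by its in-plane area in mm^2.
Regions smaller than a minimum lesion area are discarded.  Scoring is done
per 0.5 mm slice with no slice-thickness renormalization: the study
compares methods at a fixed thin-slice protocol, so the classic 3 mm
convention is deliberately not applied.

The mass variant converts each lesion's volume times mean HU to milligrams
of hydroxyapatite through a factor measured on a calibration rod of known
density -- the standard phantom-calibrated calcium-mass score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Lesion",
    "AgatstonResult",
    "agatston_score",
    "agatston_mass",
    "mass_calibration_factor",
    "AGATSTON_THRESHOLD_HU",
]

AGATSTON_THRESHOLD_HU = 130.0
DEFAULT_MIN_AREA_MM2 = 1.0

#: 8-connectivity in-plane, the conventional choice for Agatston lesions.
_STRUCTURE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Lesion:
    area_mm2: float
    max_hu: float
    mean_hu: float
    weight: int
    n_voxels: int


@dataclass
class AgatstonResult:
    score: float
    lesions: list[Lesion] = field(default_factory=list)
    mass_mg: float | None = None
    threshold_hu: float = AGATSTON_THRESHOLD_HU

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be non-negative")


def density_weight(max_hu: float) -> int:
    """Agatston weighting factor from a lesion's maximum HU."""
    if max_hu < 130.0:
        return 0
    if max_hu < 200.0:
        return 1
    if max_hu < 300.0:
        return 2
    if max_hu < 400.0:
        return 3
    return 4


def agatston_score(
    hu_slice: np.ndarray,
    roi_mask: np.ndarray,
    spacing_mm: float,
    threshold_hu: float = AGATSTON_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> AgatstonResult:
    """Score one slice within one ROI.

    Connected components (8-connected) of supra-threshold voxels inside the
    ROI each contribute area(mm^2) x weight(max HU); sub-minimum-area
    components are discarded, so an ROI with no qualifying lesion scores
    exactly zero.
    """
    hu_slice = np.asarray(hu_slice, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if hu_slice.shape != roi_mask.shape:
        raise ValueError("image slice and ROI mask shapes differ")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    voxel_area = spacing_mm**2
    supra = (hu_slice >= threshold_hu) & roi_mask
    labels, n = ndimage.label(supra, structure=_STRUCTURE)
    lesions: list[Lesion] = []
    score = 0.0
    for lab in range(1, n + 1):
        sel = labels == lab
        nvox = int(sel.sum())
        area = nvox * voxel_area
        if area < min_area_mm2:
            continue
        mx = float(hu_slice[sel].max())
        w = density_weight(mx)
        lesions.append(
            Lesion(area_mm2=area, max_hu=mx, mean_hu=float(hu_slice[sel].mean()), weight=w, n_voxels=nvox)
        )
        score += area * w
    return AgatstonResult(score=score, lesions=lesions, threshold_hu=threshold_hu)


def mass_calibration_factor(
    hu_slice: np.ndarray,
    rod_mask: np.ndarray,
    rod_density_mgha: float,
    threshold_hu: float = AGATSTON_THRESHOLD_HU,
) -> float:
    """Mass calibration factor c (mgHA/cm^3 per HU) from a known rod.

    c = rod density / mean HU of the rod's supra-threshold core, so scoring
    the rod itself with this factor recovers its own mass.
    """
    core = np.asarray(rod_mask, dtype=bool)
    supra = core & (np.asarray(hu_slice, dtype=float) >= threshold_hu)
    if not supra.any():
        raise ValueError("calibration rod shows no supra-threshold voxels; use a denser rod")
    mean_hu = float(np.asarray(hu_slice, dtype=float)[supra].mean())
    if mean_hu <= 0:
        raise ValueError("non-positive mean rod HU")
    return rod_density_mgha / mean_hu


def agatston_mass(
    result: AgatstonResult,
    calibration_factor: float,
    voxel_volume_cm3: float,
) -> float:
    """Calcium mass (mg) of a scored ROI: sum of lesion volume x calibrated density.

    Each lesion's HA density is estimated as its mean HU times the
    calibration factor (mgHA/cm^3 per HU).
    """
    if calibration_factor <= 0:
        raise ValueError("calibration factor must be positive")
    if voxel_volume_cm3 <= 0:
        raise ValueError("voxel volume must be positive")
    mass = 0.0
    for les in result.lesions:
        mass += les.n_voxels * voxel_volume_cm3 * les.mean_hu * calibration_factor
    result.mass_mg = float(mass)
    return result.mass_mg
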