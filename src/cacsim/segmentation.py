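"""Geometry-driven ROI segmentation.

Because the phantom geometry is known exactly, segmentation is a pure
function of the phantom definition and configuration -- it never inspects
image content, so ROIs are identical across noise realizations and tube
voltages.  Measurement ROIs are the insert footprint dilated by a margin
that captures reconstruction blur and partial-volume spill; background ROIs
are congruent discs placed on insert-free rings of the scoring region;
calibration-rod ROIs are eroded cores that avoid partial-volume edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import INSERT_REGION_RADIUS_MM, PhantomDefinition, VOXEL_MM

__all__ = ["ROI", "ROISet", "segment_inserts", "segment_background", "segment_calibration_rod", "background_annulus"]

DEFAULT_DILATION_MM = 1.0
DEFAULT_EROSION_MM = 1.0


@dataclass(frozen=True)
class ROI:
    """One region of interest: a boolean in-plane mask plus identity."""

    name: str
    mask: np.ndarray  # (ny, nx) bool
    kind: str  # "insert" | "background" | "rod"
    center_mm: tuple[float, float]
    diameter_class_mm: float
    insert_name: str | None = None
    density_mgha: float | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ROISet:
    """A named collection of mutually disjoint ROIs on one scan grid."""

    rois: list[ROI]
    spacing_mm: float
    phantom_name: str

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def of_kind(self, kind: str) -> list[ROI]:
        return [r for r in self.rois if r.kind == kind]

    def validate_disjoint(self) -> None:
        total = np.zeros_like(self.rois[0].mask, dtype=np.int32)
        for r in self.rois:
            total += r.mask
        if total.max() > 1:
            raise ValueError("ROI masks overlap")


def _grid_xy(phantom: PhantomDefinition, spacing_mm: float):
    nx, ny = phantom.grid_shape
    x = (np.arange(nx) + 0.5) * spacing_mm - nx * spacing_mm / 2.0
    y = (np.arange(ny) + 0.5) * spacing_mm - ny * spacing_mm / 2.0
    return np.meshgrid(x, y)


def _disc_mask(xx, yy, center, radius_mm) -> np.ndarray:
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius_mm**2


def segment_inserts(
    phantom: PhantomDefinition,
    dilation_mm: float = DEFAULT_DILATION_MM,
    spacing_mm: float = VOXEL_MM,
) -> ROISet:
    """One ROI per calcification insert: footprint dilated by ``dilation_mm``.

    A 5 mm insert with the default 1 mm dilation yields a 7 mm ROI.  ROIs are
    checked to be pairwise disjoint and inside the scoring region.
    """
    if dilation_mm < 0:
        raise ValueError("dilation must be non-negative")
    xx, yy = _grid_xy(phantom, spacing_mm)
    rois = []
    for name in phantom.insert_names:
        p = phantom.insert(name)
        r = p.dims_mm[0] + dilation_mm
        dist = float(np.hypot(*p.center_mm)) + r
        if dist > INSERT_REGION_RADIUS_MM and phantom.name.startswith("thorax"):
            raise ValueError(f"ROI for {name!r} extends outside the scoring region")
        rois.append(
            ROI(
                name=f"roi_{name}",
                mask=_disc_mask(xx, yy, p.center_mm, r),
                kind="insert",
                center_mm=p.center_mm,
                diameter_class_mm=2.0 * p.dims_mm[0],
                insert_name=name,
                density_mgha=p.density_mgha,
            )
        )
    out = ROISet(rois, spacing_mm, phantom.name)
    out.validate_disjoint()
    return out


def segment_background(
    phantom: PhantomDefinition,
    n_rois: int | None = None,
    roi_size_class: float | None = None,
    dilation_mm: float = DEFAULT_DILATION_MM,
    spacing_mm: float = VOXEL_MM,
) -> ROISet:
    """Background ROIs congruent to the insert ROI size classes.

    Positions come from the phantom definition (insert-free rings of the
    scoring region).  ``roi_size_class`` filters to one insert diameter
    class; ``n_rois`` truncates the list.  Each mask is verified to contain
    no insert-footprint voxels.
    """
    xx, yy = _grid_xy(phantom, spacing_mm)
    spots = phantom.background_spots
    if roi_size_class is not None:
        spots = [s for s in spots if s["diameter_mm"] == roi_size_class]
    if n_rois is not None:
        if n_rois > len(spots):
            raise ValueError(f"only {len(spots)} background positions available")
        spots = spots[:n_rois]
    rois = []
    for i, s in enumerate(spots):
        d = s["diameter_mm"]
        mask = _disc_mask(xx, yy, s["center_mm"], d / 2.0 + dilation_mm)
        for name in phantom.insert_names:
            p = phantom.insert(name)
            if np.any(mask & _disc_mask(xx, yy, p.center_mm, p.dims_mm[0])):
                raise ValueError(f"background ROI {i} intersects insert {name!r}")
        rois.append(
            ROI(
                name=f"bkg_{i}_d{d:g}mm",
                mask=mask,
                kind="background",
                center_mm=tuple(s["center_mm"]),
                diameter_class_mm=float(d),
            )
        )
    out = ROISet(rois, spacing_mm, phantom.name)
    if rois:
        out.validate_disjoint()
    return out


def segment_calibration_rod(
    phantom: PhantomDefinition,
    erosion_mm: float = DEFAULT_EROSION_MM,
    spacing_mm: float = VOXEL_MM,
) -> ROISet:
    """Eroded core masks of the calibration rods plus one background core.

    Erosion by ``erosion_mm`` keeps the sampled voxels clear of
    partial-volume edges; an erosion at least the rod radius is an error.
    """
    if erosion_mm < 0:
        raise ValueError("erosion must be non-negative")
    xx, yy = _grid_xy(phantom, spacing_mm)
    rois = []
    for name in phantom.insert_names:
        p = phantom.insert(name)
        core = p.dims_mm[0] - erosion_mm
        if core <= 0:
            raise ValueError(f"erosion {erosion_mm} mm empties rod {name!r}")
        rois.append(
            ROI(
                name=f"core_{name}",
                mask=_disc_mask(xx, yy, p.center_mm, core),
                kind="rod",
                center_mm=p.center_mm,
                diameter_class_mm=2.0 * p.dims_mm[0],
                insert_name=name,
                density_mgha=p.density_mgha,
            )
        )
    for i, s in enumerate(phantom.background_spots):
        core = s["diameter_mm"] / 2.0 - erosion_mm
        if core <= 0:
            raise ValueError("erosion empties the background reference region")
        rois.append(
            ROI(
                name=f"bkg_core_{i}",
                mask=_disc_mask(xx, yy, s["center_mm"], core),
                kind="background",
                center_mm=tuple(s["center_mm"]),
                diameter_class_mm=float(s["diameter_mm"]),
            )
        )
    out = ROISet(rois, spacing_mm, phantom.name)
    out.validate_disjoint()
    return out


def background_annulus(roi: ROI, width_voxels: int = 2) -> np.ndarray:
    """A ``width_voxels``-wide ring immediately outside an ROI mask.

    Used to sample the local pure-background signal for the volume-fraction
    method.
    """
    from scipy.ndimage import binary_dilation

    grown = binary_dilation(roi.mask, iterations=width_voxels)
    return grown & ~roi.mask
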