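"""Volume-fraction calcium mass (single-energy).

Each ROI voxel's signal i is interpreted as a linear blend of pure
background (S_Bkg) and the calibration-rod calcium signal (S_Obj):

    k_i = (i - S_Bkg) / (S_Obj - S_Bkg)

so a voxel at the rod signal is 100 % "calibration calcium" and a voxel at
background is 0 %.  Summing k_i over the ROI gives the calcium volume in
units of the calibration density rho_cal, hence

    M = sum_i k_i * v_voxel * rho_cal.

Negative k_i from noise are retained so that noise averages out and the
background-mass distribution stays centred -- the detectability threshold
(mean background + 1.5 SD) relies on this.

A literal-transcription variant ``convention="printed"`` implements
k_i = (i - S_Obj)/(S_Obj - S_Bkg), under which a pure-calcium voxel maps to
0 and background to -1; it is provided for exactness testing only, since it
contradicts the fraction interpretation that the mass formula requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import ROI, background_annulus
from .sim import ReconImage

__all__ = [
    "VolumeFractionInputs",
    "VolumeFractionResult",
    "volume_fraction_mass",
    "measure_reference_signals",
]


@dataclass(frozen=True)
class VolumeFractionInputs:
    """Reference signals and calibration density for the volume-fraction method."""

    s_obj: float  # HU of the pure calibration calcium
    s_bkg: float  # HU of pure background
    rho_cal_mgha: float  # density of the calibration rod, mgHA/cm^3
    voxel_volume_cm3: float

    def __post_init__(self) -> None:
        if self.s_obj == self.s_bkg:
            raise ValueError("S_Obj must differ from S_Bkg")
        if self.rho_cal_mgha <= 0:
            raise ValueError("calibration density must be positive")
        if self.voxel_volume_cm3 <= 0:
            raise ValueError("voxel volume must be positive")


@dataclass
class VolumeFractionResult:
    k_map: np.ndarray  # per-voxel calcium fraction over the ROI (1-D, ROI order)
    k_total: float     # K = sum of fractions
    volume_cm3: float  # V = K * v_voxel
    mass_mg: float     # M = V * rho_cal


def volume_fraction_mass(
    hu_slice: np.ndarray,
    roi_mask: np.ndarray,
    inputs: VolumeFractionInputs,
    convention: str = "background",
) -> VolumeFractionResult:
    """Apply the volume-fraction chain to one ROI on one slice."""
    hu_slice = np.asarray(hu_slice, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if hu_slice.shape != roi_mask.shape:
        raise ValueError("image slice and ROI mask shapes differ")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    i = hu_slice[roi_mask]
    denom = inputs.s_obj - inputs.s_bkg
    if convention == "background":
        k = (i - inputs.s_bkg) / denom
    elif convention == "printed":
        k = (i - inputs.s_obj) / denom
    else:
        raise ValueError("convention must be 'background' or 'printed'")
    k_total = float(k.sum())
    volume = k_total * inputs.voxel_volume_cm3
    return VolumeFractionResult(
        k_map=k,
        k_total=k_total,
        volume_cm3=volume,
        mass_mg=volume * inputs.rho_cal_mgha,
    )


def measure_reference_signals(
    calibration_image: ReconImage,
    rod_roi: ROI,
    bkg_roi: ROI,
    measurement_protocol=None,
) -> tuple[float, float]:
    """(S_Obj, S_Bkg) as mean HU over eroded core masks of a calibration scan.

    If ``measurement_protocol`` is given, its tube voltage and exposure must
    match the calibration scan (reference signals are protocol-specific).
    """
    prot = calibration_image.protocol
    if measurement_protocol is not None:
        if (prot.kv, prot.exposure_mr) != (measurement_protocol.kv, measurement_protocol.exposure_mr):
            raise ValueError(
                "calibration scan protocol (kv, exposure) does not match the measurement protocol"
            )
    vals_obj = calibration_image.hu[:, rod_roi.mask]
    vals_bkg = calibration_image.hu[:, bkg_roi.mask]
    return float(vals_obj.mean()), float(vals_bkg.mean())


def local_background_signal(hu_slice: np.ndarray, roi: ROI, width_voxels: int = 2) -> float:
    """Mean HU of the ring immediately outside ``roi`` (local S_Bkg sample)."""
    ring = background_annulus(roi, width_voxels)
    return float(np.asarray(hu_slice, dtype=float)[ring].mean())
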