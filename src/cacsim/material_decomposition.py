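"""Dual-energy material decomposition in the image domain.

Calibration fits a rational polynomial mapping a voxel's paired low/high
tube-voltage signals (S_L, S_H, in HU) to a basis-material density f
(mgHA/cm^3):

    f(S_L, S_H; p) = (p0 + p1 S_L + p2 S_H + p3 S_L^2 + p4 S_L S_H + p5 S_H^2)
                     / (1 + p6 S_L + p7 S_H)

The eight coefficients are solved by Levenberg-Marquardt least squares on
rods of known density scanned at both energies; the fit is initialized from
the linear-in-parameters solution with the denominator frozen (p6 = p7 = 0),
which makes it deterministic without a hand-picked starting point.

A numerical subtlety drives the implementation: calibration-rod signal
pairs are almost collinear in the (S_L, S_H) plane (both signals grow with
density), so the quadratic surface is well determined *along* the rod
manifold but unidentified transverse to it.  The linear stage therefore
solves in a scaled signal space by truncated SVD, which returns the
minimal-norm solution -- flat in the unidentified directions -- instead of
an exactly-interpolating surface with explosive transverse gradients.  For
well-spread sample designs nothing is truncated and the fit is exact.
Decomposition is voxel-by-voxel; ROI mass follows by summing f times the
voxel volume.  Negative densities from noise are retained so background
masses stay centred for the detectability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CalibrationSample",
    "CalibrationModel",
    "fit_calibration",
    "decompose",
    "DecompositionResult",
    "mass_from_density_map",
]


@dataclass(frozen=True)
class CalibrationSample:
    """One (low-energy HU, high-energy HU, known density) triple."""

    s_low: float
    s_high: float
    f_true: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s_low) and np.isfinite(self.s_high) and np.isfinite(self.f_true)):
            raise ValueError("calibration sample values must be finite")
        if self.f_true < 0:
            raise ValueError("known density must be non-negative")


@dataclass
class CalibrationModel:
    """Fitted coefficients p0..p7 plus diagnostics."""

    p: np.ndarray
    residual_rms: float
    signal_range: tuple[tuple[float, float], tuple[float, float]]  # (S_L, S_H) ranges seen in fit
    protocol_tag: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (8,):
            raise ValueError("model requires exactly 8 coefficients")

    def denominator(self, s_low, s_high):
        return 1.0 + self.p[6] * np.asarray(s_low, float) + self.p[7] * np.asarray(s_high, float)

    def predict(self, s_low, s_high):
        """Density f (mgHA/cm^3) from paired signals; denominator must stay positive."""
        sl = np.asarray(s_low, dtype=float)
        sh = np.asarray(s_high, dtype=float)
        den = self.denominator(sl, sh)
        if np.any(den <= 0):
            raise ValueError("rational-model denominator non-positive for given signals")
        p = self.p
        num = p[0] + p[1] * sl + p[2] * sh + p[3] * sl**2 + p[4] * sl * sh + p[5] * sh**2
        return num / den

    def to_dict(self) -> dict:
        return {
            "p": self.p.tolist(),
            "residual_rms": self.residual_rms,
            "signal_range": [list(r) for r in self.signal_range],
            "protocol_tag": self.protocol_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            p=np.array(d["p"], dtype=float),
            residual_rms=float(d["residual_rms"]),
            signal_range=tuple(tuple(r) for r in d["signal_range"]),
            protocol_tag=d.get("protocol_tag", ""),
        )


def _design(sl: np.ndarray, sh: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(sl), sl, sh, sl**2, sl * sh, sh**2])


def fit_calibration(
    samples: list[CalibrationSample],
    protocol_tag: str = "",
    fit_denominator: bool = True,
) -> CalibrationModel:
    """Fit the 8-coefficient rational model to known-density samples.

    Requires at least 8 samples (8 unknowns).  The objective is
    sum (f(S_L, S_H; p) - f_true)^2, minimized by Levenberg-Marquardt from
    the frozen-denominator linear solution.  A rank-deficient design (e.g.
    all samples identical) or a denominator sign change over the sampled
    signal range is an error.
    """
    if len(samples) < 8:
        raise ValueError(f"need at least 8 calibration samples, got {len(samples)}")
    sl = np.array([s.s_low for s in samples])
    sh = np.array([s.s_high for s in samples])
    f = np.array([s.f_true for s in samples])

    # scale HU signals to O(1) so the SVD truncation threshold is meaningful
    scale = 1000.0
    sls, shs = sl / scale, sh / scale
    A = _design(sls, shs)
    rank = np.linalg.matrix_rank(A, tol=1e-10 * np.linalg.norm(A, 2))
    if rank < 3:
        raise ValueError("rank-deficient calibration design; samples do not span the model")
    p_lin, *_ = np.linalg.lstsq(A, f, rcond=1e-4)
    p0 = np.concatenate([p_lin, [0.0, 0.0]])

    if fit_denominator:
        def resid(p):
            den = 1.0 + p[6] * sls + p[7] * shs
            den = np.where(np.abs(den) < 1e-12, 1e-12, den)
            return (A @ p[:6]) / den - f

        sol = least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        p = sol.x
        # the denominator must stay positive not just on the rod samples but
        # for any plausible noisy voxel signal; if the refined coefficients
        # violate that over an expanded signal box, keep the (already
        # near-optimal) frozen-denominator solution
        margin = 0.5
        lo_l, hi_l = sls.min(), sls.max()
        lo_h, hi_h = shs.min(), shs.max()
        span_l, span_h = hi_l - lo_l, hi_h - lo_h
        corners_l = np.array([lo_l - margin * span_l - 0.5, hi_l + margin * span_l + 0.5])
        corners_h = np.array([lo_h - margin * span_h - 0.5, hi_h + margin * span_h + 0.5])
        dens = 1.0 + p[6] * corners_l[:, None] + p[7] * corners_h[None, :]
        if np.any(dens <= 0.05):
            p = p0
    else:
        p = p0

    # undo the signal scaling so coefficients apply to raw HU
    unscale = np.array(
        [1.0, 1 / scale, 1 / scale, 1 / scale**2, 1 / scale**2, 1 / scale**2, 1 / scale, 1 / scale]
    )
    model = CalibrationModel(
        p=p * unscale,
        residual_rms=0.0,
        signal_range=((float(sl.min()), float(sl.max())), (float(sh.min()), float(sh.max()))),
        protocol_tag=protocol_tag,
    )
    den = model.denominator(sl, sh)
    if np.any(den <= 0):
        raise ValueError(
            "fitted denominator changes sign over the calibrated signal range; "
            f"denominator extrema: [{den.min():.4g}, {den.max():.4g}]"
        )
    model.residual_rms = float(np.sqrt(np.mean((model.predict(sl, sh) - f) ** 2)))
    return model


@dataclass
class DecompositionResult:
    """Voxelwise basis-material densities over an ROI and the integrated mass."""

    f_values: np.ndarray  # mgHA/cm^3 per ROI voxel (1-D, ROI order)
    mass_mg: float
    mean_density: float


def mass_from_density_map(f_values: np.ndarray, voxel_volume_cm3: float) -> float:
    """ROI mass (mg) = sum f * v_voxel, with f in mg/cm^3 and v in cm^3."""
    if voxel_volume_cm3 <= 0:
        raise ValueError("voxel volume must be positive")
    return float(np.asarray(f_values, dtype=float).sum() * voxel_volume_cm3)


def decompose(
    low_slice: np.ndarray,
    high_slice: np.ndarray,
    roi_mask: np.ndarray,
    model: CalibrationModel,
    voxel_volume_cm3: float,
) -> DecompositionResult:
    """Voxel-by-voxel decomposition of co-registered low/high slices in an ROI."""
    low_slice = np.asarray(low_slice, dtype=float)
    high_slice = np.asarray(high_slice, dtype=float)
    if low_slice.shape != high_slice.shape:
        raise ValueError("low- and high-energy slices must share a grid")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != low_slice.shape:
        raise ValueError("ROI mask and image shapes differ")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    f = model.predict(low_slice[roi_mask], high_slice[roi_mask])
    return DecompositionResult(
        f_values=f,
        mass_mg=mass_from_density_map(f, voxel_volume_cm3),
        mean_density=float(f.mean()),
    )
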