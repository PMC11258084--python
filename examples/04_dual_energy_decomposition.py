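"""Calibrate and apply dual-energy material decomposition.

Scans the 8-rod calibration phantom at 80 and 135 kV, fits the rational
signal-to-density model on all rod-core voxels, then decomposes paired
scans of the low-density thorax phantom voxel-by-voxel and integrates ROI
masses.  Because no background subtraction is involved, the method's mass
noise is lower than the volume-fraction method's, which is what gives it
the detectability edge for faint calcifications.
"""

from cacsim import (
    CalibrationSample,
    build_calibration_phantom,
    build_measurement_phantom,
    decompose,
    fit_calibration,
    scan,
    segment_calibration_rod,
    segment_inserts,
)
from cacsim.experiment import ExperimentConfig, _fit_dual_energy_model

cfg = ExperimentConfig(master_seed=7, n_angles=360)
model, samples = _fit_dual_energy_model(cfg, "medium")
print(f"fitted model on {len(samples)} rod-core voxel samples; residual {model.residual_rms:.2f} mgHA/cm^3")
print("coefficients p0..p7:", ", ".join(f"{v:.3g}" for v in model.p), "\n")

phantom = build_measurement_phantom("medium", "low")
imgs = {kv: scan(phantom, cfg.protocol("medium", kv), seed=7, n_slices=1) for kv in (80.0, 135.0)}
voxvol = imgs[80.0].voxel_volume_cm3
print(f"{'insert':>24s} {'measured mg':>12s} {'truth mg':>9s}")
for roi in segment_inserts(phantom):
    res = decompose(imgs[80.0].hu[0], imgs[135.0].hu[0], roi.mask, model, voxvol)
    truth = phantom.ground_truth_mass_mg(roi.insert_name, per_slice=True)
    print(f"{roi.insert_name:>24s} {res.mass_mg:12.4f} {truth:9.4f}")
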