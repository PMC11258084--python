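# Methods

This note documents the physical model, the study conditions encoded in the
defaults, the numerical choices, and what the simulation does and does not
capture.

## Imaging model

**Attenuation.**  Mass-attenuation tables (cm²/g, 10–150 keV) for H, C, N,
O, P, Ca and for water, air, PMMA and aluminum ship as plain-text fixtures
in NIST tabulation style and are interpolated log-log, the standard
treatment for photon cross sections away from absorption edges (none of the
bundled materials has an edge above 10 keV in-range).  Compounds are built
from elemental mass fractions: calcium hydroxyapatite Ca₁₀(PO₄)₆(OH)₂
(Ca 0.399, P 0.185, O 0.414, H 0.002; nominal density 3.16 g/cm³) and lipid
as tripalmitin C₅₁H₉₈O₆ (0.92 g/cm³).  Internal consistency is tested:
recombining H/O with water's mass fractions reproduces the bundled water
table to < 0.2 %.

**Spectra.**  Tube spectra are filtered-Kramers bremsstrahlung for a
tungsten anode behind 6 mm Al, tabulated at 1 keV for 80/120/135 kV.  The
6 mm inherent filtration stands in for a clinical tube plus bowtie-centre
and was chosen for realistic calcium contrast: with it, a 100 mgHA/cm³ rod
reads ≈ 195 HU above water at 120 kV, matching commercial calcium-scoring
phantoms.  Characteristic tungsten lines are omitted; they carry a few
percent of fluence and shift the mean energy by less than the
filtration uncertainty.  Additional filtration is applied bin-by-bin by
Beer–Lambert attenuation through the aluminum table.

**Forward projection.**  Parallel-beam geometry.  Because every phantom
primitive is a circle, ellipse or annulus, per-material line integrals are
computed in closed form — bin-averaged chords, exact for a detector that
integrates over its 0.5 mm pitch — with later primitives contributing the
*difference* between their composition and their container's.  A map-based
Radon path (scikit-image) exists for arbitrary density maps and serves as
an independent cross-check; the two agree to rasterization error (≈ 1 % on
body-scale structures).  Expected counts are
`N(θ,s) = Φ Σ_E w(E) exp(−Σ_m (μ/ρ)_m(E) A_m(θ,s))` with the energy sum
taken after attenuation — this is the entire beam-hardening mechanism.
Air attenuation along the beam is neglected (< 0.5 % over the field of
view).  The spectrum is re-binned to 2 keV for the sum; 1 keV changes
reconstructed HU by < 0.5 HU.

**Noise and reconstruction.**  Quantum noise is an independent Poisson draw
per detector element and view.  The exposure-to-fluence constant
(5.2×10⁸ photons · mR⁻¹ per detector element, split across views so dose is
independent of the view count) was calibrated once so the medium-phantom
scoring region shows ≈ 20 HU noise at 120 kV and 2.0 mR — typical clinical
calcium-scan noise — and scales linearly with the per-size exposures
(0.9 / 2.0 / 5.4 mR for small/medium/large).  Reconstruction is filtered
back projection with a Hann-apodized ramp (cutoff at Nyquist); zero counts
are clamped to 0.5 before the log (photon starvation rule).  The HU scale
comes from scanning a noiseless water cylinder of the same patient size
under the same protocol: μ_water is the mean over a central disc, μ_air the
mean over the outside-air region, mirroring scanner self-calibration so the
background of every phantom sits near 0 HU despite beam hardening.  A
noiseless monoenergetic project→reconstruct round trip recovers μ to
≈ 10⁻⁶ relative away from edges (the analytic projector and the FBP
discretization are mutually consistent); the 3 % acceptance bound is loose.

## Phantoms and study conditions

Thorax measurement phantoms: printed pixel grids 640×440 / 740×540 /
840×640 at 0.5 mm with elliptical bodies of 30×20 / 35×25 / 40×30 cm
(the extra grid margin is air); a 10 mm outer fat ring (20:80 water/lipid
by mass, 0.95 g/cm³); a PMMA body; and a central 90 mm water-equivalent
scoring region carrying the nine calcification inserts (three diameters
1/3/5 mm × three HA loadings, length 1.5 mm, i.e. three 0.5 mm slices) on
a 27 mm ring.  An insert is modelled as soft tissue (water-equivalent,
1.0 g/cm³) plus its HA loading.  The scoring region is water-equivalent
rather than PMMA because calcifications must sit in a ≈ 0 HU matrix for
the 130 HU Agatston threshold to behave as designed — PMMA itself reads
≈ +110 HU.  Rasterization anti-aliases edges by 4× sub-voxel supersampling;
per-insert rasterized HA mass converges to the analytic cylinder mass
(< 1 % at 4×).

Density triples per patient size (mgHA/cm³): low group small (15, 19, 25),
medium (52, 59, 73), large (37, 45, 52); high group small (110, 140, 180),
medium (500, 640, 780), large (250, 330, 410).  Only the medium low triple
is pinned by the emulated commercial insert set; the others were chosen
once to span the group ranges (15–73, 110–780) with the medium phantom
carrying the top of each range, and are configuration, not constants.

Calibration phantoms: an 8-rod disc (0–600 mgHA/cm³, 10 mm rods in a
water-equivalent body) scanned at 80/135 kV for the decomposition model,
and a single-rod (100 mgHA/cm³) phantom scanned at 120 kV supplying the
volume-fraction reference signal and the Agatston mass factor.  By default
one mid-size rod phantom calibrates all patient sizes, as with a single
physical disc; per-size refitting is config and changes results negligibly
because every scan is HU-self-calibrated.

Segmentation is purely geometric (the phantom is known exactly): insert
ROIs are footprints dilated 1.0 mm (a 5 mm insert → 7 mm ROI, capturing
blur and partial-volume spill); background ROIs are congruent discs on
four insert-free rings (33 positions per slice, ≈ 99 samples per method
and protocol for threshold estimation); rod cores are eroded 1.0 mm.

## Scoring and statistics

Agatston: threshold 130 HU, 8-connected in-plane lesions, minimum lesion
area 1.0 mm², per-slice scoring at 0.5 mm with no 3 mm slice-thickness
renormalization (the comparison is at fixed thin slices).  The mass
variant multiplies lesion volume × mean HU by a factor measured on the
100 mgHA/cm³ rod.

Volume fraction: the implemented per-voxel fraction is
`k_i = (i − S_Bkg)/(S_Obj − S_Bkg)`, the form under which a pure-calcium
voxel is 100 % and pure background 0 %, as the description of k as a
calcium percentage requires; the variant `(i − S_Obj)/(S_Obj − S_Bkg)`
appears in some transcriptions and is available behind
`convention="printed"` for exactness testing.  `S_Obj` comes from the
eroded rod core; `S_Bkg` is sampled from a 2-voxel ring immediately
outside each ROI.  Negative fractions are retained so background masses
stay centred — the detection threshold depends on that.

Material decomposition: the 8-coefficient rational model is fitted by
Levenberg–Marquardt from a linear-in-parameters start (denominator frozen),
with two stabilizations that matter in practice.  First, rod signal pairs
are nearly collinear in the (S_L, S_H) plane, so the quadratic surface is
unidentified transverse to the rod manifold; the linear stage therefore
solves in a scaled signal space by truncated SVD (relative cutoff 10⁻⁴),
which returns the minimal-norm solution — flat along unidentified
directions — and is exact for well-spread designs.  Second, if the refined
denominator could reach zero anywhere in an expanded signal box (rod range
± 50 % plus a 500 HU margin, covering noisy voxels), the frozen-denominator
solution is kept.  Default calibration sampling is every rod-core voxel of
the noisy calibration scans (≈ 1600 samples), which conditions the fit the
way practical image-domain calibration does; 8 rod-mean sampling is config.
Decomposition is voxel-by-voxel; negative densities are retained.

Detection statistics: Agatston false negative ⇔ score exactly 0; mass
methods ⇔ mass ≤ mean + 1.5 SD of background masses, estimated per
(method, patient size, ROI size class) — the inclusive ≤ matters at the
boundary.  False positives are the mirror rule on background ROIs.
Diagnostic metrics use the 81 insert measurements per group against 81
matched background negatives (three per size class per slice).  With a
1.5 SD Gaussian threshold the expected background false-positive rate is
≈ 6.7 % one-sided; it is reported, not asserted.  Accuracy is RMS error
against analytic per-slice ground truth (RMSE) and against ordinary
least-squares fitted values, intercept included (RMSD); a zero-intercept
regression is config.

## Problem sizes and determinism

The default study profile runs the full 0.5 mm voxel grids with 360
projection angles over 180° and 2 keV spectrum bins; one full two-group
experiment takes ≈ 2.5 minutes on a single CPU, and the acceptance script
averages three master seeds in ≈ 7–8 minutes.  A 720-angle profile is
config for finer angular sampling; it changes scores marginally because
dose is held fixed per detector element.  Partial-volume behaviour — the
driver of the detectability results — lives in the 0.5 mm voxel grid,
which is therefore never coarsened.  All randomness flows from one master
seed through stable per-(phantom, kV, slice) hashes; a fixed seed
reproduces every image bit-for-bit.  The reduced "tiny" fixture (192²
grid, 4 inserts, 180 angles) builds, scans and scores in seconds and
carries the noise-free recovery checks (mass methods within 10 % of ground
truth for ≥ 3 mm inserts; in practice ≈ 2 % for decomposition and ≈ 5 %
for volume fraction, the latter dominated by blur spill against a locally
sampled background).

## What the simulation does and does not show

Modelled: polyenergetic beam hardening, quantum noise scaling with patient
size and exposure, partial volume at 0.5 mm, blur from apodized FBP, the
full calibration chains of both mass methods.  Not modelled: Compton
scatter, detector energy response and electronic noise, helical/cone-beam
geometry, cardiac motion and metal artifacts, anatomical background
heterogeneity (the scoring background is uniform soft-tissue equivalent),
and bowtie-shaped fluence profiles.  Passing results therefore demonstrate
the *relative* behaviour of the three scorers under controlled
noise/partial-volume conditions, not absolute clinical performance.

One documented divergence: with the stabilized calibration fit, the
decomposition method is as accurate as the volume-fraction method (its
background decomposes to ≈ 0 density), so its RMS error is not inflated by
a background-density offset.  An unregularized fit of the same
non-identifiable model can assign pure background a large non-zero density
— an offset that cancels in the mean+1.5·SD detection rule but dominates
RMSE; that regime, and only it, makes decomposition simultaneously the
most detectable and least accurate method.  The package deliberately ships
the stable fit and records the contrast in the test suite.
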