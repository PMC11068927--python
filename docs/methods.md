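# Methods

`dwiqa` quantifies two things about echo-planar (EPI) diffusion-weighted
MRI: how accurate the apparent diffusion coefficient (ADC) is, and how
badly off-resonance distorts the image geometry. It bundles the analysis
stages with a synthetic-data module that generates the phantoms and
brain-like scenes the pipeline is validated on. This note records the
models, the defaults and why, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Signal model and ADC estimation

Voxelwise signal follows the two-compartment (IVIM-style) decay

S(b) = S0 · [ f · exp(−b·D*·10⁻⁶) + (1−f) · exp(−b·D·10⁻⁶) ]

with diffusivities in μm²/s and b in s/mm² (1000 μm²/s = 1.0·10⁻³ mm²/s,
hence the 10⁻⁶). f = 0 gives the mono-exponential model that the ADC fit
assumes. The fit is an unweighted ordinary least squares of ln S on b per
voxel: slope = −ADC·10⁻⁶, intercept = ln S0. It is closed-form, exact on
noise-free mono-exponential data (tested to 10⁻⁹ relative), and applies to
any b-value subset containing 0 — the pipeline routinely compares the
all-b fit ("ADCall") with the two-point {0, 800} fit ("ADC0,800").
A weighted or nonlinear fit would down-weight noisy high-b points; it is a
possible extension, not implemented.

### Noise floor

Magnitude MR images have Rician noise; in background the second moment is
E[S²] = 2σ². The background level η² is estimated as the mean squared
intensity over a user-placed cuboid (≥ 100 voxels) pooled across all
b-volumes, and signals are corrected in quadrature:
S′ = sqrt(max(S² − η², 0)). Samples with S² ≤ η² carry no usable signal
and are dropped from that voxel's regression (never clamped into it);
voxels with fewer than two usable points are marked invalid. Replicate
acquisitions at the same b (the two phase-encode polarities) are averaged
after correction, before the log.

Two statistical facts shape how this correction should be read, and both
are asserted in the test suite:

* E[S′²] = ν² exactly — the corrected squared signal is unbiased, and an
  ADC computed from RMS-pooled signals is debiased by the correction.
* the voxelwise *log-domain* fit is largely self-correcting:
  E[ln S_meas] = ln ν + O(σ⁴/ν⁴), so at moderate SNR the correction
  changes the voxelwise ADC little, and at very low SNR the log of the
  corrected signal acquires a −(σ/ν)² Jensen bias. The correction's real
  leverage in this pipeline is the flagging: samples at or below the floor
  are excluded instead of dragging the fit.

That flagging produces a qualitative effect the brain study reproduces:
when the strongly attenuated CSF signal at b = 800 falls below the floor,
the all-b fit loses its high-b anchor and leans on the steep
fast-compartment segment at low b, so mean ADCall in CSF rises well above
mean ADC0,800. For a noise-free bi-exponential the ordering is the
opposite (the convex dip of ln S at low-mid b flattens the OLS slope
relative to the {0, 800} chord) — the divergence between the two subsets
is a noise-floor phenomenon, not a property of the clean signal.

### Reference values

Calibrated vial ADCs are temperature-corrected by linear interpolation in
a user-supplied calibration table (vial → {°C: μm²/s}); temperatures
outside the tabulated range are an error. Comparisons are expressed as
(ADC1 − ADC2)/ADC_reference.

## Geometric distortion

### Grid phantom and marker detection

The grid phantom is three orthogonal families of square-section beams
(6 mm thick, 25 mm apart, lattice spanning 10 cm per axis). Markers are
the beam intersections; the synthetic generator emits the full 5×5×5
lattice with exact world coordinates. Two rasterization choices matter
for subvoxel accuracy and are deliberate: voxels get partial-volume
(box-overlap) coverage rather than a hard binary threshold, and beams
overhang the outer lattice plane by 7.5 mm so every intersection is a
complete three-axis cross. Without these, the normalized cross-correlation
(NCC) response aliases (≈ 0.26 mm mean localization error at 1.5 mm
voxels) and boundary markers bias inward by up to ≈ 1 mm; with them the
zero-distortion detection floor is ≈ 0.03 mm mean / 0.05 mm max.

Detection matches a cross-shaped template (same rasterization, default
15 mm arms) by NCC within one search neighborhood per expected marker
(half the grid spacing). The peak is refined per axis by quadratic
interpolation of its two neighbors (offset clipped to ±0.5 voxel).
Markers whose peak NCC falls below 0.5 (configurable) or whose
neighborhood has no intensity variation are reported missing and excluded
from — but counted alongside — the statistics.

### Referencing and reporting

Detected markers are referenced to the theoretical lattice by a rigid
(rotation + translation, explicitly no scaling) Procrustes fit computed on
the central 3×3×3 markers only, via the Kabsch SVD construction with
reflection correction; lattices with an even line count have no
unambiguous center and require an explicit selection. Restricting the fit
to the central block means global positioning is removed while peripheral
distortion is measured, not absorbed. Distortion is the per-marker
Euclidean distance after alignment; a report carries the per-marker
distances, their mean and maximum, and detection counts. Scenario
summaries average the per-acquisition means and the per-acquisition
maxima arithmetically across b-values/repetitions. The same pipeline run
on a high-resolution (CT-like) image serves as the manufacturing-accuracy
check of the physical grid.

## Off-resonance: warping, estimation, metrics

An off-resonance field B(x) in Hz displaces EPI signal along the
phase-encode (PE) axis by d = pe_sign·B/bw pixels (bw = per-pixel PE
bandwidth). The synthetic warp is a pull-back with Jacobian modulation,
out(x) = J(x)·v(x − d(x)), J = 1 − ∂d/∂x by central differences, which
conserves PE line integrals to first order (tested: ≤ 0.2% on smooth
fields) — conservation is what makes reversed-PE estimation possible.

The field estimator is a deliberately simple integral-matching stand-in
for external reversed-gradient tools: per PE line, the normalized
cumulative-intensity profiles of the blip-up and blip-down images are
samples of one underlying profile at +d and −d, so monotone CDF inversion
yields d at each pixel. The implementation symmetrizes the match
(averaging the forward and negated reverse estimates), which makes the
estimator exactly antisymmetric in the input order and second-order
accurate; the raw field is then smoothed with an intensity-weighted
Gaussian (default 4 mm) so empty background neither contributes nor
bleeds in. Accuracy on smooth ≤ 2 px fields is ≈ 0.02–0.07 px RMS inside
the object; externally computed Hz field maps can be ingested instead
(d = Hz/bw). Correction resamples the up image at x + d and the down
image at x − d (linear interpolation, Jacobian-modulated — the
first-order inverse of the warp) and averages the pair.

Field summaries: ppm = Hz/f₀·10⁶ (f₀ the scanner resonance, e.g.
14.707 MHz at 0.35 T, 123.152 MHz at 3 T); displacement
mm = Hz/bw·voxel_PE; and the 95th percentile of the absolute value within
a mask (linear-interpolation quantile — the convention is a choice and is
documented because order-statistic conventions differ).

## VOI statistics

Each volume of interest (vial cylinder — default radius 6 mm, height
39 mm — or tissue label) is summarized over its valid voxels by mean,
median, sample (n−1) standard deviation, and the nonparametric skew
(mean − median)/SD, defined 0 when SD = 0 and bounded by |·| ≤ 1. ADC
variants are compared per subject by two-tailed paired Wilcoxon
signed-rank tests (zero differences dropped; exact null for n ≤ 25
without ties, normal approximation with tie correction otherwise; the
all-zero case is undefined and reported as such), flagged at p < 0.05
with no multiplicity correction.

Note the sampling noise of the nonparametric skew: for an i.i.d.
near-Gaussian sample its SD is ≈ sqrt(0.57/n), i.e. ≈ 0.08 at the ~66
voxels a vial VOI holds at 3×3×6 mm — single-acquisition skew values
below ≈ 0.1 are indistinguishable from zero at this VOI size, and the
maximum over several vials will frequently exceed 0.1 by chance alone.

## Synthetic study designs and their scope

* **Vial study** (`studies.vial_study`): four vials with calibrated
  diffusivities 400/1000/1600/2020 μm²/s (20 °C values), S0 = 1000,
  b = {0, 200, 400, 600, 800} s/mm², 3×3×6 mm voxels, Rician noise at
  SNR(b=0) = 40, two PE repeats, background cuboid of 768 voxels,
  noise-floor-corrected fits on all b and on {0, 800}.
* **Grid study** (`studies.grid_distortion_study`): grid at 1.5 mm
  isotropic voxels (fine enough that localization error stays well below
  the millimeter displacements under test), noise-free, warped by a
  deterministic cos² ridge field whose peak displacement sits exactly on
  the x = +50 mm marker plane and which vanishes on the central block —
  so the true maximum is known by construction and cannot be absorbed by
  the rigid referencing. Field estimation and correction run on the
  warped pair.
* **Brain cohort** (`studies.brain_cohort_study`): seven subjects of
  nested-ellipsoid heads (CSF D = 3000 with f = 0.3, D* = 10000; GM 900;
  WM 700 μm²/s; 3% between-subject CV), SNR(b=0) = 15 — chosen so the
  background floor η = σ√2 exceeds the CSF b = 800 signal by ≈ 50%, the
  low-field regime in which the b-value subsets genuinely diverge.

What these do not emulate: coil sensitivity and spatially varying noise,
partial-volume mixing at tissue boundaries beyond voxelization, bulk
motion and cardiac pulsation, eddy currents, multi-shot readouts,
gradient nonlinearity, and the concentration-dependence of real phantom
vials. Passing the synthetic suites therefore demonstrates the
correctness and internal consistency of the estimators under their stated
noise model, not scanner-grade performance.

## Degenerate inputs and tie-breaks

Vials that overlap or leave the grid, ellipsoids exceeding the volume,
voxels coarser than the beam, and sub-thickness grid spacing are
geometry/resolution errors. Displacements beyond the image extent are
warp errors. All-zero PE lines estimate zero displacement. Collinear or
< 3 point pairs are registration errors, as are < 3 detected central
markers. NCC peaks at the response boundary skip quadratic refinement on
the clipped axis. All generators are deterministic given a seed; every
workflow writes a manifest of its inputs and parameters, and reruns are
byte-identical.
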