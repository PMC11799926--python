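# Methods

This note documents the models, numerical choices and known limitations of
`adaptct`. The toolkit implements an offline adaptive-radiotherapy (ART)
validation chain: a CBCT→synthetic-CT generator plus the quantitative
machinery used to judge whether synthesized CTs are good enough to plan on —
image-quality metrics, DVH-derived dose indices, and 3-D gamma analysis —
all exercisable end-to-end on seeded digital thorax phantoms.

## Synthetic thorax phantoms

Clinical CBCT/CT pairs cannot ship with a toolkit, so every pipeline stage is
validated on a parametric digital thorax. The phantom is an axial elliptical
body (soft tissue, 40 ± 20 HU) on air (−1000 HU), containing two lung
ellipsoids (−700 ± 50 HU), a heart ellipsoid, a posterior vertebral column
with a spinal-cord canal, rib-like bone arcs (700 ± 100 HU) on the body
shell, and a spherical lesion (GTV, 30 HU) inside one lung. Lung masks
exclude overlapping mediastinal and bony structures, so the mask hierarchy
GTV ⊂ ipsilateral lung ⊂ bilateral lungs ⊂ body holds exactly. Cohorts are
generated with per-case geometry jitter (body axes ±6%, organ centers a few
mm, lesion radius ±15%) from seeds derived deterministically from a master
seed: the same call is always bit-identical.

CBCT-like degradation stacks four artifact families on the clean CT, in this
order: a radially quadratic cupping bias (default −80 HU at the
field-of-view center, 0 at the edge — the dominant scatter artifact shape),
per-slice straight-line streaks (4 per slice at ±60 HU), a global affine HU
miscalibration (gain 1.02, offset −40 HU), and white HU noise (sd 20 HU).
These defaults were calibrated once so that the body-masked MAE between
degraded and clean volumes on the default phantom lands near 96 HU, the
scale of uncorrected thorax CBCT error reported in the clinical literature
this toolkit's validation design follows; the calibration is a convention,
not a physical scatter model. The generator does not emulate projection-
domain reconstruction, beam hardening or respiratory motion, so passing
tests demonstrate that the pipeline removes *systematic, spatially smooth
and affine* HU corruption — not that it handles motion artifacts or
truncation in real cone-beam data.

The analytic dose generator assigns the prescription (60 Gy default) inside
the GTV and halves the dose every `falloff_mm` (default 8 mm) of Euclidean
distance outside it, which yields clinically plausible gradient indices
(GI ≈ 6–8) on default phantoms.

## Preprocessing

* Intensities are clipped to [−1000, 3000] HU, then Z-score normalized.
  The normalization statistics are pooled over the *training* cohort's
  clipped body voxels and frozen as a fixed affine map, so any model output
  is exactly invertible back to HU. (A per-volume normalization would make
  the inverse depend on the corrupted input — undesirable for a
  calibration-recovery task.)
* Body delineation thresholds at −300 HU, keeps the largest connected
  component, closes with a radius-2 structuring element and fills holes
  (3-D plus per-slice). Against the simulator's ground truth this recovers
  the body outline to Dice > 0.98 away from a 2-voxel boundary band.
* Rigid registration recovers translation by subvoxel phase correlation;
  an optional refinement stage (Powell minimization of the mean-squared
  intensity difference) adds small Euler-angle rotations. Synthetic pairs
  are organ-aligned by construction, so deformable registration is out of
  scope. All resampling is trilinear with −1000 HU fill.
* The 2.5-D input for slice k stacks slices (k−1, k, k+1) with edge
  replication at the volume boundaries.

## The UNet++ generator

The generator is a nested encoder–decoder. An encoder column of residual
bottleneck blocks (1×1 reduce → 3×3 → 1×1 expand with a projected shortcut)
produces one feature map per scale; the full-size preset has five scales at
512×512 in-plane with 3 input channels and 1 output channel, the tiny preset
three scales at base width 8 so CPU training is practical. Downsampling is
2×2 max pooling; upsampling is bilinear interpolation (a convolution in the
receiving node follows, so no transposed convolutions are needed). Every
decoder node X^{i,j} (j > 0) receives the channel concatenation of all
same-scale predecessors X^{i,0..j−1} with the upsampled X^{i+1,j−1}; the
node set is exactly {X^{i,j} : i + j < depth}. Deep supervision is not used.

The synthesis head is a linear 1×1 convolution on X^{0,depth−1} whose output
is **added to the center input slice** (residual synthesis). The head is
zero-initialized, so an untrained model is exactly the identity map on the
CBCT. This matters a great deal numerically: without it, a freshly
initialized residual encoder emits activations an order of magnitude larger
than the targets and the optimizer spends most of a short training budget
re-learning the identity; with it, training starts from the CBCT baseline
and immediately optimizes the *correction*, which is the quantity of
interest. The output is linear (no activation) because targets are z-scored
intensities.

The whole network runs on a small reverse-mode autodiff engine written for
this package (conv2d as shift-GEMM over BLAS, max-pool, bilinear ×2
upsampling, separable Gaussian blur, elementwise ops, Adam). Every
primitive's gradient is verified against central finite differences in the
test suite, and the convolution forward pass is verified against
`scipy.signal.correlate2d`.

## Training

The loss is `L = λ1·L_MAE + λ2·L_MSE + λ3·L_SSIM` with λ = (100, 1, 1).
MAE and MSE are averaged over the body region only (the union of air
outside the patient carries no calibration information); the SSIM term is
`1 − SSIM` over the full image, using the windowed local SSIM (11-tap
Gaussian window, σ = 1.5, fixed dynamic range 4 in normalized units) so a
perfect prediction gives exactly zero loss and the term has useful
gradients. Which body mask (CT's, CBCT's or their union) the masking uses
is a free choice; the union is used.

Optimization is Adam. Full-scale defaults are lr 1e-4 for 200 epochs;
augmentation applies, with probability 0.5, one of {rotation ±10°,
translation ±10% of the image, horizontal flip}, identically to the input
stack, target and mask. The desk-scale protocol used throughout the tests
and the acceptance script is: tiny preset, 20 phantom cases of 64×64×16
voxels at 2 mm, 30 epochs, batch 8, lr 1e-3 — the higher rate matches the
much smaller model and the 30-epoch budget and was fixed as part of the
scaled protocol. The trailing 15% of cases form the validation split,
echoing a 70/15 train/test cohort ratio. Whole-volume synthesis runs
slice-wise 2.5-D inference, inverts the frozen normalization to HU and
composites −1000 HU outside the CBCT body outline.

Under these conditions the held-out body-masked MAE versus the planning CT
drops from ≈97 HU (raw CBCT) to well under the 30%-reduction bar, and a
pure affine miscalibration is recovered to a residual MAE below 10 HU —
the direction and character of improvement expected of a CBCT-to-sCT
model, at phantom scale.

## Image-quality metrics

MAE is the mean absolute HU difference over the evaluation region (the body
mask by default; the region choice is configurable because conventions
differ). PSNR is `10·log10(MAX²/MSE)` dB, with MAX taken from the reference
volume in-region by default and a fixed-range option (4000 HU) provided,
because per-image maxima are fragile when most HU are negative; identical
images return a documented 100 dB cap instead of infinity. SSIM comes in
two forms: the *global* single-window formula evaluated once with
whole-region statistics, and the conventional *windowed* mean of local SSIM
(via scikit-image). Stabilizers use the standard k1 = 0.01, k2 = 0.03.
Cohort evaluation prints, alongside mean ± sd of each metric for CBCT and
synthetic CT against the planning CT, percentage improvements computed as
`(mae_cbct − mae_act)/mae_act` for MAE and `(m_act − m_cbct)/m_cbct` for
PSNR/SSIM — the formulas are embedded in the report because no single
convention exists for "percent amelioration".

## DVH and dose indices

A voxel belongs to a structure iff its center is inside the mask; cumulative
DVHs are built by exact voxel counting at 0.05 Gy resolution. Dx% queries
are answered as step quantiles on the exactly-counted curve (the largest
bin dose received by at least x% of the structure), so a uniform dose yields
Dx% equal to that dose for every x; linear interpolation across a
plateau-to-zero jump would bias such degenerate but common test cases.
HI = (D2% − D98%)/D50%. GI = V50%/V100%. CI uses the Paddick form
V_GTV,ref²/(V_GTV·V_ref), which is bounded in [0, 1] by construction;
because published CI values above 1 necessarily come from the ratio form
V_ref/V_GTV, that form is available behind `form="ratio"`, and values
above 1 from the Paddick form are impossible rather than flagged. OAR
tables report Dmean, Dmax and V5/V20/V30 as percent of structure volume.
Dose overlay after rigid registration is trilinear with zero fill.

## Gamma analysis

For each reference voxel at or above the low-dose threshold (10% of the
global reference maximum; sub-threshold voxels are excluded from both
numerator and denominator of the pass rate), γ is the minimum over a
displacement lattice of `sqrt(ΔD²/ΔD_tol² + |r|²/DTA²)` with the evaluated
dose trilinearly interpolated at lattice points (step DTA/10 by default).
Normalization is global (DT% of the reference maximum) by default, with a
local mode available; the global/local choice and the absolute mode are the
dominant clinical conventions. The search is truncated at radius 3·DTA:
beyond it the DTA penalty alone exceeds 3, which cannot affect pass/fail at
γ ≤ 1. The production implementation sorts displacements by |r| and retires
a voxel as soon as its current best γ² is below the DTA penalty of the next
displacement — an exact, not approximate, pruning. An independent
brute-force oracle (exhaustive over the same lattice, with its own manual
trilinear interpolation, guarded to ≤32³ grids) agrees with it to 1e-6
per voxel on random smooth-plus-noise dose pairs. Displaced points outside
the evaluated grid are excluded from the search in both implementations.

## Problem sizes

Desk-scale defaults — 64×64×16 phantoms, tiny preset, 30 epochs, 20 cases,
16³ gamma grids with a 1 mm evaluation step for oracle comparisons — were
chosen so the full pipeline (two trainings included) runs in well under an
hour on a single CPU core while still exercising every code path at
realistic parameter ratios. The full-size preset reproduces the clinical
geometry (5 scales, 3×512×512 in / 1×512×512 out) and is exercised for
shape contracts in the tests.

## Known limitations

* The phantom's artifact model is additive and global; real cone-beam
  scatter, beam hardening, truncation and motion are not simulated, so
  clinical performance claims cannot be derived from these tests.
* The CPU engine is single-threaded and desk-scale; the full 512×512
  five-scale preset is practical for inference-shape checks, not for
  200-epoch training.
* Registration assumes near-axis-aligned volumes with small rotations;
  deformable alignment is explicitly out of scope.
* DICOM support covers axial CT series and RT Dose grids with axis-aligned
  geometry; oblique orientations are not interpreted.
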