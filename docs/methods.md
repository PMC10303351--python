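# Methods

This note records the models behind `fundushsi`, the defaults that matter,
what the synthetic phantoms do and do not emulate, and the design choices
made where the procedure was genuinely open.

## Vessel segmentation

The enhancement filter is the classic two-dimensional Gabor pair: a
Gaussian envelope of standard deviations (σx, σy) pixels modulated by a
cosine (real part) and sine (imaginary part) plane wave of spatial
frequency f₀ cycles/pixel along the rotated x′ axis. The real kernel is
even and the imaginary kernel odd under point reflection, so the complex
magnitude is insensitive to ridge polarity — bright-on-dark and
dark-on-bright vessels respond identically, which is why binarization acts
on the response map rather than the raw green channel. Filtering is
correlation (no kernel flip); with the parity above, the magnitude is
identical under either convention. Borders are reflection-padded.

The angle grid [−π/2, π/2] in 1° steps is taken inclusive at both ends
(181 angles); the two endpoint kernels coincide up to the sign of the
imaginary part, which the magnitude absorbs.

Defaults: f₀ = 1/6 cycles/px, σx = σy = 1.75 px, kernel halfwidth 8 px.
The half-period of the carrier (3 px) and the envelope width then match
the ridge cores of 2–12 px vessels; during development f₀ = 1/8 and
σ = 2.5 px were evaluated and consistently produced a wider, blurrier
response ridge (Dice against phantom ground truth ≈ 0.83 mean, with
single-seed minima at the 0.80 boundary, versus 0.88/0.85 for the
defaults), so the sharper bank was adopted. All parameters are exposed in
`GaborParams` and the run config.

Iterative threshold selection starts from the global mean and repeatedly
resets the threshold to the average of the two group means. Convergence
requires both a step smaller than ε (default 0.5 gray levels on the 0–255
scale) *and* a stable low/high partition; because the mean-of-means map is
piecewise constant between data values and monotone, the second condition
is reached in finitely many extra steps and makes the returned threshold
an exact fixed point. With the step test alone, the iteration can stop
one or two gray levels short of the fixed point on weakly bimodal inputs.
Ties (value == T) go to the low group. The Gabor response map is min–max
rescaled to 0–255 before thresholding so ε is expressed in meaningful
units; a flat map returns an empty mask.

When a field-of-view (FOV) mask is available, the exterior is filled with
the mean interior green intensity before filtering and the threshold is
computed from FOV pixels only. Without this, the black exterior forms the
dominant low mode of the histogram (the mean-of-means split then separates
"inside vs outside" rather than "vessel vs background") and the FOV rim is
itself a strong oriented edge. The output is restricted to the FOV eroded
by 2 px. Small-object removal (default: components under 30 px at
8-connectivity) delegates to scikit-image.

`estimate_fov_mask` thresholds mean channel intensity (default 0.05),
keeps the largest connected component, closes and hole-fills it — adequate
for the circular aperture of fundus photographs.

## Camera model and color checker

The camera integrates illuminant × reflectance × sensitivity per channel
and normalizes by illuminant × sensitivity, so a perfect white maps to
RGB = (1, 1, 1) at unit gain. Defaults: Gaussian sensitivities peaking at
600/540/460 nm with 40 nm standard deviation under a flat illuminant —
the simplest model that makes RGB an informative summary of the spectrum.
Any real light-source correction is considered folded into these curves;
there is no separate divide-out step.

The synthetic 24-patch checker has a 6-level neutral ramp (0.05–0.90) and
18 chromatic patches drawn from a fixed smooth family: flat level + two
wide Gaussian components at 480/620 nm (amplitudes ±0.3) + four small
narrow components (±0.01) that raise the spectral rank to ≥ 7. The level
is sampled conditionally on the chromatic excursion so no patch ever needs
clipping, keeping the family exactly low-dimensional. This mirrors the
well-documented low intrinsic dimensionality of natural and
checker-target reflectances — the property that makes spectral
reconstruction from three camera numbers possible at all. With this
family the 6-eigenvector basis truncation error and the RGB-regression
residual together stay below 0.02 RMSE per patch (worst case ≈ 0.015 over
12 seeds).

## Spectral reconstruction

The wavelength grid is 380–780 nm at 1 nm (401 samples); the band is the
instrument's visible range, the step a free choice (configurable). PCA is
fitted to the calibration spectra (covariance divided by n; components
sign-fixed so the largest-magnitude loading is positive); requesting more
components than the data's rank is an error rather than a padded basis.
The regression target is the 6 basis coefficients, not the raw
401-vector: 24 patches cannot support 401 independent regressions. The
feature expansion is the fixed 11-term polynomial in (R, G, B) up to the
bilinear/trilinear products; ridge default 1e-6 (a numerical stabilizer —
at 24 × 11 the design is comfortably overdetermined). Reconstructed
spectra are clipped to [0, 1]; on noiseless in-span fixtures the clip
never triggers.

## Phantoms

Each phantom is a seeded, pure function of its parameters: a circular FOV
(radius 0.46 × image size) on black; inside it, a dark reddish background
(flat ~0.10 reflectance rising to ~0.22 in the red — a stand-in for the
pigment-epithelium/choroid return) and branching vessel trees. Trees
leave an optic-disc-like origin (0.7 R from center, random bearing)
through distinct, interleaved bearing slots — three artery and three vein
trees by default — as quadratic Bézier segments of 2 recursion levels,
widths 3–6 px for arteries (children ×0.75, floor 2 px) and 1.5× wider
veins, capped at 12 px. An earlier draft grew all trees from the exact
same point; the resulting artery/vein overlap put up to a quarter of
artery pixels inside vein tubes, making the ground-truth labels
meaningless, so the seeding was respread. Cross-sections are Gaussian
with σ equal to the local radius; the ground-truth mask is the one-sigma
core, so labeled pixels carry 61–100 % vessel color over background.
Composite color is α·class RGB + (1−α)·background, plus i.i.d. Gaussian
RGB noise (default sd 0.01) inside the FOV. Default coverage lands at
7–11 % of the FOV (the generator rejects configurations above 50 %).

Artery/vein spectra are smooth parametric curves, not literature
hemoglobin tables: a logistic red-band rise (base 0.12, amplitude 0.48
centered at 575 nm) minus two Gaussian absorption dips at 510/545 nm for
the artery; the vein is the artery minus `contrast_scale` times a fixed
nonnegative difference profile (red logistic of amplitude 0.24 plus a
small 0.03 mid-band Gaussian). A shared dip at 535 nm deepens with
(1 − contrast_scale), emulating the reported mid-band reflectance loss
with disease severity, and the vein's red-band reflectance rises as the
contrast collapses. Stage defaults: normal 1.0, BDR 0.6, PPDR 0.45,
PDR 0.25 — spaced so the per-stage difficulty ordering is measurable.
Because the difference is linear in `contrast_scale`, halving the scale
halves the pointwise artery–vein gap exactly, which the tests exploit.

What the phantoms do **not** emulate: lesions (exudates, hemorrhages),
vignetting and focus falloff, vessel tortuosity/caliber variation along a
segment, ocular-media scattering, sensor noise structure, and real
oxy/deoxyhemoglobin band shapes. Passing recovery tests on phantoms
therefore demonstrates internal consistency of the pipeline under
controlled contrast, not clinical performance.

## A/V score model

A separate score model is fitted per severity stage (the score plots are
stage-specific): 2-component PCA of the vessel-pixel spectra (covariance
divided by n, so duplicating every pixel leaves the model exactly
unchanged), min–max bounds recorded from the training scores, test scores
normalized with the *training* bounds and clamped (no leakage), and a
scalar threshold on normalized component 1. Which side of the threshold
is arterial is learned from the labeled training means — PCA signs are
arbitrary. Threshold methods: `midpoint` (midpoint of the
class-conditional means of normalized PC1) and `f1-scan` (0.01-step sweep
maximizing the training macro-F1). `fit_score_model` defaults to
`midpoint`; the end-to-end pipeline defaults to `f1-scan` because the
artery score distribution has a heavy low tail (vessel-edge pixels mixed
with background), which drags the midpoint toward the artery mode and
systematically sacrifices artery sensitivity; the scan is also the closer
stand-in for a manually placed per-stage threshold.

A known structural limit, measured on the phantoms: with a physically
honest edge-mixing profile, within-class PC1 spread is dominated by
brightness, and part of the class signal lands in PC2, which the
x-axis-only rule cannot use (a two-component linear discriminant on the
same scores scores roughly 8 points higher in artery sensitivity). The
pipeline keeps the one-component rule deliberately: it is the procedure
under study. At full contrast it operates around artery 84/88 and vein
93/90 sensitivity/precision on held-out phantoms — including the
artery-below-vein sensitivity asymmetry that pixel-level A/V methods show
on real fundus data, for the same reason (artery edge pixels misread as
veins).

## Evaluation

Confusion counts are restricted to ground-truth vessel pixels, so
sensitivity and precision denominators are the true artery (vein) pixel
populations and relabeling background pixels cannot change them;
segmentation quality is reported separately as Dice rather than folded
into the A/V metrics. Tables round to one decimal; F1 cells are computed
from unrounded sensitivity/precision. The stage-trend report checks, per
class and indicator, that the normal stage attains the strict maximum and
PDR the strict minimum across the four stages.

## Orchestration

`run_pipeline` executes simulate → (optionally) segment → calibrate →
reconstruct → classify → evaluate with image-level 70/30 train/test
splits (whole images, never pixels, to avoid leakage; test size =
round(0.3 n)). Classification runs over ground-truth vessel masks so
that A/V metrics are not confounded by segmentation errors; enabling the
segmentation stage adds per-image Dice to the manifest. Default study
size: 10 phantoms of 256×256 per stage — large enough that the per-stage
pixel counts (≈ 12 000 vessel pixels per stage per split) make the metric
table stable to well under a point. Everything derives from the config
seed; rerunning a config reproduces metrics byte-for-byte.
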