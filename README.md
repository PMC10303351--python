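# fundushsi

Hyperspectral analysis of fundus photographs for diabetic-retinopathy (DR)
staging support: segment the retinal vessels, turn every vessel pixel's RGB
into a visible-band reflectance spectrum, and separate arteries from veins
from those spectra. The package is aimed at researchers studying
spectral artery/vein (A/V) discrimination who need a fully testable,
self-contained version of this pipeline: a synthetic fundus-phantom
generator stands in for clinical images, so every stage runs and is
validated end-to-end without patient data.

## The pipeline

1. **Vessel segmentation** (`fundushsi.segmentation`). The green channel is
   filtered with an oriented Gabor bank,

   g(x, y) = (2π σx σy)⁻¹ exp(−½ (x′²/σx² + y′²/σy²)) · {cos, sin}(2π f₀ x′),
   x′ = x cos θ + y sin θ, y′ = −x sin θ + y cos θ,

   over θ ∈ [−π/2, π/2] in 1° steps (181 angles). Per pixel only the
   maximum magnitude response R(x, y) = maxθ √(G²ᵣθ + G²ᵢθ) is kept. R is
   binarized by iterative mean-of-means threshold selection
   (T₀ = image mean; Tₖ₊₁ = (μ_low(Tₖ) + μ_high(Tₖ))/2 until convergence),
   and small connected components are removed.
2. **Spectral reconstruction** (`fundushsi.reconstruction`). A 24-patch
   color checker with known reflectance spectra (380–780 nm) is imaged by
   the camera model; PCA of the patch spectra gives a mean spectrum and
   6 eigenvector spectra, and a ridge-regularized regression maps an
   11-term polynomial expansion of RGB, (1, R, G, B, R², G², B², RG, GB,
   RB, RGB), to the 6 basis coefficients. Applying the resulting
   transformation matrix per pixel simulates r(λ) = μ(λ) + Σₖ cₖ vₖ(λ) for
   every vessel pixel.
3. **A/V classification** (`fundushsi.classification`). Per DR stage, the
   vessel-pixel spectra are projected onto their first two principal
   components, scores are min–max normalized to [0, 1], and a scalar
   threshold on the first (x-axis) component assigns artery (drawn red)
   vs vein (drawn blue); the artery side is learned from a labeled subset.
4. **Evaluation** (`fundushsi.evaluation`). Per class and stage,
   sensitivity = 100·TP/(TP+FN), precision = 100·TP/(TP+FP) and their
   harmonic mean F1, over ground-truth vessel pixels; vessel detection
   itself is scored with the Dice coefficient.

The synthetic module (`fundushsi.synthetic`) generates seeded phantoms —
a dark circular field of view, branching Bézier vessel trees (2–12 px,
veins 1.5× wider) colored through a Gaussian-sensitivity camera model from
hemoglobin-like artery/vein spectra — with a severity level
(normal/BDR/PPDR/PDR) whose `contrast_scale` (1.0/0.6/0.45/0.25) shrinks
the artery–vein spectral difference the way DR progression does.

## Worked example

```python
import fundushsi as f

scene = f.make_phantom_fundus(stage=f.NORMAL, noise_sd=0.0, seed=7)
mask = f.segment_vessels(scene.image, fov=scene.fov_mask)
print("dice:", round(f.dice_coefficient(mask, scene.vessel_mask), 3))

checker = f.make_color_checker(seed=1)
basis = f.fit_spectral_basis(checker.spectra, k=6)
M = f.fit_transformation(checker, basis, ridge=1e-6)
cube = f.reconstruct_cube(scene.image, scene.vessel_mask, M, basis)
mean_a = f.mean_class_spectrum(cube, scene.av_labels, f.ARTERY)
mean_v = f.mean_class_spectrum(cube, scene.av_labels, f.VEIN)
print("red-band (620-780 nm) mean reflectance: artery %.3f vein %.3f"
      % (mean_a.band_mean(620, 780), mean_v.band_mean(620, 780)))

model = f.fit_score_model(cube, scene.av_labels, threshold_method="f1-scan")
pred = f.labels_to_map(f.classify(f.project_scores(cube, model), model),
                       cube.coordinates, scene.av_labels.shape)
counts = {c: f.confusion_counts(pred, scene.av_labels, c)
          for c in (f.ARTERY, f.VEIN)}
print(f.metrics_table({"normal": counts}).to_string(index=False))
```

prints

```
dice: 0.857
red-band (620-780 nm) mean reflectance: artery 0.502 vein 0.370
 stage  class  sensitivity  precision    f1   tp  fp  fn
normal artery        100.0      100.0 100.0 1451   0   0
normal   vein        100.0      100.0 100.0 2549   0   0
```

The Dice score says the Gabor segmentation recovers 86 % overlap with the
true vessel mask on a noiseless phantom; the reconstructed mean spectra
show the expected red-band gap between (brighter) arteries and veins; and
on this noiseless scene, with the score model fitted and applied to the
same pixels, the PC1 threshold separates the classes perfectly. The honest
held-out experiment — 10 noisy phantoms per stage, 70/30 image-level
split, a fresh score model per stage — is one command:

```sh
fundushsi run --seed 1 --out-dir scratch/run --n-images 10
```

Test-set F1 degrades monotonically with severity (e.g. artery
87.2 → 69.0 → 62.7 → 48.6, vein 92.1 → 83.1 → 76.5 → 70.8 at seed 1),
mirroring the clinical picture in which the artery–vein reflectance gap —
and hence spectral separability — shrinks as retinopathy advances.

The CLI also exposes each stage separately: `simulate`, `segment`,
`calibrate`, `reconstruct`, `classify`, `evaluate` (see `fundushsi --help`).

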