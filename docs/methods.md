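# Methods

This document describes the models, algorithms, parameter choices and
numerical conventions implemented in `vstseg`, and their limitations.

## 1. Problem setting

The package implements a dual-input segmentation method for cardiac CT: a
hybrid CNN–transformer network that receives both the CT image and a
visual-saliency map computed from it, and predicts a 7-class label map
(background plus six cardiac substructures: left-ventricular myocardium LVM,
left ventricle LV, left atrium LA, right ventricle RV, right atrium RA,
ascending aorta AO). Per-structure volumes derived from the segmentation are
compared against reference volumes with paired statistics.

Because no patient data ships with the package, every component is exercised
on synthetic labelled phantoms (section 2). The phantoms are a test-bed, not
a realism claim: they exist so that the saliency construction, the network,
the training loop and the evaluation metrics are all verifiable end to end.

## 2. Synthetic phantoms (`vstseg.phantom`)

A phantom is a 2-D slice or 3-D volume containing all six structures as
connected regions with exact ground truth:

* **Volumes.** Per-structure target volumes are drawn uniformly from
  literature ranges of manual whole-heart segmentation (defaults, in ml:
  LVM 65.4–128.8, LV 45.1–173.5, LA 38.4–98.9, RV 62.9–198.9, RA 51.1–114.2,
  AO 21.4–48.8). In 3-D the target voxel count is `round(V·1000 / voxel
  volume)`, so the realised volume matches the draw to within half a voxel.
  In 2-D, a fixed foreground fraction (0.35) of the grid is apportioned by
  the sampled volume mix.
* **Geometry.** Each structure is grown voxel-by-voxel in order of an
  anisotropic ellipsoid metric, claiming only voxels face-adjacent to the
  region grown so far, so each structure is connected by construction even
  when it deforms around previously placed structures. The LVM is grown
  outward from the already-placed LV, which yields a closed myocardial
  shell; this is verified after placement (every voxel face-adjacent to LV
  is LV or LVM), along with single-connectedness and no border contact.
  Centres and axes are jittered per seed. 3-D placements use per-structure
  axial centres (atria below the ventricular plane) and a slightly
  contracted in-plane layout; the default 3-D spacing is 2.5 mm because the
  largest literature volumes cannot be packed into a 64³ grid at finer
  spacing. `generate_dataset` deterministically rejects the occasional
  infeasible jitter draw and substitutes further child seeds.
* **Intensities.** Piecewise-constant means on a [0, 1] scale with
  contrast-filled chambers and aorta brighter than myocardium (LVM 0.35,
  LV 0.85, LA 0.65, RV 0.60, RA 0.55, AO 0.90), optional Gaussian noise
  (default sd 0.05) and optional cross-boundary blur. Noise and blur perturb
  the image only; masks and volumes stay exact.

Determinism: one `numpy` generator seeded from the spec drives every draw,
so identical specs give bit-identical phantoms.

## 3. Visual-saliency map (`vstseg.saliency`)

The saliency map is the network's second input. It combines a local and a
global stage.

**Local stage.** The image is decomposed into `n_scales = 6` levels of a
Gaussian pyramid (separable 5-tap binomial kernel [1,4,6,4,1]/16, reflect
boundary, decimation by 2; the image must be at least 2^(n_scales−1) per
axis). On every level, three centre–surround contrast maps are computed as
|value − mean over an annulus| with annulus radii (1, 4]:

1. *intensity* — the level itself;
2. *texture* — local Shannon entropy of 16-bin intensity histograms over a
   5×5 window;
3. *colour proxy* — the mean contrast of three fixed window/level presets of
   the single CT channel ((0.0, 0.6), (0.2, 0.8), (0.4, 1.0) on the
   per-image min–max scale), standing in for colour channels that CT lacks.

This yields 6 × 3 = 18 maps. Per feature, maps are upsampled back to full
resolution by repeated 2× bilinear interpolation and summed into fused
feature maps; the local saliency is the sum of squares of their min–max
normalisations: `S_local = N(IFM')² + N(TFM')² + N(CFM')²`.

**Global stage.** Per pixel k, `S_global(k) = Σ_j ‖p_k − p_j‖` where `p_k`
concatenates the 3×3 patch around k across the three window presets applied
*without* clipping or per-image normalisation, i.e. as pure affine maps.
This keeps the stage homogeneous: scaling the image by c scales `S_global`
by c (a property tested directly). The exact computation is quadratic in
pixel count and is run blocked; for images larger than 64 per side the
default path computes it on a bilinearly downsampled copy (max side 64) and
upsamples the result (`exact=True` disables this).

**Fusion.** `ω = θ·N(S_local) + (1−θ)·N(S_global)` with θ = 0.5, and
`SM = ω · S_global`. `N(·)` is min–max normalisation to [0, 1]; a constant
map normalises to all zeros, so a constant image has identically zero
saliency. ω is a convex combination and therefore lies in [0, 1].

## 4. Network (`vstseg.model`)

Two identical CNN encoders process the CT image and the saliency map. Each
encoder is `stages = 4` repetitions of [3×3 conv + ReLU, ×2; 2×2 max pool]
with channel doubling from `base_channels = 32`, giving an input-to-
bottleneck downsampling factor of 16. The bottlenecks are fused by channel
concatenation and flattened into a token sequence of length
`H·W / (2^stages)² = H·W/256` at the defaults (1024 tokens at 512×512); a
learnable position embedding (truncated normal, sd 0.02, clipped at 2 sd) is
added, then `depth = 8` transformer layers with `heads = 8` multi-head
self-attention and a 4× MLP are applied. The default layer uses pre-layer-
normalisation for trainability; `pre_norm=False` gives the strict residual
composition `y = MSA(x); out = y + MLP(y)` used in oracle tests. Output
tokens are reshaped to a feature map and decoded by a skip-connected
upsampling CNN (nearest-neighbour ×2 + conv block per level, skips from the
image encoder) into 7 class scores per pixel, with auxiliary 1×1 score
heads at the intermediate resolutions for deep supervision.

Reference numpy oracles `self_attention` (Eq. `x + softmax(xW_q(xW_k)ᵀ/√d)
xW_v`) and `msa` (concatenated heads projected by `W_o`, one residual)
define the attention semantics; the trainable modules are tested against
them.

**Ablation ladder** (one config axis, `mode`): `unet` (single encoder, no
transformer) ⊂ `multi_unet` (two image-fed encoders) ⊂
`multi_unet_transformer` (plus transformer) ⊂ `vst` (second encoder fed the
saliency map). The last two have exactly equal parameter counts, so the
vst-vs-multi_unet_transformer contrast isolates the saliency input from
capacity.

**Initialisation.** Kaiming-normal weights, zero biases; the main and
auxiliary score heads are zero-initialised so that the initial prediction is
exactly uniform over classes (initial cross entropy = ln 7). Without this
the randomly initialised heads put large mass on arbitrary classes and
early training collapses onto the background majority class.

**Numerics.** All network arithmetic is float32 on a small in-package
reverse-mode autograd engine (`vstseg.nn`) written on numpy: convolution is
evaluated as nine shifted BLAS mat-muls (one per 3×3 tap), and every op's
gradient is verified against central finite differences in float64.

## 5. Training (`vstseg.training`)

Loss: `L_total = L_dice + L_CE`, where `L_dice` is soft Dice averaged over
the six foreground classes with the *linear* denominator
`(2Σp·g + ε) / (Σp + Σg + ε)`, ε = 1e−5, and `L_CE` is mean per-pixel
negative log-likelihood. With deep supervision the auxiliary outputs
contribute `w_i · (dice + CE)` against nearest-neighbour-downsampled labels
with weights (0.5, 0.25, 0.125). The logged decomposition satisfies
`l_total = l_dice + l_ce + Σ w_i l_aux,i` exactly at every step.

Optimiser: Adam with β₁ = the configured momentum coefficient and
β₂ = 0.999. The reference schedule is lr 0.01, momentum 0.1, batch 12,
1000 epochs × 250 iterations; desk-scale runs (tests, acceptance script)
keep the momentum coefficient but lower the learning rate to 3e-3 and run a
few hundred steps on a tiny architecture (stages 3, base 8, depth 2,
heads 2, 64×64 inputs), because lr 0.01 is too hot for that configuration
to converge within hundreds of steps.
Images are min–max normalised per slice; saliency maps likewise. Training
is deterministic given the seed and raises on non-finite loss.

Cross-validation: `run_crossval` implements k-fold splits (random
permutation cut into k near-equal folds; 80/20 at k = 5) repeated with
different permutations and averaged, recording per-fold validation DSC and
the fold assignments.

## 6. Evaluation (`vstseg.evaluation`)

* **DSC** `2|A∩B|/(|A|+|B|)`; conventions: 1.0 when both sets are empty,
  0.0 when exactly one is.
* **Hausdorff distance** between boundary voxel sets in mm, computed from
  Euclidean distance transforms with the physical spacing; boundaries are
  erosion differences under face connectivity; the classical maximum is the
  default, a percentile variant (e.g. HD95) is available. Undefined (raises
  / reported as None) when a mask lacks the label.
* **Volume** voxel count × voxel volume / 1000 (ml).
* **Paired statistics** on per-structure volume differences: Shapiro–Wilk
  at α = 0.05 gates between the paired t-test (normality not rejected) and
  the Wilcoxon signed-rank test. A constant nonzero difference (normality
  test undefined) goes to the Wilcoxon branch; identical vectors raise.
  Summaries report min/max, median and median-inclusive (type-2) quartiles.
  At least 6 pairs are required.

## 7. Limitations

* Phantoms are analytic shapes with piecewise-constant intensities; results
  on them measure implementation correctness and learnability, not clinical
  performance. No claim about real CT accuracy is made or testable here.
* The autograd engine is single-threaded numpy/BLAS; the reference-scale
  network (512×512, 8 layers, 250k steps) is far beyond desk runtime, so
  tests and the acceptance script run reduced configurations. The
  architecture laws (token counts, parameter-count equalities) are checked
  at full scale analytically and at reduced scale by execution.
* The fast global-saliency path is an approximation (downsample → exact →
  upsample); exactness is only guaranteed (and tested) for images up to 64
  per side or with `exact=True`.
* The desk-scale ablation contrast (saliency input at matched capacity) is
  a direction check on small noisy datasets, not an effect-size estimate.
* PNG image I/O quantises intensities to uint16 at 10⁴ counts per unit
  (round-to-nearest, max error 5e-5); NIfTI round trips are exact.
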