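# Methods

`rms` simulates a full respiratory cycle from a single end-of-inhale (EOI)
chest projection image. This note records the model, the synthetic cohort it
is trained and validated on, the numerical choices, and what the packaged
experiments do and do not demonstrate.

## Model

The predictor is an encoder–recurrent–decoder network with a differentiable
resampler:

1. **Encoder.** Four down-sampling blocks (two 3×3 convolutions + ReLU, then
   2×2 max pooling), feature channels doubling per level from
   `base_channels`. The bottleneck is flattened through a fully connected
   layer into a 1×512 latent vector `x0`. We use size-preserving ("same")
   convolutions: with unpadded convolutions the power-of-two size arithmetic
   needed for symmetric skip connections and the fixed-size flatten layer
   breaks down, so padding is the only self-consistent reading of the
   architecture.
2. **One-to-many rollout.** A two-layer LSTM (hidden size = latent size,
   zero-initialised states, forget-gate bias 1) consumes `x_{t-1}` and emits
   `x_t` autoregressively for t = 1…9, producing one latent per remaining
   phase of the 10-phase cycle.
3. **Decoder.** A symmetric expanding path (nearest-neighbour ×2 upsampling,
   skip concatenation from the corresponding encoder level, two 3×3
   convolutions). The skip features are computed once, from the EOI image,
   and reused for all nine decodes — only p0 is ever encoded. The two-channel
   output is bounded by `tanh × max_disp` (default 0.25·H pixels); the final
   convolution is zero-initialised so training starts from the identity
   deformation.
4. **Spatial transformer.** Each predicted displacement vector field (DVF)
   backward-warps p0 with bilinear interpolation:
   `p̂_t(i,j) = p0(i + u_y(i,j), j + u_x(i,j))`, border-clamped and
   differentiable in both the image and the field. Masks are warped with
   nearest-neighbour sampling so labels survive.

Displacements are stored in pixels (channel 0 = columns, channel 1 = rows),
backward-warping; physical lengths use the pixel spacing in mm.

### Training objective

`L = w_s·L_smooth + w_m·L_MSE − w_n·L_NCC` over the nine predicted phases:

* `L_smooth` — forward-difference gradient penalty of the DVFs, summed over
  phases and divided by 2N (N = pixels per field).
* `L_MSE` — per-pixel mean squared intensity error, summed over phases. The
  per-pixel mean keeps weights resolution-independent; the weight `w_m`
  absorbs the scale (a bare pixel sum at H=W=32 corresponds to
  `w_m ≈ 1000`).
* `L_NCC` — squared local normalized cross-correlation (default 9×9 window,
  ε = 1e-5, exact border window counts), averaged over pixels and phases. It
  is a similarity in [0, 1], so the objective *subtracts* it; adding it, read
  literally, would reward decorrelation.

Defaults: Adam, learning rate 1e-3, batch 4, 90 epochs, weights
`(w_s, w_m, w_n) = (0.05, 30, 1)`. These are desk-scale choices sized for a
single CPU core: the loss-weight ratio restores MSE dominance comparable to
a pixel-summed formulation while leaving the smoothness term strong enough
to keep fields C¹-plausible, and 90 epochs is past the loss plateau of the
default cohort. The held-out test split doubles as the validation set for
best-checkpoint selection (the final and best checkpoints are both written;
they coincide once the loss has plateaued).

### Resolutions

The phantom cohort is written at 64×64 (4 mm/pixel); the network trains at
32×32 (block-mean downsampled inputs). For evaluation the predicted fields
are bilinearly upsampled back to 64×64 with displacements rescaled ×2, so
Dice and diaphragm metrics are measured at data resolution. A coarse motion
model applied at full resolution is standard registration practice and keeps
the full training run around five minutes on one core.

## Synthetic phantom cohort

No public 4D sequence ships with the package; a seeded generator emulates
cropped sequential chest DRRs:

* **Anatomy.** Two half-elliptical lungs (dark, with smooth Gaussian-field
  texture standing in for vascular markings) on a bright soft-tissue
  background with a brighter spine band; a convex diaphragm border; optional
  bright nodule discs. Shapes are jittered per case; edges are anti-aliased
  by 4× supersampled coverage.
* **Cycle.** Phase t of the 10-phase cycle scales a fixed smooth per-case
  displacement basis by `A · sin²(πt/10)`: zero at EOI (p0), maximal at
  mid-cycle (end-of-exhale), returning toward inhale by p9. The vertical
  profile rises smoothly from `apex_motion_fraction` (default 0.1) at the
  apex to 1 at the diaphragm dome and decays below it with slopes < 1/pixel,
  keeping the field invertible at all allowed amplitudes; a small lateral
  inward squeeze (15% of vertical) completes the 2D field.
* **Amplitude.** The cohort-mean diaphragm excursion is 28 mm — within the
  1.5–4 cm range reported for deep-breathing 4D acquisitions, and calibrated
  once so that the default end-exhale overlap Dice(mask₀, mask₅) ≈ 0.88
  (band 0.85–0.95): motion a static predictor cannot shrug off. Per case the
  amplitude scales with the sampled lung height (taller lungs excurse more),
  so the EOI image genuinely carries motion information — the premise of the
  method — plus a 5% residual jitter that is *not* visible in the image and
  therefore sets an irreducible error floor.
* **Phases.** Phase images are exact backward warps of the EOI render (plus
  σ = 0.002 sensor noise per phase); phase masks are nearest-neighbour warps
  of the labeled EOI mask. Ground truth DVFs, images and masks are therefore
  mutually consistent by construction.
* **3D mode** renders small HU-valued volumes (air −1000, lung −800 ± 30,
  soft tissue 0, bone +400) with the same analytic diaphragm motion, feeding
  the preprocessing path.

Everything is a pure function of `(spec, seed)`; dataset builds write a JSON
manifest with per-case seeds and a spec hash, and rebuilds are byte-identical.

### What the phantom does *not* model

Rib cage and cardiac shadows, scatter and beam hardening, perspective
magnification differences across phases, hysteresis between inhale and
exhale limbs, irregular breathing, and pathology-driven motion asymmetry.
Passing the packaged experiments shows the pipeline learns smooth
anatomy-conditioned motion from a single projection under these idealised
conditions; it does not certify clinical accuracy on real radiographs.

## Preprocessing path

For volumetric input (NIfTI/DICOM or the 3D phantom): threshold segmentation
at −400 HU (lung parenchyma vs soft tissue in standard HU) with
border-connected air removed and the two largest components labeled
left/right; beam's-eye-view ray casting of the lungs-only attenuation
(affine HU map clamped at zero) — parallel AP beam by default, with an
optional perspective point-source mode; one bounding box per case (union of
the projected masks over all ten phases, so inter-phase pixel
correspondence survives the crop); corner-aligned bilinear resize; min–max
normalisation with one intensity range per case (inter-phase intensity
changes are signal, not nuisance).

## Evaluation suite

* **Dice** between predicted and ground-truth whole-lung masks, per phase;
  predicted masks are the EOI mask warped by the predicted field (the
  predictions are deformations of p0 by construction, so mask warping is
  exact with respect to the model output).
* **Diaphragmatic position**: apex-to-dome length per lung, in mm. The dome
  detector takes the most superior point of the per-column inferior
  boundary within the central 60% of the lung's column span, avoiding
  costophrenic angles and the mediastinal border. Signed errors
  (predicted − true) are aggregated per phase (mean ± std); absolute errors
  feed the pooled median.
* **Ventilation maps** `v = det J − 1` from central-difference Jacobians of
  the predicted fields (one-sided at borders). Under the backward-warp
  convention det J > 1 marks local contraction of content at exhale.

## Numerical and engineering choices

* The network runs on a compact reverse-mode autodiff engine written on
  numpy (float32), keeping the package dependency-light and CPU-only; every
  operator is validated against central finite differences, and the warper,
  Jacobian, ray caster and losses additionally against brute-force oracles.
* Determinism: parameter init, batch shuffling, and the generator all derive
  from explicit seeds; two identical runs produce identical checkpoints.
  Checkpoints embed architecture metadata and an architecture hash, the
  optimizer state and the shuffling RNG state, so a resumed run reproduces
  an uninterrupted one to float tolerance.
* Degenerate inputs: constant images normalise to zero; warped masks that
  shed sub-1% speckles are cleaned, while losing a major lung component
  raises; empty masks, degenerate boxes and non-finite fields raise.
* Open reading fixed here: the architecture names ten DVFs for nine
  predicted phases; we emit nine fields (t = 1…9), the identity field for
  p0 being implicit.

## Problem sizes

Packaged experiments use the 40 train / 20 test cohort at 64×64 with 32×32
training (≈5 min on one CPU core), a 200-epoch single-case memorisation
check (≈40 s), and 16×16 oracle fixtures (seconds).
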