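# Methods

`cxct` corrects scatter artifacts in cone-beam CT (CBCT) slices by training
a small convolutional network G against a *contextual* (CX) objective that
tolerates the few-pixel residual misalignment left after deformable
registration of the planning CT onto the CBCT.  This note records the model,
the numerical choices, what the synthetic data do and do not emulate, and
the design decisions taken where the design was genuinely open.

## The contextual similarity and loss

Given two images, each is represented as a set of deep feature vectors
(one per spatial position of a chosen convolutional layer),
S = {s_i} and T = {t_j}.  The chain is:

1. **Target-centered cosine distances.**
   d_ij = 1 − ⟨s_i − μ_t, t_j − μ_t⟩ / (‖s_i − μ_t‖ ‖t_j − μ_t‖), with
   μ_t the mean of the *target* features only.
2. **Per-row scale normalisation.**  d̃_ij = d_ij / (min_k d_ik + ε),
   ε = 1e-5.  Each source feature is judged relative to its own best
   match, which is what makes the similarity scale-invariant.
3. **Affinities.**  w_ij = exp((1 − d̃_ij)/h), bandwidth h = 0.5.
4. **Row normalisation.**  CX_ij = w_ij / Σ_k w_ik, so each row of the CX
   matrix is a distribution over target features.
5. **Global similarity.**  CX(S,T) = (1/N_t) Σ_j max_i CX_ij — every
   target feature contributes its best source match; identical sets give
   1, uniformly dissimilar N×N sets give exactly 1/N.
6. **Loss.**  L_CX = −log CX(S,T).

The training objective combines a *content* term that anchors the output
to the CBCT input s and a *style* term that pulls intensities toward the
planning-CT label t:

L(G) = L_CX(G(s), s, conv4_2) + λ · Σ_{l ∈ {conv2_2, conv3_2, conv4_2}} L_CX(G(s), t, l),

with λ = 5.  Style feature sets larger than 6400 (80×80) vectors are
subsampled once per run with a seeded uniform draw, applied to identical
positions on both sides of each comparison.  Comparison baselines are the
Euclidean pixel loss ‖x − y‖₂ and the perceptual loss
‖φ_l(x) − φ_l(y)‖₁ at conv4_2.

### Numerical choices

- **Zero-norm guard.** The norm of a centered feature is floored at ε.
  A floor (rather than adding ε) keeps the CX matrix exactly invariant
  under joint rescaling of S and T, and only ever acts at exactly zero
  norm.  If *both* members of a pair are zero after centering they are
  identical and their distance is defined as 0; a zero-vs-nonzero pair
  gets cosine 0 (distance 1).
- **Overflow.** d̃ can reach ~1/ε, so (1 − d̃)/h is shifted by its row
  maximum before exponentiation; the shift cancels in the row
  normalisation.
- **Loss floor.** The global similarity is clamped at 1e-12 before −log,
  so totally dissimilar sets give a large finite loss.
- **Orientation.** Rows index the first argument (S), columns the second
  (T); the global similarity takes column-wise maxima and averages over
  target features.
- **One known degeneracy.** In feature dimension 1 all centered features
  are collinear, so cosine similarity cannot separate distinct scalars
  and CX(S,S) < 1 is possible; self-similarity = 1 requires pairwise
  distinct feature *directions* (D ≥ 2 in practice).

## Feature extraction

Features come from a frozen VGG-19-topology network (blocks of 2/2/4/4/4
3×3 convolutions with 64/128/256/512/512 channels, ReLU, 2×2 max pooling
between blocks; the fully connected head is never materialised).  HU
images are affinely windowed from [−1000, 1500] HU to [0, 1] — the window
is a package choice, wide enough to keep air-to-cortical-bone contrast
linear — and replicated to three channels.

Two backends share this topology and expose identical layer names and
shapes:

- **pretrained** — loads VGG-19 convolution weights from a local `.npz`
  file.  No network access is ever attempted; ImageNet weights are a
  pluggable input, not a dependency.
- **surrogate** (default) — fixed, seeded random weights, so the entire
  package builds, trains and tests deterministically with no weight file.
  Each kernel is a convex mix (`lowpass_mix`, default 0.5) of a random
  local-average component (a random channel-mixing coefficient spread
  uniformly over the 3×3 support) and white Gaussian noise, rescaled to
  the He gain.  The low-pass component matters: with pure white-noise
  kernels the deep features are texture-noise dominated, and prolonged
  optimisation of a feature-matching loss then decouples from pixel
  fidelity (the CX loss keeps falling while held-out MAE rises).  Mixing
  in local averaging gives features the local-intensity content that
  trained filters possess, and restores the alignment between the CX
  objective and image quality that the method relies on.

Random features are a stand-in for semantics: they preserve the loss
geometry (self-similarity, misalignment tolerance, the relative ordering
of losses) but not ImageNet-level semantic matching, so absolute
corrected-image quality with the surrogate understates what the
pretrained extractor would give.

## The correction network

The published description — five layers, 3×3 kernels, stride 2, ReLU,
channel width 512 for input sides ≥ 128 else 1024, spatial size halved
until it reaches 4 — underdetermines a shape-preserving network: a pure
stride-2 stack cannot return the input resolution.  We implement a
symmetric encoder–decoder:

- encoder: stride-2 3×3 convolutions + ReLU until the spatial side
  reaches `min_spatial` (4) or the layer budget is exhausted; remaining
  layers become stride-1 bottleneck convolutions (so the 17-layer ablation
  variant is expressible);
- decoder: mirrored nearest-neighbour 2× upsampling + 3×3 convolution +
  ReLU stages;
- a final linear 3×3 projection, near-zero initialised, whose output is
  **added to the input** (residual mode, default).  Residual output makes
  the initial mapping the identity and anchors the body contour to the
  input — the property that matters for treatment-position fidelity.

"Width" in the published description is read as channel width for the
adaptive 512/1024 rule and as spatial width for the "halve until 4" rule;
both readings are noted because the source text conflates them.

Training: Adam, learning rate 1e-4, batch size 1 (unstated in the source
recipe; chosen minimal), seeded shuffling, 300 epochs at full scale.
Source and label features are extracted once before the loop (they never
change), so each step costs one extractor forward/backward on G(s) only.
A non-finite loss aborts with the offending term named.  A
`single_image` mode optimises the output pixels of one pair directly by
the same objective, matching the iterative-optimisation reading of the
training description.

**Checkpoint selection.**  When a validation set is supplied, the
returned model is the epoch with the lowest validation MAE (ordinary
early stopping; `select_best_val`).  This matters in the weakly aligned
regime: every loss is optimised against *misaligned* labels, so its
exact optimum is not the clean anatomy, and prolonged optimisation
eventually trades pixel fidelity for loss value.  Empirically all three
losses reach their best held-out MAE within a few epochs on the phantom
task; the CX objective degrades far more slowly afterwards than L2 or
perceptual — the same robustness ordering the method is built on.  This
is also why the study design holds out a validation split.

All gradients flow through a small in-repo reverse-mode autodiff over
numpy arrays (`_autodiff.py`) whose primitives (elementwise ops,
reductions, matmul, 3×3 convolution via im2col/GEMM, 2×2 max pooling,
nearest upsampling) are verified against central finite differences.

## Synthetic phantom data

Each example is a triplet that emulates the clinical training situation:

- **clean truth** — an elliptical soft-tissue body (+40 HU) with a skin
  rim (−140 HU), two symmetric cortical-bone ellipses (+700 HU) with
  marrow cores (+232 HU) and an optional air cavity (−1000 HU); skin and
  marrow defaults follow published pelvic ROI means, the others are
  standard CT values.  Geometry is jittered per slice.
- **input (CBCT stand-in)** — the clean slice plus, inside the body only:
  a radial cupping bias −A(1 − (r/R)²) (centre depressed by exactly
  A = 80 HU), 6 oriented streaks of alternating sign (amplitude 60 HU,
  Gaussian cross-profile, width 1.5 px) and Gaussian noise (σ = 15 HU).
  Over the body this yields ~50 HU MAE, comparable to clinical CBCT
  error levels.
- **label (registered-CT stand-in)** — the clean slice warped by a smooth
  displacement field, bilinearly interpolated from a coarse seeded grid,
  each component bounded by `max_displacement` (default 4 px).  The warp is
  applied to the *label*, matching the convention that the CBCT is static
  and the CT moves during registration.

Deliberately not modelled: projection-domain scatter physics (Monte
Carlo), cone-beam geometry, beam hardening, anatomy beyond the phantom's
five tissue classes.  Consequently, passing tests demonstrate the
mathematics, the training dynamics and the misalignment-robustness
*directions* (CX vs pixel/feature baselines), not clinical-grade
correction quality.

Splits default to train/val/test fractions; rotation augmentation expands
the training split only.  Datasets are byte-reproducible from their specs
and master seed.

## Metrics

MAE, PSNR (10·log10((2ⁿ−1)²/MSE), default n = 12 for HU data, n = 8
supported for rescaled images), SSIM with k1 = 0.01, k2 = 0.03 evaluated
globally by default (matching the single-formula definition; a
sliding-window mode defers to scikit-image for comparability), population
standard deviation, and ROI mean CT number (marrow, skin).  All metrics
operate on raw HU, are mask-aware, and aggregate as across-slice means
plus the population std of per-slice MAE.

## Desk-scale study conditions

The bundled experiments run on one CPU at desk scale: 64×64 slices, 40
training / 8 validation / 8 test pairs, 30 epochs, generator channel
width 32, surrogate extractor.  These sizes are the package's default
experimental conditions; the full-scale values (512×512, width 512/1024,
300 epochs, pretrained extractor) remain available through configuration.
At 64×64 the conv2_2/conv3_2/conv4_2 feature sets hold 1024/256/64
vectors, all below the 6400 style-sampling cap, so sampling is a no-op at
desk scale and becomes active at full scale.

## Known limitations

- The surrogate extractor preserves orderings and directions, not
  absolute quality; corrected-image quality at desk scale is bounded by
  random-feature matching.
- Global-statistics SSIM saturates near 1 for images agreeing in mean and
  variance; use the sliding mode for structure-sensitive comparisons.
- The L2 comparison loss is the plain Euclidean norm of the difference
  (a normalised root-mean-square variant is available behind a flag).
- PSNR of identical images is an error by definition; the evaluation
  aggregator records it as infinity.
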