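# Methods

## The grading problem

Apples are graded premium / middle / poor (codes 0/1/2) from RGB
photographs in which the background is deliberately similar in hue and
texture to the fruit surface. The grades are visually ordered: higher
grades carry more, larger and darker surface defects. Two graders are
implemented over the same data pipeline — a compact CNN and a classical
GLCM+HOG+SVM baseline — and compared with confusion-matrix accuracy
`A = N_T / N_V × 100%`.

## Synthetic data generator

Real graded-apple photo sets are not redistributable, so `synthgen`
renders parametric stand-ins. Each image is an elliptical fruit (semi-axes
~0.36 of the frame, radially shaded with a per-fruit light tilt) over a
background whose colour is a blend between the fruit colour and a dull
green-grey, controlled by `background_similarity` (default 0.8 — clutter
similar to the fruit, the condition the pipeline is designed for), plus a
smooth low-frequency texture field. Defects are soft-edged dark ellipses
drawn inside the fruit.

Per-grade defect parameters (defaults):

| grade   | count range | total area fraction of fruit | centre contrast |
|---------|-------------|------------------------------|-----------------|
| premium | 0–1         | 0.001–0.008                  | 0.30            |
| middle  | 2–4         | 0.02–0.06                    | 0.45            |
| poor    | 5–9         | 0.08–0.18                    | 0.60            |

The intervals are strictly ordered in expectation, which is the property
the graders exploit; `validate()` enforces it. The contrast is the
fraction of brightness removed at a defect centre. These are modelling
choices for a plausible ordinal grading rubric, not measurements of real
fruit.

Determinism uses a splittable seeding scheme: each fruit draws from
`SeedSequence([config_seed, 7, fruit_seed])`, each view from
`SeedSequence([config_seed, 11, fruit_seed, view_id])`, so adding fruits
never perturbs existing ones and identical inputs give bit-identical
rasters. Views share one defect layout; a view rotates the layout about
the fruit centre by `view_id · 360°/views_per_fruit` and jitters the fruit
position, emulating re-photographing the same apple.

The default working resolution is 780×1040 (a quarter of 3120×4160
full-frame captures, which `downscale_quarter` produces by 4×4 block
averaging); tests and smoke runs generate directly at 208×208 or 64×64.

What the generator does **not** model: specular highlights, stem/calyx
structure, defect taxonomy (bruise vs rot vs insect damage), shadows,
occlusion, or photometric camera effects. Passing smoke tests therefore
demonstrate that the pipeline learns an ordered defect statistic under
clutter — not field performance on real fruit.

## Augmentation recipe

Each original yields exactly ten derived sub-images: salt-and-pepper
(density 0.3), Gaussian noise, horizontal flip, brightness gain 1.5,
darkness gain 0.9, and rotations at 60°, 120°, 180°, 240°, 300°. The
originals themselves are excluded from the augmented pool — the 10×
cardinality (3,600 → 36,000) forces this reading. Choices within the
recipe:

* The brightness/darkness "percentages" are multiplicative gains.
* Salt-and-pepper corrupts exactly `round(d·H·W)` distinct locations
  (sampled without replacement, each set to 0 or 255 across all channels
  with equal probability) rather than per-pixel Bernoulli — the corrupted
  fraction is exact and testable, and the visual effect is identical.
* The Gaussian-noise σ is not pinned down by the recipe; the default is
  σ = 10 on the 0–255 scale — visible but non-destructive — and is
  configurable.
* Rotations use bilinear interpolation on a same-size canvas with black
  corner fill; 180° is an exact index reversal.
* The train/validation split (80/20, `|train| = round(0.8·N)`) is done on
  the **post**-augmentation pool, which places augmented siblings of one
  fruit on both sides. This replicates the reference protocol;
  `split_by_fruit` provides the leakage-free alternative.

## CNN grader

Architecture (input 208×208×3): Conv1 5×5×8 → pool, Conv2 3×3×16 → pool,
Conv3 1×1×32 (no pool — the 1×1 layer mixes correlated features across
channels at one location), Conv4–6 3×3×64 → pool each, Fc1 256, Fc2 256,
softmax 3. Convolutions are stride-1 SAME; activations are ReLU
(configurable in principle; the reference accounting is
activation-agnostic).

**Pooling arithmetic.** The published per-layer accounting this package
reproduces (Conv2 1,168; Conv4 18,496; Fc1 590,080; Fc2 65,792) is only
consistent if every 3×3/stride-2 pool maps n → ⌊n/2⌋, giving the chain
208 → 104 → 52 → 26 → 13 → 6 and a 6·6·64 = 2,304-wide rasterized vector
(590,080 = 2,304·256 + 256). Neither ceil-SAME (→7) nor VALID (→5)
pooling produces that chain, so the pool operator pads the bottom/right
edge with −∞ exactly as needed for ⌊n/2⌋ windows. Two printed counts are
knowingly not reproduced: a 1-channel Conv1 count (208) contradicts the
RGB input (this package counts 5·5·3·8+8 = 608), and the printed Conv3/5/6
entries disagree with the formula every other row obeys (expected 544 /
36,928 / 36,928); both are treated as typographical.

**Training.** Mean cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8); reference defaults: learning rate 1e-4, batch 20, 3,001 steps,
inputs scaled to [0, 1]. Batches are drawn without replacement per step
from a seeded generator; training is bit-reproducible for a fixed seed and
thread count (pure NumPy; BLAS reductions are deterministic per build).
`stop_above_train_acc` optionally stops once the running mean of the last
20 batch accuracies passes a threshold. Divergence (non-finite loss)
raises with the step index.

**Gradient verification.** The backward pass (softmax/cross-entropy head,
full connections, max-pool error routing to the argmax, and the
convolution adjoint — SAME correlation with the 180°-rotated,
channel-transposed kernel) is checked against central finite differences
(ε = 1e-5) on tiny architectures; observed maximum relative deviation is
~1e-8, asserted < 1e-4. Prediction ties break toward the lowest class
index.

Checkpoints are single-file `.npz` archives embedding the architecture and
a format version; save → load → forward is bit-identical.

## Classical grader

Weighted-mean grayscale uses BT.601 luminance (0.299/0.587/0.114). The
bilateral filter is implemented directly: within an odd window of the
configured diameter (90 → 91), each neighbour is weighted by
`exp(−d²/2σ_s²)·exp(−ΔI²/2σ_c²)` with per-pixel renormalization and
replicate borders. (The scikit-image implementation was evaluated and
rejected: its spatial grid `arange(-w//2, w//2+1)` is asymmetric for odd
windows and its default zero padding darkens edges; both fail the
definitional double-loop oracle.)

GLCM: gray values are uniformly binned to 64 levels; co-occurrence counts
at distance 1 for angles {0°, 45°, 90°, 135°} (offset
`(round(d·sin a), round(d·cos a))`, counted in both directions, normalized
— computed via `skimage.feature.graycomatrix`). Four Haralick statistics
are computed in-package: ASM = ΣP², Ent = −Σ P ln P (nats),
Con = Σ(i−j)²P, and Cor with marginal means/SDs, defined as 0 for
degenerate marginals. Their mean and population variance over the angle
set give the 8-value texture block. Distance, angles and level count are
conventions, not pinned by the reference recipe.

HOG: √-gamma compression, [−1,0,1] centred differences with replicate
borders, unsigned orientations in [0°, 180°), magnitude-weighted cell
histograms with linear interpolation between adjacent bins, blocks of 4×4
cells L2-normalized as `v/√(‖v‖² + ε²)` (ε = 1e-5), concatenated at
1-cell stride. Cell size 8 px and 9 bins are the canonical defaults; only
the 4×4 cells/block geometry is fixed by the reference recipe.

Merged vectors (GLCM block first, then HOG) are standardized with
statistics fitted on training data only, then classified by an RBF SVM
(C = 1, γ = 'scale', one-vs-one multiclass via scikit-learn).

## Evaluation

Confusion matrices are tallied with rows = actual, columns = predicted,
classes ordered (premium, middle, poor). Accuracy is reported in percent
rounded half-up to 2 decimals. Multi-view aggregation sums the per-view
softmax probability vectors (probabilities, not logits — scores on a
common [0, 1] scale) and takes the argmax, ties toward the lowest class.

## Problem sizes and numerical choices in the test suite

* The convergence smoke tests run at 64×64 input — the smallest size the
  five-pool architecture admits (64 → 2) — with 200 images/class for
  training, the high-contrast generator condition
  (`high_contrast_config`: contrasts 0.35/0.60/0.85), learning rate 1e-3
  and early stop at 0.97 running accuracy; both graders clear 90% well
  within 500 steps (typically ~60 for the CNN).
* The full-scale augmentation cardinality check (3,600 → 36,000 →
  28,800/7,200) runs at 208×208 working resolution, streaming one
  original at a time to bound memory.
* Gradient checks use networks ≤ 1,000 parameters, ε = 1e-5, relative
  deviation `|a−n| / max(|a|+|n|, 1e-8)`.
* The CLI surface exposes the stages as
  `pomgrade synth|augment|split|train-cnn|train-classical|eval|pipeline`
  with one YAML config and a single global seed; re-running a config
  reproduces manifests, curves, reports and checkpoints byte-identically.

## Known limitations

* The generator's grade rubric is an assumed ordinal defect model; no
  claim is made about real grading criteria beyond the ordering.
* The CNN is CPU-only NumPy; at the 208×208 reference size a full
  3,001-step run is feasible but slow (hours, not minutes).
* Headline accuracies reported for the original private-data study
  (99% / 98.98% / 95.33%) are not reproducible here and are not targets;
  the printed confusion matrices are used only as arithmetic inputs.
* The post-augmentation split leaks augmented siblings between train and
  validation by construction; use `split_by_fruit` for honest
  generalization estimates.
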