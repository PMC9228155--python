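# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of `cascadefis`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## 1. The Takagi–Sugeno ANFIS unit

The atomic model is a first-order Takagi–Sugeno fuzzy system over `k`
inputs (canonically `k = 2`). Each input `x_i` carries `m` triangular
fuzzy sets

```
mu(x; a, b, c) = max( min( (x-a)/(b-a), (c-x)/(c-b) ), 0 ),   a <= b <= c
```

and the grid partition forms one rule per membership combination
(`n = m^k` rules). For an input vector `x`:

```
w_j    = prod_i mu_{j,i}(x_i)              (rule firing strength)
wbar_j = w_j / sum_i w_i                   (normalisation)
y      = sum_j wbar_j (p_j . x + r_j)      (weighted linear consequents)
```

Degenerate triangles (`a = b` or `b = c`) evaluate the collapsed ramp as 1
at the shared point — the limit of the ramp as its width shrinks — so a
zero-width fuzzy set still fires at its peak instead of producing 0/0.

**Initialisation.** `m` triangles per input with peaks on a uniform grid
over the observed `[min, max]` and feet on the neighbouring grid nodes
(half-overlap). The outermost feet extend one grid step beyond the range so
every in-range value keeps positive total firing. A zero-variance input is
widened to a unit interval around its value.

**Hybrid training.** With premises fixed, the output is linear in the
stacked consequent coefficients, so each epoch solves that least-squares
problem in closed form (ridge default `1e-8`; the overlapping triangular
partition makes the design genuinely rank-deficient at ridge 0, which is
reported as an error rather than silently pseudo-inverted). Between epochs
the premise parameters `(a, b, c)` take one gradient step on the training
RMSE, computed by central finite differences with step `1e-4` of the input
span and learning rate `premise_lr * span` (default `premise_lr = 0.01`),
followed by re-sorting each triple to restore `a <= b <= c`. Finite
differences were chosen over analytic subgradients because the piecewise-
linear membership has kinks exactly where training pushes parameters, and
the models are small enough (tens of parameters) that the cost is
negligible. Default 10 epochs for a standalone unit; 1 epoch per unit
inside the cascade, where the LSE does nearly all the work.

**Zero firing at inference.** Inputs outside every rule's support are
either an error (`on_zero_firing="error"`, default for the functional API)
or clamped into the fitted per-input range and re-evaluated
(`"clamp"`, used throughout the cascade) — clamping selects the nearest
firing region in input space and keeps the predictor total.

## 2. The modified cascade

The classifier consumes `G` feature groups (default 7 groups of 9 reduced
components). Wiring:

* **Level 1** — one module per group. A group's 9 features are digested by
  an internal chain of eight 2-input units (`f1,f2 -> u1`; `u1,f3 -> u2`;
  …), keeping every unit in the canonical 2-input rule form, bounding the
  rule count (4 rules/unit at `m = 2` instead of `2^9` for one 9-ary
  unit), and feeding each unit with the previous unit's output. A true
  k-ary group unit is available (`kary_groups=True`) for experimentation.
* **Levels 2..G** — a single 2-input combiner per level fusing the previous
  level's scalar with the next group module's output, giving exactly `G`
  levels for `G` groups. A binary reduction tree would be an alternative
  reading of the same level count; the sequential chain is implemented
  because it matches "each module consumes the previous output" most
  directly.

Every unit is trained against the encoded class target. A **passthrough
guard** replaces any chain unit or combiner whose training RMSE exceeds
that of its first input by an identity passthrough, which makes the
level-wise training RMSE non-increasing by construction and protects the
cascade from a badly conditioned unit late in the chain.

**Pair selection.** The classical cascade scores candidate input pairs by
the training RMSE of a one-epoch 2-input fit and trains the best pair
first. `select_pairs` implements exactly that (single LSE pass as the
score, ties broken lexicographically); the group chains use the natural
feature order by default (`pair_selection=False`) because on reduced
ICA components no ordering is privileged, and the fixed order keeps the
wiring identical across one-vs-rest sub-models.

**Label codec.** Classes are sorted and mapped to `0..l-1`.

* `one-vs-rest` (default): one scalar cascade per class trained on the
  class indicator, predictions by argmax of the class scores.
* `index-regression`: a single cascade regresses the class index; decoding
  rounds to the nearest integer and clamps to `[0, l-1]`.

Index regression imposes a total order on what is an unordered label set:
classes that land next to each other on the index axis need the regressor
to resolve a step of exactly 1.0 between them. On the reference synthetic
experiment (8 classes × 100 images) it reaches 0.94 test accuracy while
one-vs-rest reaches 1.00 at 8× the (sub-second) training cost, so
one-vs-rest is the default; both codecs are first-class and tested.

## 3. Feature descriptors

Nine descriptors; lengths at the default configuration:

| descriptor | length | notes |
|---|---|---|
| colour structure (CS) | 64 | HSV 16×2×2 quantisation, 8×8 structuring window, presence counts, sum-1 normalised |
| region shape (RS) | 10 | 7 signed-log Hu moments + eccentricity + solidity + normalised area of the largest Otsu foreground component |
| edge histogram (EH) | 80 | 4×4 sub-images × 5 directional classes, 2×2-block filters, no-edge threshold 11 (the conventional reference value) |
| colour layout (CL) | 12 | YCbCr 8×8 block means → orthonormal 2-D DCT → zigzag 6+3+3 |
| GLCM | 20 | 8 grey levels, distance 1, angles 0/45/90/135, {contrast, correlation, energy, homogeneity, entropy} |
| HOG | 2916 | 10-px cells, 2×2 blocks, 9 orientations, L2-Hys |
| SIFT pooled | 256 | mean+std over keypoints of 128-dim descriptors |
| SURF slot | 128 | **stand-in**: two-scale ORB, 256 bits → 64 4-bit group means, pooled mean+std |
| ORB pooled | 64 | 256-bit descriptors packed to 32 bytes, pooled mean+std |

Greyscale is ITU-R BT.601 luma. Keypoint pooling is per-dimension mean and
standard deviation — training-free and deterministic, unlike a
bag-of-visual-words codebook. An image with no detectable keypoints yields
the zero vector of the correct length. The environment has no true SURF
implementation (it is patent-encumbered and absent from scikit-image), so
the SURF slot is filled by the multi-scale ORB variant above; it plays the
same role — a fast binary keypoint descriptor at a second scale — and the
slot keeps its name so the nine-descriptor grouping is unchanged.

The nine descriptors map onto **seven groups** — six image-level
descriptors get one group each and the three keypoint descriptors share
one — the only assignment that reconciles nine descriptors with seven
per-group reduction blocks. The assignment is configurable (`group_map`).

"Column layout" in the descriptor-set tradition this package follows is
read as the MPEG-7 Colour Layout descriptor; a literal per-column-mean
variant is available (`color_layout_variant="column-mean"`).

## 4. Per-group reduction

Each group is reduced independently to 9 components (7 × 9 = 63 total).
The default is FastICA (whitening, log-cosh contrast, max 500 iterations,
tolerance 1e-4, fixed seed); PCA is the deterministic alternative.  Both
are stored as affine maps (centering vector + linear map), serialise to
JSON, and transform out-of-sample data exactly; the stored map is kept
C-contiguous so a round-tripped reducer reproduces transforms bit-exactly
(BLAS results depend on memory layout).

FastICA's fixed-point iteration can diverge on a group whose whitened
spectrum is nearly degenerate (small sample counts make this likely); a
group whose empirical rank falls below the component count, or whose
unmixing matrix comes back non-finite, falls back to PCA for that group
with a `RuntimeWarning`. The fallback is per-group, deterministic, and
keeps the 63-column contract intact. Metric MDS has no out-of-sample
transform, so it is accepted only by the `compare_methods` harness — which
reports downstream accuracy and wall time per (method, component count) —
and rejected as a pipeline reducer. Wall times are reported, never
asserted: they are hardware-bound.

## 5. Synthetic data

The generator emulates a turntable capture of single fruits: 100×100 RGB
frames, pure white background, one object per frame, the object rotated
across frames, and a per-class `round(0.7 · per_class)` train split with
test frames interleaved across the rotation so both splits cover all poses.

A class is a lobed ellipse — radius `r(θ) = r0 (1 + λ cos νθ)` with
semi-axes 20–30 px, lobedness λ ≤ 0.12, ν ∈ 3..6 — filled with a
class-specific hue (HSV, s = v = 0.85) and an optional stripe or spot
texture, rendered with a 1-px antialiased silhouette, ±5 % size jitter,
per-image hue jitter and σ = 3 pixel noise. Class hues are evenly spaced on
the wheel; the `separability` dial (default 1) widens hue jitter towards
class overlap. Defaults were chosen once to make the default experiment
(8 classes × 100 frames) solvable by colour+shape+texture in the way the
real single-fruit imagery is, and are not revisited.

What the generator does **not** model: real fruit photometry (specular
highlights, shading gradients, surface blemishes), segmentation artefacts
from background removal, class imbalance, and intra-class variety (a real
class mixes cultivars and viewing geometries). Passing the synthetic
experiment therefore demonstrates that the pipeline's machinery — feature
extraction, per-group ICA, cascade training, evaluation — is correct and
end-to-end consistent, not that the descriptor set would reach any
particular accuracy on photographic benchmarks.

## 6. Evaluation

The confusion matrix has true classes on rows. Micro scores pool counts
before forming precision/recall; macro scores average per-class values
unweighted **and build the F-score from the averaged precision and recall**
(the convention of the formula family implemented here — note this differs
from averaging per-class F-scores, which is what scikit-learn's macro-F
does; the test suite cross-checks micro and weighted against scikit-learn
exactly and documents this one deliberate difference). Weighted scores use
true-class supports. Average accuracy is the per-class mean of
`(tp_i + tn_i)/total`; for `l > 2` it exceeds overall accuracy because
every correct prediction is also a true negative for the other `l-1`
classes. Undefined per-class ratios (never-predicted class) contribute a
configurable `zero_division_value` (default 0). `beta` defaults to 1.

Cross-validation is stratified k-fold (default 10), shuffled under the run
seed; the reducer and cascade are refitted inside every fold on that fold's
training portion only — features are extracted once, which is safe because
descriptor extraction is per-image and training-free.

## 7. Problem sizes and determinism

The reference experiment is 8 classes × 100 frames (560 train / 240 test),
chosen as the smallest configuration that exercises all seven groups, all
seven cascade levels and a stratified 10-fold CV with comfortable class
support; it completes in a couple of minutes on one CPU core. Every source
of randomness (dataset generation, ICA, fold shuffling) funnels through a
single run seed, and a rerun under the same seed reproduces the metrics
report bit-exactly — this is asserted, not assumed.

## 8. Known limitations

* The premise gradient step is a fixed-step finite-difference descent, not
  a line search; with the default single epoch inside the cascade it never
  runs there, and standalone units rely mostly on the LSE.
* Index-regression decoding is sensitive to the arbitrary alphabetical
  class order (see §2).
* The SURF slot is a stand-in (see §3); results attributed to "SURF"
  describe that stand-in.
* The raw descriptor dimensionality (3550 at defaults) is
  configuration-dependent; only the post-reduction 63 is normative.
* MDS participates in method comparison only.
* `compare_methods` timings depend on the host and are informational.
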