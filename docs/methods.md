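# Methods

## Working geometry

All feature extraction operates on a single 64×64 RGB working image
(bilinear resampling, values kept as 8-bit integers). Using one size for
both descriptors keeps the topological and gradient features co-registered;
the size is the one the HOG configuration is laid out for (8×8 cells → 8×8
cell grid → 7×7 blocks). Grayscale conversion uses BT.601 luma weights
(0.299, 0.587, 0.114) evaluated in integer arithmetic,
`(299R + 587G + 114B + 500) // 1000`, which is exact rounding and makes the
conversion commute with constant intensity shifts — a property the HOG
shift-invariance tests rely on.

## Cubical persistence

The sublevel filtration of a channel includes pixels with intensity ≤ t.
Pixels are top cells: included pixels are 4-connected, the complement is
8-connected (the standard planar cubical duality).

* **H₀** is computed by a union-find sweep over pixels in increasing
  intensity order. A pixel with no previously-entered neighbor births a
  component at its own value; a merge kills the younger component at the
  current value (elder rule; ties on birth value are broken by pixel index,
  which only affects which zero-persistence pair is dropped). Exactly one
  essential component (death = ∞) remains.
* **H₁** uses duality: a hole of the sublevel set at threshold t is a
  bounded 8-connected component of the pixels with intensity > t. Running
  the filtration backwards (pixels in decreasing order plus a virtual
  border node representing the unbounded outside), a merge at value v of a
  complement component with maximum intensity M corresponds to a hole alive
  for v ≤ t < M. No essential 1-dimensional class exists for a 2-D image.

Zero-persistence pairs (birth = death) are dropped; they are invisible to
any Betti curve. Diagrams store intensity values rather than grid indices,
so they can be re-vectorized on any threshold grid. Correctness is
established by exhaustive comparison against an independent flood-fill
oracle (`scipy.ndimage.label` component and hole counts per threshold) on
hundreds of random small images; the comparison is exact, not approximate.

Betti curves use the activity convention **birth ≤ t < death**, the only
convention consistent with the worked example ([2,1,1,1,1] requires the
(1,2) component to be inactive at t = 2). Essential classes count through
the last threshold. The default grid is 100 thresholds linearly spaced over
the full [0, 255] range (not per-image min/max), so curve positions are
comparable across images. A superlevel filtration can be obtained by
negating the channel; the default 800-dim descriptor uses the sublevel
filtration only, matching the 200-per-channel accounting
(100·β₀ + 100·β₁ across R, G, B, gray).

## HOG

Central differences Gx(x,y) = I(x+1,y) − I(x−1,y) (and likewise Gy) with
replicate padding at the border, which avoids spurious border edges.
Orientations are unsigned, folded into [0, 180°), with θ := 0 where the
gradient vanishes. Nine bins with centers at 10°, 30°, …, 170°; each
pixel's magnitude is split between the two nearest centers by linear
interpolation with circular wrap, so per-cell bin sums conserve gradient
mass exactly. Blocks of 2×2 cells at a one-cell (8 px) stride are
normalized by v/√(‖v‖² + ε²) with ε = 10⁻⁶ (the ε enters squared under the
root, and its prose value 1e-6 is used literally); an all-zero block stays
zero. Blocks and cells are concatenated row-major. 49 blocks × 36 values =
1,764 features.

## Fusion

Both descriptors are unit-normalized before anything else; the fusion
weights the *normalized* vectors (weighting raw vectors would let the HOG
magnitude dominate). α is the cosine of the two normalized vectors on their
leading min(1764, 800) = 800 entries — normalized again by the truncated
segments' norms, so α is a true cosine on the shared basis — clamped to
[0, 1] against round-off. Both descriptors are nonnegative, so α ≥ 0 holds
automatically. If either descriptor is identically zero (e.g. a constant
image has a zero HOG vector), α falls back to 0.5, the least-informative
equal weighting, and the pipeline stays total. The fused concatenation has
1,764 + 800 = 2,564 entries; the trailing four (the last four β₁ entries of
the grayscale channel) are dropped to reach 2,560 = 8 × 320, the classifier
token geometry.

## Classifier

Plain multi-head self-attention (8 heads over 8 tokens of 320) with a
residual connection and no positional encodings — the tokens are fixed
feature segments, not a sequence. Additive zero-mean Gaussian noise
(σ = 0.05) is applied to the attended representation during training only,
as lightweight augmentation; it is placed after attention, before
flattening. Then two dense layers (defaults 512 → 128, ReLU, dropout 0.3)
and a 2-unit softmax.

Training: mean cross-entropy, AdamW (decoupled weight decay 10⁻², applied
to weight matrices only), cosine annealing of the learning rate from its
base value (default 10⁻⁴) to 0 over the configured epochs (default 500),
mini-batches of 64. After every epoch the validation accuracy is measured
with a deterministic forward pass (no noise, no dropout) and the
best-validation snapshot is kept; reported metrics always come from that
snapshot. One seed drives initialization, shuffling, noise and dropout, so
identical seeds reproduce identical runs bit for bit.

The network, backward pass and optimizer are implemented in numpy; the
analytic gradients are validated against central finite differences in the
test suite (relative tolerance 10⁻⁴, with an absolute floor for
exactly-zero gradients such as the key-projection bias, which cancels in
the softmax).

## Evaluation protocol

Stratified k-fold cross-validation (k = 20 by default, configurable for
desk-scale runs). Features are extracted per image, so feature extraction
cannot leak across folds; the only fitted preprocessing — a
standardization (zero mean, unit variance per feature) — is fit on each
training split and applied to its validation split. Standardization matters
numerically: fused entries have magnitude ~1/√2560, and centering/scaling
puts the first dense layer in a well-conditioned regime.

Positive class = disease (label 1); decision threshold 0.5 on its softmax
probability. Precision/recall/F1 are positive-class, AUC is the rank
statistic (ties half-credit; undefined and reported as missing for a
single-class batch), confusion matrices are row-normalized percentages of
the true-label count. Per-fold seeds are derived from the global seed by a
fixed affine map, so folds are independently reproducible.

## Synthetic tissue generator

The generator emulates transverse muscle sections under a membrane stain
(green channel; e.g. Alexa-488-conjugated WGA) with a nuclear counterstain
(blue channel; DAPI-like): polygonal fibers as cells of a multiplicatively
weighted Voronoi tessellation of jittered lattice seeds (lognormal radius
weights whose spread is set from the requested area coefficient of
variation), fiber boundaries rendered as a bright membrane, one nucleus per
fiber placed at the fiber's interior centroid with probability
`p_central_nucleus` and at the periphery otherwise, plus additive Gaussian
pixel noise (σ = 8) clipped to [0, 255]. The red channel carries only
noise. Ground truth (fiber count, per-fiber areas, nucleus placement) is
recomputed directly from the stored tessellation.

Class presets encode the morphology pathologists read: healthy = 10 fibers
per 64×64 field, area CV 0.25, central-nucleation fraction 0.05; diseased =
26 fibers, area CV 0.55, central-nucleation fraction 0.7. These defaults
make the two classes strongly separable by construction — Betti-curve
levels respond directly to fiber count and membrane geometry — which is the
point: the generator validates the pipeline's mechanics, not the clinical
difficulty of the task. Passing the end-to-end test therefore shows the
pipeline recovers a planted morphological signal; it says nothing about
performance on real stained tissue, which has stain variability, fibrosis,
imaging artifacts and far subtler class differences, none of which are
modeled.

## Problem sizes and numerical choices

* End-to-end cross-validation checks run at 100 images per class with
  5 folds and a 100-epoch training budget — sizes chosen for a desk-scale
  run; the 500-epoch default remains in `AttnMLPConfig` for full runs.
  On the strongly separable synthetic presets the reduced budget trains to
  the same (perfect) validation accuracy as longer runs.
* The homology oracle suite uses images ≤ 12×12 with ≤ 10 thresholds so the
  flood-fill oracle stays exhaustive; equality is exact.
* Degenerate inputs: constant images produce a zero HOG vector (handled by
  the α = 0.5 fallback), single-class training splits and
  fewer-samples-than-folds classes raise validation errors rather than
  producing silent nonsense.

## Known limitations

* H₂ (cavities), persistence images/landscapes and diagram metrics are out
  of scope; the vectorization is Betti curves only.
* Fusion weights are static (a measured cosine), not learned end to end.
* The classifier is CPU-scale numpy; it is meant for descriptor-sized
  inputs, not images.
* The synthetic generator does not model fibrosis, inflammation, stain
  normalization issues, or specific disease sub-phenotypes.
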