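# aftgnet

Classification of stained muscle-tissue images by fusing **global topological
features** (cubical persistent homology, vectorized as Betti curves) with
**local gradient features** (Histogram of Oriented Gradients), weighted by
their cosine similarity and classified with an attention-based MLP.

## Who this is for

Researchers analyzing transverse sections of skeletal muscle stained with a
membrane marker (e.g. fluorophore-conjugated wheat germ agglutinin, which
outlines fiber boundaries) who want an automated, reproducible alternative to
manual morphometry for separating diseased from healthy tissue. Myopathic
muscle shows more and smaller, irregularly shaped fibers and centrally
located nuclei; both signatures are topological and geometric, which is what
this feature pair captures. A synthetic tissue generator is included so the
entire pipeline can be exercised, end to end, without any imaging data.

## The method

Every image is resized to a 64×64 RGB working geometry.

**Topological features.** For each channel c ∈ {R, G, B, gray}, the sublevel
filtration includes pixels with intensity ≤ t for 100 thresholds t spanning
[0, 255]. Persistence diagrams PD₀ (connected components, 4-connectivity,
elder rule at merges) and PD₁ (holes, computed by duality with the
8-connected complement) are vectorized as Betti curves
βₖ(t) = #{(b, d) ∈ PDₖ : b ≤ t < d}, giving 2 × 100 numbers per channel and
an 800-dim descriptor f_TDA.

**Gradient features.** On the grayscale image, central-difference gradients
feed 9-bin unsigned-orientation histograms over 8×8 cells (magnitude votes
split linearly between neighboring bin centers), normalized over 49
overlapping 2×2-cell blocks by v/√(‖v‖² + ε²), ε = 10⁻⁶: the 1,764-dim
descriptor f_HOG.

**Cross-weighted fusion.** With f̃ = f/‖f‖ and
α = cos(f̃_HOG, f̃_TDA) ∈ [0, 1] measured on the leading 800 entries, the
fused vector is [α·f̃_HOG ‖ (1−α)·f̃_TDA], truncated from 2,564 to 2,560
entries so it segments into 8 tokens of 320.

**Classifier.** The tokens pass through 8-head self-attention with a residual
connection, Gaussian noise injection (σ = 0.05, training only), then two
ReLU dense layers with dropout and a 2-unit softmax. Training uses
cross-entropy with AdamW, cosine-annealed learning rate, and keeps the
checkpoint with the best validation accuracy. Evaluation is stratified
k-fold cross-validation with positive-class precision/recall/F1, accuracy,
rank-based AUC, and row-normalized percentage confusion matrices.

## Worked example

```python
from aftgnet.synth import generate_dataset
from aftgnet.evaluate import run_cv
from aftgnet.model import AttnMLPConfig

ds = generate_dataset(30, seed=7)           # 30 healthy + 30 diseased images
summary, reports = run_cv(ds.records, cfg=AttnMLPConfig(epochs=100, seed=7),
                          k=5, seed=7)
print(summary.mean)
print(summary.pooled_confusion)
```

prints

```
{'precision': 1.0, 'recall': 1.0, 'f1': 1.0, 'accuracy': 1.0, 'auc': 1.0}
[[100.   0.]
 [  0. 100.]]
```

i.e. with the default healthy/diseased presets (10 large-fiber vs 26
small-fiber tissues, central-nucleation fractions 0.05 vs 0.7) every
validation image in every fold is classified correctly: the Betti-curve
levels directly encode the fiber-count and fiber-size differences, so the
synthetic classes are strongly separable. The confusion matrix rows are
percentages of each true class.

The same flow is available from the shell:

```bash
aftg synth --n 30 --seed 7 --out data/
aftg extract --manifest data/manifest.csv --out features/
aftg evaluate --manifest data/manifest.csv --folds 5 --seed 7 --epochs 100 --out cv/
```

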