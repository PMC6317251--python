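# Methods

`parenchymaseg` segments lung parenchyma — the low-attenuation functional
tissue of the lung — from thoracic CT, using a classifier trained entirely
on algorithmically generated labels.  This note records the model, its
assumptions, the parameters that matter, and the design decisions taken
where the procedure left genuine freedom.

## 1. Weak-label generation

Every 512×512 slice is tiled into non-overlapping 8×8 patches and each
patch reduced to two scalars: its mean and its minimum intensity (HU).
Two-class k-means is run twice over all patches of the input volume(s),
once per statistic.  Parenchyma (≈ −850 HU) and outside-body air
(≈ −1000 HU) land in the low cluster of both runs.

Three filters then remove everything that is low-intensity but not lung:

1. **Cross-shaped verification.**  A low patch survives only if each of
   the four in-slice rays from it (full row to the left and right, full
   column up and down) contains at least one high patch.  Outside-body
   air always has at least one open ray, so it is discarded; patches on
   the grid border can never survive.
2. **Intersection of the two runs.**  The mean-statistic run keeps
   spurious patches in the air gap between body and scanner bed (the gap
   is flanked above and below by high structures); the min-statistic run
   has the complementary artifact (any patch containing one bright pixel
   leaves the low cluster, so its ring of artifacts sits elsewhere).  The
   logical AND of the two kept-masks cancels both.
3. **Connected components.**  Components are labeled in 3-D over patch
   addresses (6-connectivity) and at most the two largest components of
   size ≥ 1% of the grid survive — two lungs being the anatomical prior.
   The procedure names no retention rule, so this is ours.

Each surviving cell is expanded to the 32×32 pixel window that shares its
centre (rows `[8i−12, 8i+20)`); windows reaching past the slice are
filled with −1024 HU (air), the physically neutral value.  An equal
number of windows is drawn uniformly without replacement from the
non-surviving cells, giving an exactly balanced two-class dataset.
All randomness is seeded.

**k-means implementation.**  For 1-D data the optimal two-cluster
partition is a threshold partition of the sorted values, so we solve the
clustering *exactly* with a prefix-sum sweep over all split points —
equivalent to Lloyd's algorithm run to its global optimum but
deterministic and free of local minima.  A unit test cross-checks it
against `sklearn.cluster.KMeans` and against exhaustive search.

## 2. The patch classifier

A deliberately shallow CNN decides whether a 32×32 window is centred on
parenchyma:

    input 32×32 → conv(5×5, 6 kernels) → ReLU → LRN(3 channels)
               → 2×2 max-pool → FC(120) → dropout(0.5) → ReLU
               → FC(2) → softmax

Trained by mini-batch SGD (batch 128, momentum 0.9) for 50 epochs; the
reference learning rate is 0.01 and the optimized setting is 1e-4.  LRN
constants are the classic AlexNet values (α = 1e-4, β = 0.75, k = 2).
The network and its backward pass are implemented directly on NumPy,
which keeps the package dependency-light and bit-reproducible; the
gradients are verified against central finite differences in float64.

Numerical choices that required a decision:

* **Input normalization.**  Inputs are clipped to [−1024, 1024] HU and
  zero-centred by the training-set mean, *keeping the HU scale*.  This is
  the input convention of the classic CNN toolboxes this architecture
  descends from, and it matters: the stated learning rates are only
  meaningful at that input scale (rescaling to unit range makes 1e-4
  roughly 10⁶ times smaller in effect and the optimizer cannot leave the
  constant-prediction regime in any realistic number of iterations).
  At HU scale the LRN layer also acts as a genuine activation normalizer
  rather than a near-identity.
* **Weight initialization.**  Gaussian scaled by fan-in, zero biases,
  with one addition: the second half of the convolution kernels is the
  negation of the first (antithetic pairs).  Without it, a flat image
  region whose intensity has the "wrong" sign can fail to activate any
  unit, making uniform tissues of different intensity (flat air vs flat
  parenchyma) indistinguishable forever — the dying-ReLU failure.
* **Restart on collapse.**  Even so, on data with large perfectly
  uniform regions some initial seeds drift into that dead basin during
  training and do not leave it.  The collapse is detectable from the
  training set alone —
  final training accuracy remains near chance for one class — so `fit`
  retrains from a derived seed (up to 3 restarts) whenever training
  accuracy ends below 0.85.  Restarts are deterministic given
  `random_state` and use no held-out or ground-truth information.
* **Decision rule.**  argmax of the softmax; an exact tie goes to
  non-parenchyma, the cheaper error for the downstream hole filling.
* **Dropout placement** follows the listed layer order
  (FC → dropout → ReLU → FC), although ReLU-after-dropout is unusual.

The model-selection score is the average F-score
`F_avg = Σ_c P_c·R_c/(P_c+R_c)` over the two classes — each term is half
the class F1, so `F_avg` equals the macro-averaged F1 and is 1 for a
perfect classifier.  Elsewhere-reported per-class F1 values differ from
these terms by a factor 2.

## 3. Whole-volume segmentation

*Voxel-wise* mode classifies the 32×32 window centred on every voxel;
*patch-wise* mode makes one decision per 8×8 cell and broadcasts it
(64× fewer classifier calls).  Because convolution, ReLU and LRN are
translation-equivariant, the voxel-wise mode computes them once per
padded slice and applies the fully-connected head to strided crops of
the four pooling phases; this is exactly equivalent to window-by-window
classification (asserted by test) and roughly 35× faster.

Post-processing: keep the largest 3-D connected component
(26-connectivity; optionally the two largest for anatomically separated
lungs), then fill holes per slice (4-connected background regions not
touching the slice border become foreground).  Per-slice 2-D filling is
deliberate: it recovers lesions fully enclosed by parenchyma, while
pathology touching the lung-field boundary stays unrecovered because its
background region reaches the slice border through the body — the
documented failure mode of this method, which the test suite reproduces.
The difference mask before/after filling localises interior lesions.

## 4. Evaluation metrics

DSC `2|A∩B|/(|A|+|B|)` (both-empty = 1, one-empty = 0); exact symmetric
Hausdorff distance between boundary voxel sets (face-neighbour surface
definition, coordinates scaled by spacing, in mm), plus an explicitly
labeled per-slice-mean variant; voxel-wise sensitivity TP/P and
specificity TN/N; ROC/AUC by threshold sweep (equal to pairwise
concordance — used as the test oracle); and cohort self-adaptability,
the percentage of volumes the pipeline brings to a usable (non-empty)
mask without intervention, with a configurable success rule.

## 5. The phantom generator

Real thoracic CT cannot be redistributed with this package, so a
parametric phantom supplies inputs with analytic ground truth: air
background (−1000 HU), an elliptical body (+40), two elliptical lung
fields (−850) strictly inside it, a thin scanner-bed slab (+100)
separated from the body by an air gap, optional circular lesions (+30)
either interior to a lung or centred on its rim (effusion-like), and
i.i.d. Gaussian noise (default σ = 20 HU, a realistic parenchyma noise
level).  The chest wall is kept ≥ ~2 patch-widths thick so pure-body
patches exist along every verification ray, as in real anatomy.  Ground
truth parenchyma is the rasterized lung interiors minus lesion voxels.

What the phantom does *not* emulate: vascular and bronchial texture,
partial-volume gradients at tissue interfaces, scanner-specific intensity
shifts, gravity-dependent attenuation, and anatomic variability between
slices.  Tests passing on phantoms therefore demonstrate the pipeline's
logic (label generation, training, inference, post-processing, metrics),
not clinical performance.  Noise-free phantoms (σ = 0) are an idealized
special case used where deterministic oracles are needed; their
perfectly uniform regions are harsher for ReLU optimization than real
CT, which is what motivated the antithetic init and restart mechanism.

## 6. Problem sizes used in the shipped experiments

The reference cohort behind the published patch arithmetic is 2,460
slices (23 subjects); the shipped end-to-end experiment uses a 20-slice
512×512 phantom — the native slice size, one subject's worth of data —
which yields ≈ 16,000 balanced training patches.  Training there runs
the optimized setting for 10 epochs (≈ 1,300 SGD iterations), enough for
convergence at this data scale; the hyper-parameter table's 50-epoch
default remains the package default for real data.  Segmentation DSC is
reported against the analytic lung-field mask (parenchyma plus interior
lesion for the final hole-filled stage; parenchyma alone for the
pre-filling stages).

## 7. Known limitations

* Weak labels are conservative at lung boundaries (a cell must be almost
  entirely parenchyma to survive clustering), so the raw CNN mask is
  eroded by 1–2 voxels relative to ground truth; the effect shrinks with
  slice resolution and is part of the method.
* The 32×32 receptive field is fixed; multi-scale ensembles are out of
  scope.
* Lesion-specific segmentation (nodule, consolidation, effusion) is not
  attempted; interior lesions are only *localised* via the hole-filling
  difference.
* The pooled-clustering mode assumes intensity comparability across the
  pooled volumes (same scanner calibration); per-volume clustering is
  available via the labeler's interface when that fails.
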