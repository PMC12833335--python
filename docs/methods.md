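# Methods

## Problem setting

Stem diameter at the second above-ground internode is a standard
jointing-stage maize trait: it correlates with lodging resistance and is
normally taken with a vernier caliper along two perpendicular directions,
because the cross-section is elliptical rather than circular. This package
estimates both the major- and minor-axis diameters from a 3D point cloud of
one plant plus its immediate ground neighbourhood, in two stages: semantic
segmentation (stem vs. background) followed by geometric measurement.

## Segmentation network

The backbone is a hierarchical set-abstraction / feature-propagation
architecture for unordered point sets. Inputs are nine channels per point —
normalized coordinates, RGB color, unit normal — shaped `(B, 9, N)` next to
a `(B, 3, N)` coordinate tensor. The default hierarchy is

| stage | points | channels |
|-------|--------|----------|
| SA1   | 1024   | 64       |
| SA2   | 256    | 128      |
| SA3   | 64     | 256      |
| SA4   | 16     | 512      |
| FP4→FP1 | back to N | 256, 256, 128, 128 |

Each SA level samples centers by farthest-point sampling (deterministic
start at index 0), groups up to `k = 32` neighbours by ball query, applies a
shared per-point MLP with batch normalization, and max-pools over the
neighbourhood. Ball-query radii are specified as fractions
{0.04, 0.08, 0.16, 0.32} of the batch bounding-box diagonal so the same
configuration works at any scene scale. FP levels interpolate coarse
features to the finer level with inverse-distance weights over the three
nearest coarse points, concatenate the skip features, and apply a shared
MLP; the head is a 128→128 point-wise map with dropout 0.5 followed by a
128→2 classifier.

Three enhancement blocks sit between SA2 and SA3, where features are still
geometric enough for spatial encoding but already carry semantics; each can
be toggled independently so ablation variants (baseline, +RPE, +LGRM,
+RPE+LGRM, +RPE+LRSA, all three) are all runnable:

* **RPE.** With `x_c` the centroid of the SA2 point set (one center per
  sample, `(B, 3, 1)`), each point's code is
  `r_i = [Δx_i, Δy_i, Δz_i, d_i]` with `d_i = ‖x_i − x_c‖₂`. The `(B, 4, 256)`
  code tensor is mapped to 128 channels by a 1×1 convolution with batch
  normalization and ReLU, and added to the features: `f'_i = f_i + e_i`.
  The single-centroid reading follows the declared center-tensor shape; the
  distance channel is rotation-invariant about the center by construction.
* **LGRM.** The N = 256 point features are laid out row-major on an
  `h × h` grid with `h = ceil(√N)` (16 for the default); when `N < h²` the
  first `h² − N` point features are appended again in their original order
  ("forward mirror padding") before reshaping. The inverse flatten drops
  the padded tail, so rearrange∘flatten is an exact identity for every N —
  a property the tests sweep over N ∈ [1, 400].
* **LRSA.** A pre-norm residual transformer block over the grid tokens:
  channel LayerNorm, 4-head self-attention across all h·w tokens, and a
  convolutional feed-forward sublayer (1×1 expansion ×4 → depthwise 3×3 →
  1×1 projection), each sublayer with a residual connection. Input and
  output shapes are identical. The output projections of both sublayers are
  zero-initialized so a fresh block is the identity map — a standard
  residual-branch stabilization that also makes the block's residual
  contract directly testable. Padded tokens attend by default; a
  `mask_padding` flag excludes them as keys. The internal widths (4 heads,
  ×4 expansion, full-grid attention) are this package's design choices:
  with 256 tokens, full attention is cheap and avoids a patching scheme.

When LRSA is enabled without LGRM, the grid rearrangement is still applied
internally as shape plumbing (attention needs the grid); when LGRM is
enabled alone, rearrange∘flatten reduces to the identity, so that variant is
functionally the baseline — its value in ablation tables comes from
interaction with LRSA, not from the reshaping itself.

### Numerical backend

No GPU framework is used: the package includes a small tape-based
reverse-mode autodiff engine over numpy arrays with exactly the primitives
the network needs (broadcast arithmetic, channel-wise linear maps, batched
matmul, max-pooling, fused softmax/log-softmax and normalization, point
gathering, depthwise 3×3 convolution). Every primitive's gradient is
verified against central finite differences at float64; the engine runs at
float32 by default. The backward sweep releases the tape as it goes, which
keeps memory flat across training steps.

## Training

AdamW (decoupled weight decay 0.01), learning rate 0.001, 32 epochs by
default, point-wise cross-entropy. Scenes are subsampled to a fixed budget
(default 4096 points) per step, centered and scaled into the unit sphere;
missing colors default to mid-gray, missing normals are estimated by local
covariance eigen-analysis (k = 16 neighbours, sign oriented toward +y). The
checkpoint kept is the epoch with the highest validation mean IoU, the
appropriate criterion under heavy class imbalance (background points
outnumber stem points roughly 20:1). The loss is unweighted by default —
class weighting is exposed (`TrainConfig.class_weights`) but not needed on
the synthetic task. Training is reproducible bit-wise for a fixed seed in
single-threaded execution; all randomness (init, dropout, subsampling,
shuffling) derives from explicit generators.

Segmentation quality is scored with per-class accuracy
`Acc_i = TP_i/(TP_i+FN_i)` and `IoU_i = TP_i/(TP_i+FP_i+FN_i)`, averaged
over classes (mAcc, mIoU); classes absent from the ground truth are
excluded from the means with a warning rather than counted as zero.

## Measurement pipeline

1. **Principal axis.** PCA of the stem-labeled points: `v₁` is the top
   eigenvector of the coordinate covariance. The sign is chosen so the
   ground-facing end has the smaller axial coordinate — using the
   background centroid when labels are available, else the +y up
   convention. `λ₁/λ₂ < 4` raises a degenerate-axis warning.
2. **Slicing and node detection.** 15 uniform slices along `v₁` cover the
   stem's axial extent; slices with fewer than 30 points are invalid. Each
   slice is projected onto the `(v₂, v₃)` plane and ellipse-fitted. Node
   peaks are local maxima of the major-axis-length sequence over valid
   slices (plateaus report their first index) with topographic prominence
   of at least 5% of the median major-axis length; no smoothing is applied
   (15 samples are few, and the swelling amplitude comfortably exceeds the
   threshold). Fewer than two peaks is a hard failure carrying the
   diagnostic sequence.
3. **ROI and diameter.** The second internode is the region strictly
   between the upper edge of the first peak's slice and the lower edge of
   the second peak's slice. Three cross-sections centred at 1/4, 1/2 and
   3/4 of the ROI's axial extent, each of thickness ROI/15, are
   ellipse-fitted; the reported diameters are the arithmetic means of the
   valid sections' axis lengths — mirroring the manual protocol of
   averaging repeated caliper readings at multiple positions.
4. **Scale.** `S = 45 · L / Q` converts axis lengths to millimetres; `Q`,
   the checkerboard plate's edge-to-edge span in reconstruction units, is a
   user-supplied input (measured once per scene), matching the manual
   plate-measurement workflow. Automatic plate detection is out of scope.

**Ellipse fitting** is the direct least-squares conic fit with the
ellipse-specific constraint `4AC − B² = 1` in the numerically stable
block-decomposed (Halir–Flusser) form, after centering and isotropic
rescaling of the inputs; geometric parameters come from the
eigendecomposition of the conic's quadratic-form matrix, which pairs each
axis length with its direction unambiguously. At least 6 points are
required. If the constrained eigenproblem fails, a second-moment ellipse
(semi-axes `√(2λ)` of the 2D covariance — exact for points uniformly
sampled on an ellipse contour) is used as fallback; collinear inputs fail
outright. The fit is cross-checked in the tests against an independent
direct fitter and a nonlinear orthogonal-distance fit.

## Synthetic scenes

The generator emulates the structure the pipeline relies on, with defaults
chosen as realistic jointing-stage values (vertical axis = +y; units mm):

| parameter | default | rationale |
|---|---|---|
| stem height | 450 | lower-stem section of a jointing-stage plant |
| major/minor diameter | 32 / 26 | mid-range caliper values; defined *at the second-internode midpoint*, so the ground truth echoes the config exactly |
| taper | 0.12 | fractional diameter change over the height, applied relative to the reference height |
| node heights | 150, 300 | first two above-ground nodes |
| node swelling | 0.25, σ = 10 | multiplicative Gaussian bumps on both semi-axes; nodes are visibly but locally swollen (~2 cm band) |
| surface noise | 0.4 | MVS-like roughness along the local surface normal |
| stem : background points | 2500 : 50000 | ≈1:20 imbalance of real annotated scenes |
| ground | disc r = 250, smooth roughness sd = 2 | bare soil around a single plant |
| checkerboard | 3×3 of 15 mm squares, flat near the stem | the physical scale plate (45 mm span) |

Colors are class-typical with overlapping Gaussian spread (green stem,
brown soil, black/white plate squares); normals are analytic. A
`unit_scale` factor multiplies all coordinates (and the ground-truth Q) to
emulate the arbitrary global scale of multi-view reconstruction; scaling
all geometric lengths is distance-coherent by construction, which the tests
verify. Scenes are exactly reproducible from their seed.

What the generator does **not** emulate: leaves and canopy occlusion,
missing surface patches from camera blind spots, outlier clusters from
matching failures (an optional outlier fraction exists but defaults to 0),
lodged or strongly curved stems, and multi-plant clutter. Passing tests
therefore demonstrate correctness of the algorithms under clean
single-plant geometry, not field robustness; the network's headline field
accuracy cannot be reproduced without the original field data.

## Agreement statistics

Manual values `y` and predictions `ŷ` are compared with MAPE
(denominator = the manual reference value, reported in percent), MAE, RMSE
and R²; residuals `e_i = y_i − ŷ_i`; an OLS line of `ŷ` on `y` with
confidence and prediction bands

```
CI: t_{α/2,n−2} · s · sqrt(1/n + (x₀−x̄)²/Sxx)
PI: t_{α/2,n−2} · s · sqrt(1 + 1/n + (x₀−x̄)²/Sxx)
```

evaluated on a 100-point grid over `[min x, max x]` (the PI is strictly
wider everywhere); a two-sided paired t-test on `d_i = y_i − ŷ_i` with
`t = d̄/(s_d/√n)` and n−1 degrees of freedom (p > 0.05 read as no
significant difference between methods); and Bland–Altman limits
`mean(d) ± 1.96·sd(d)` with the difference signed as predicted − manual, so
a positive mean indicates overestimation by the point-cloud method. All
formulas are computed directly and validated against statsmodels/scipy in
the tests. Degenerate inputs (zero reference for MAPE, constant reference
for R², constant x for the regression) raise errors rather than returning
NaN.

## Problem sizes in the test suite

The structural tests run a miniature network (same topology, smaller
widths) on 128–256-point clouds; the architecture-contract test runs the
full default network on a 4096-point batch. The parameter-recovery study
uses 20 random stem configurations (6000 stem points each; heights 400–500
mm, major diameters 24–40 mm, axis ratios 0.75–0.95, tilts up to 6°, random
unit scales 0.5–2), noiseless and with 1%-of-radius noise. The learning
experiment trains the full default network for 30 epochs on eight
2048-point scenes with the realistic 1:20 class imbalance and scores stem
IoU on a held-out scene; it dominates the suite's runtime at roughly two
to three minutes on one CPU.

## Known limitations

* The slice-based node detector assumes two clearly swollen nodes inside
  the cloud's axial extent; stems cut above the second node or with
  atypically flat nodes fail loudly rather than degrade silently.
* Ellipse fitting assumes a near-elliptical, mostly complete cross-section;
  large missing arcs bias the axes (the fallback moment ellipse is even
  more sensitive to partial coverage).
* The principal axis is a single straight line; strongly curved or lodged
  stems would need centerline tracking, which is out of scope.
* `Q` is trusted as given; errors in the plate span propagate linearly into
  both diameters.
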