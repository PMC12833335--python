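# stalkmetric

Non-contact measurement of maize stem diameter from 3D point clouds, aimed at
jointing-stage field phenotyping where caliper measurements are slow,
subjective and destructive. Given a multi-view-reconstruction point cloud of a
single plant plus ground, the package

1. **segments** stem from background with a hierarchical point-cloud network —
   four set-abstraction (SA) levels and four feature-propagation (FP) levels,
   enhanced at the SA2/SA3 junction by **relative position encoding** (RPE:
   per point, `r_i = [Δx, Δy, Δz, ‖Δx‖₂]` relative to the level's center,
   mapped by a 1×1 convolution and added residually), a **local group
   rearrangement** (LGRM: the 256 unordered point features laid out on a
   16×16 grid with forward mirror padding) and **local-region self-attention**
   (LRSA: a shape-preserving pre-norm transformer block with a convolutional
   feed-forward sublayer on that grid);
2. **measures** the stem: PCA gives the principal growth axis
   `v₁ = argmax_v vᵀCv`; the stem is cut into 15 uniform slices along it and
   each slice is ellipse-fitted; nodes appear as increase–peak–decrease
   patterns of the slice-wise major-axis length, the region between the first
   two peaks is the second-internode ROI, and three evenly spaced
   cross-sections inside it yield the major/minor axis lengths `L`;
3. **scales** to millimetres with a 3×3 checkerboard plate of 15 mm squares
   (45 mm edge to edge): `S = 45 · L / Q`, where `Q` is the plate's
   edge-to-edge span in reconstruction units;
4. **evaluates** agreement with manual measurements: MAPE/MAE/RMSE/R²,
   regression with confidence and prediction bands, paired t-test, and
   Bland–Altman limits of agreement.

Because no public dataset of labeled maize stem clouds exists, the package
ships a first-class synthetic scene generator (elliptical tapered stem with
Gaussian node swellings, rough ground disc, checkerboard plate, per-point
labels and exact ground truth) that every stage is tested against. The
network and its training loop run on a small numpy reverse-mode autodiff
engine included in the package (`stalkmetric.nn.autograd`), so there is no
deep-learning-framework dependency.

## Worked example

```python
from stalkmetric import SyntheticStemConfig, generate_stem_scene, measure_stem

cfg = SyntheticStemConfig(stem_points=6000, ground_points=2000, seed=42)
cloud, truth = generate_stem_scene(cfg)
meas, frame, profiles, peaks = measure_stem(cloud, q_units=truth.checkerboard_span_units)
print(f"axis elongation:     {frame.elongation:.1f}")
print(f"node peak slices:    {peaks}")
print(f"measured major axis: {meas.major_mm:.2f} mm  (true {truth.true_major_mm:.1f} mm)")
print(f"measured minor axis: {meas.minor_mm:.2f} mm  (true {truth.true_minor_mm:.1f} mm)")
```

prints

```
axis elongation:     124.1
node peak slices:    [5, 9]
measured major axis: 31.89 mm  (true 32.0 mm)
measured minor axis: 26.06 mm  (true 26.0 mm)
```

The elongation `λ₁/λ₂ ≈ 124` confirms a strongly elongated cloud (values
below 4 flag a degenerate axis); slices 5 and 9 are the first two node peaks,
so the diameters are measured between them, and both axes land within 0.5%
of the generator's ground truth on this noisy (σ = 0.4 mm) scene.

The same pipeline is available from the shell:

```bash
stalkmetric synth --seed 42 --out scene.xyz --truth truth.json
stalkmetric stats scene.xyz --voxel-size 10
stalkmetric measure scene.xyz --q-units 45.0 --out measurement.json
stalkmetric train --data scenes/ --out model.npz        # labeled scenes
stalkmetric segment scene.xyz --checkpoint model.npz --out labeled.ply
stalkmetric eval --manual manual.csv --predicted pred.csv --out report.json
```

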