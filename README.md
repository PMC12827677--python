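# conefuse

Cone-marker based fusion of 2D histology sections with 3D microCT volumes.

## The problem

Correlating a stained histological section with the microCT scan of the
same resin-embedded specimen requires knowing *where* in the 3D volume the
2D cut was made — a slice-to-volume registration problem that is badly
conditioned when attempted from image content alone. `conefuse` implements
a fiducial-based solution: three 3D-printed truncated cones (radiopaque
resin, height 11 mm, base ⌀ 3 mm, apex ⌀ 0.5 mm) are embedded beside the
specimen. Because a cone's cross-section diameter shrinks linearly with
height,

    w(h) = w_base − (w_base − w_apex) · h / H,

the diameter of each marker ellipse visible in the section encodes the
height of the cut at that marker. Three markers give three 3D points,
which determine the cutting plane; resampling the volume along that plane
yields the matching *in-silico* image for registration and scoring.

The package is aimed at correlative-imaging workflows (microCT + histology
of embedded biopsies) and at anyone who wants to prototype or validate the
marker approach without scanner access: a synthetic phantom generator
reproduces the whole study — cones, tissue texture, contrast-agent
sedimentation, noise, and a ground-truth cutting plane — so every stage
has a parameter-recovery test.

## What it does

1. **Radiopacity planning** — the contrast-agent fraction needed to print
   markers at a target CT number, `k = (CT_goal − CT_resin) / (CT_CA − CT_resin)`.
2. **Detection** — slice-wise conic-section detection in the CT stack
   (adaptive threshold → Canny edge support → morphology → contour →
   least-squares ellipse fit → size/eccentricity filters), plus a
   promptable-mask backend interface (point prompt → mask) with a built-in
   threshold/flood segmenter.
3. **Calibration** — clustering of detections into per-cone tracks,
   outlier removal, and a two-pass linear regression of width (mm) vs
   slice index, giving each cone an invertible width↔height map and a
   center-drift model interpolated across unsampled slices.
4. **Section analysis** — marker ellipse extraction from the histology
   image and assignment to cones from the approximate relative layout.
5. **Plane recovery** — three (section ↔ volume) correspondences define an
   affine plane embedding; the oblique in-silico slice is resampled with
   trilinear interpolation.
6. **Registration & scoring** — rigid MSE registration (multi-resolution
   grid + Powell), and the modified local normalized cross-correlation

       LNCC(I, J) = mean_k | NCC over the 45×45 window centered at k |,

   whose absolute value makes the score robust to local contrast inversion
   between modalities, with heatmaps, checkerboard overlays, and a
   layer-sweep validation (score the section against every flat layer; the
   true cut should win).

## Worked example

Simulate a phantom study and run the full pipeline (Python; the same flow
is available as `conefuse run --config config.yaml`):

```python
from conefuse import io as cio, phantom as ph
from conefuse.pipeline import load_config, run_pipeline

vol, truth = ph.generate_phantom_volume(
    shape=(128, 192, 192), voxel_size=0.1, noise_sigma=0.045, seed=42,
    cone_specs=ph.default_three_cone_specs((128, 192, 192), 0.1, base_z=0.4))
cio.write_volume("volume.tif", vol)

plane, shape = ph.make_cutting_plane(truth.shape, 0.1, z0_mm=5.8,
                                     tilt_deg=2.0, azimuth_deg=15.0,
                                     pixel_size=0.04)
sec = ph.sample_section_image(vol, truth, plane, 0.04, shape, seed=20)
cio.write_section_image("section.tif", sec.image, 0.04)

summary = run_pipeline(load_config("config.yaml"))   # paths + layout + seed
```

Output of this exact run:

```
n_detections 205
cone_0  slope -0.022898 mm/slice  intercept 3.1105 mm  48 inliers
cone_1  slope -0.022809 mm/slice  intercept 3.1063 mm  48 inliers
cone_2  slope -0.022926 mm/slice  intercept 3.1020 mm  50 inliers
plane normal [0.0103 -0.0282  0.9995]
rigid transform: rotation -0.32°, translation (0.18, 0.01) px
LNCC (window 45): mean 0.7167, max 0.9450
```

Reading: the recovered taper slopes sit within 0.9% of the analytic value
−(3 − 0.5)/11 × 0.1 = −0.022727 mm/slice; the recovered plane normal
matches the ground-truth tilt (true normal [0.0090 −0.0337 0.9994], i.e.
the 2° cut was found to within a fraction of a degree); the near-identity
rigid transform confirms the extracted plane already lands on the section;
and the LNCC of 0.72 against the extracted plane far exceeds what any
wrong flat layer scores. All intermediates (detections CSV, calibration
JSON, plane TIFF + JSON, LNCC heatmap, checkerboard PNG, summary JSON) are
plain files in the output directory.

The CLI exposes each stage separately:

```bash
conefuse simulate --config phantom.yaml --seed 1 --out sim/
conefuse mix --goal 4600 --resin 100 --ca 25100     # → k = 0.18 (18%)
conefuse detect --volume sim/phantom.tif --n-sample 100 --seed 1 --out det.csv
conefuse calibrate --detections det.csv --pixel-size 0.05 --layout layout.json --out calib.json
conefuse run --config config.yaml
```

## Scope

Physical printing/embedding/sectioning, scanner reconstruction and
stitching, neural segmentation weights, and elastic refinement are out of
scope; the plane embedding and rigid result are exported so an external
elastic registration tool can take over. See `docs/methods.md` for the
model details, parameter choices and limitations.
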