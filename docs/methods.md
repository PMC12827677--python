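# Methods

## Model

A truncated cone of height `H` with base diameter `w_b` and apex diameter
`w_a`, embedded with its axis along the stack (z) direction, shows a
cross-section of diameter

    w(h) = w_b − (w_b − w_a) · h / H,      0 ≤ h ≤ H,

at height `h` above its base. The map is linear and invertible, so a
measured section width identifies the cutting height at that marker. With
three markers at distinct (x, y) positions, the three recovered 3D points
(axis position at the decoded height) and their 2D counterparts (ellipse
centers in the section) determine a unique affine map `A : R² → R³`; its
image is the cutting plane. The defaults use the printed design
`H = 11 mm, w_b = 3 mm, w_a = 0.5 mm` (taper 2.5/11 ≈ 0.227 mm per mm of
height). An oblique cut lengthens only the *major* axis of the marker
ellipse, so the major axis is the width measurement on the histology side;
on near-horizontal CT slices major ≈ minor ≈ width.

Assumptions: markers are upright (axis ≈ z); cuts are planar and tilt only
a few degrees (at 5° the major-axis elongation factor 1/cos θ ≈ 1.004
biases the decoded height by well under one voxel); the markers are the
brightest compact structures in both modalities.

## Coordinate conventions

Volumes are `(z, y, x)` arrays; voxel centers at integer indices; physical
mm = index × voxel size (isotropic). 2D points are `(x, y) = (col, row)`.
These conventions are defined once in `conefuse.volume` and used
everywhere, including the plane embedding (`A(u, v) = origin + u·b_u + v·b_v`
in mm).

## Pipeline stages and key parameters

**Radiopacity planning.** Linear mixing: `k = (CT_goal − CT_resin)/(CT_CA − CT_resin)`.
Targets outside the pure-material interval warn (physically unattainable)
rather than error. No iodine-concentration → HU physical model is
attempted.

**Detection** (`detect.DetectionParams`). Adaptive (local-mean) threshold
with an offset of 2% of the image dynamic range; Canny (σ 1.5, thresholds
0.1/0.3 of range) used as *edge support* — a thresholded region survives
only if ≥ 20% of its boundary lies on Canny edges, which removes flat
false-positive patches; morphological opening + closing with a 2 px disk;
subpixel contours (0.5-level) of each surviving region fitted with an
algebraic least-squares ellipse; filters on ellipse area (default derived
from the cone geometry via `params_for_cone_geometry`) and eccentricity
(≤ 0.9). All intensity-like parameters are fractions of the dynamic
range, making detection invariant to affine intensity rescaling. The
subpixel contour at the 0.5 level of a center-inside rasterization is an
essentially unbiased estimate of the continuous boundary; this matters
because a systematic width bias in calibration would translate directly
into a z-offset of the recovered plane. These parameter values are the
package's own engineering choices, exposed in the config.

**Promptable-mask backend.** The contract is image + point prompts → one
binary mask per prompt; masks not containing their prompt are discarded.
The built-in backend thresholds at Otsu's level and returns the connected
component containing the prompt (empty for background prompts). Any
promptable neural segmenter can be plugged in behind the same interface;
nothing in the package requires one.

**Calibration** (`calibrate`). Detections are clustered on their centers:
a density filter (≥ 2 neighbours within 5× the median nearest-neighbour
distance) excludes isolated false positives from centroid estimation,
k-means (farthest-point initialized) fits the `n_cones` centroids, and
points farther than a threshold (default: max of 5× median and the 95th
percentile of within-cluster distances) from every centroid stay
unassigned. The taper fit is two-pass ordinary least squares of width
(mm) on slice index: pass-1 residuals are centered on their median (gross
outliers bias the pass-1 intercept; without centering the threshold would
reject the inliers instead), points beyond 3 × 1.4826 × MAD are dropped,
and pass 2 refits. A fixed-mm residual threshold can override the robust
default. The per-axis linear center-drift fit interpolates the axis
position across unsampled slices and absorbs small marker tilt. The
regression variable is slice index (not mm height) because the plane
construction needs a z-index directly; the voxel size is stored in the
model.

**Section matching** (`histology`, `matching`). Marker-emphasis
preprocessing (channel selection for RGB input, then suppression of
pixels below a saturation threshold, default 75% of range — markers are
the most saturated structures in the phantom renderer; real stains will
need retuning) feeds the same detection chain. Assignment to cones
minimizes total squared distance between normalized (centroid-removed,
unit-RMS) ellipse centers and the normalized expected layout — invariant
to translation and isotropic scale but deliberately *not* to rotation,
since the approximate layout is what fixes the section's orientation.
Both the given orientation and its 180° flip are evaluated: if the two
best assignments disagree but score within a margin (symmetric layouts),
the match errors rather than guesses.

**Plane and extraction** (`plane`). The affine three-point embedding (not
a bare point + normal) is used so the in-plane frame and scale come from
the correspondences, handing the rigid registration a full initial guess.
Oblique resampling uses trilinear interpolation (`map_coordinates`,
order 1), which reproduces any globally trilinear field exactly and
returns lattice values bit-exactly on axis-aligned integer planes;
samples outside the volume take a fill value (default 0). Output pixel
pitch defaults to the voxel size (section resampled at CT scale).

**Rigid registration** (`metrics.rigid_register`). Both images are
Gaussian-smoothed (σ = 1 px) and min-max normalized; a 3-level
multi-resolution search runs an exhaustive rotation × translation grid at
the coarsest level (±6°, step 1°; ±12 px) and Powell refinement at every
level. The pre-smoothing exists for a measured reason: resampling a noisy
image at subpixel offsets attenuates its noise, which lowers the MSE and
biases the optimum toward spurious subpixel rotations (up to ≈ 0.25° at
10% noise without smoothing, < 0.1° with it). The procedure is fully
deterministic. The MSE is evaluated over the overlap region only; empty
overlap at the initial guess errors.

**Scoring** (`metrics.lncc`). Per-window NCC in absolute value, averaged
over all fully interior windows (heatmap = input − window + 1 per axis;
the off-by-one alternative "reduced by the window size" was considered
and the standard valid-window convention adopted). Default window 45 px.
Windows where either image has (numerically) zero variance contribute 0;
global means are subtracted first so constant windows cancel exactly in
the integral-image sums. The vectorized implementation is tested against
a literal per-window double loop to < 1e-6. The layer sweep scores the
section against every flat z-layer (center-cropped to common size; first
maximum wins ties) — validating that the true cut layer
maximizes the score and that an oblique extraction beats every flat layer.

## The synthetic phantom

`phantom.generate_phantom_volume` renders: a uniform embedding medium
(default 0.1); the cone solids at attenuation 1.0 with an optional
sedimentation term linear in height (default slope 0, matching the
observation that contrast-agent settling varies intensity without
distorting geometry); a tissue stand-in — a Gaussian-smoothed white-noise
field (σ 0.3 mm) thresholded to a blobby cylinder (radius 1.8 mm) between
the cones, intensities between medium and marker level; and additive
Gaussian noise. The default study preset is 256³ voxels at 0.05 mm — a
desk-scale stand-in for the real ~4 µm/50 GB scans; full-resolution
emulation is a non-goal. Reference noise level: 5% of the marker-medium
contrast. Generation is deterministic per seed.

`sample_section_image` renders the simulated stained section: marker
footprints come from the analytic cone solids evaluated on the section
grid (ground-truth ellipse parameters from moments of a 3× supersampled
solid test — for a uniform ellipse the second moments give the axes
exactly); tissue intensity is the CT volume sampled on the plane and
passed through a monotone stain transfer (inversion + gamma + rescale).
Using the *same* underlying texture with different contrast is deliberate:
a stained section shows the same physical structure as the scan, and the
contrast-inversion-robust LNCC is exactly what makes the layer sweep peak
at the true layer. An independent random field would make that validation
meaningless. What the phantom does **not** emulate: X-ray physics (beam
hardening, phase contrast), reconstruction/stitching artifacts, sectioning
distortion, stain variability, marker damage — so passing tests show the
algorithmic chain is correct and well-conditioned, not that the detection
defaults transfer to arbitrary real scans.

Ground-truth cutting planes built by `make_cutting_plane` keep the
in-plane frame block-aligned (x̂ projected onto the plane) regardless of
the tilt-axis azimuth, matching how sections are physically cut and
keeping the section orientation compatible with layout matching.

## Numerical choices

- Zero-variance LNCC windows score 0 (undefined NCC), threshold 1e-10 × n
  × mean squared centered intensity.
- Taper fit requires ≥ 2 surviving points on ≥ 2 distinct slices; a zero
  fitted slope (no taper) errors.
- Width lookups outside the calibrated range warn (extrapolation) but
  proceed — partially scanned cones remain usable.
- Matching ambiguity margin: 1e-3 per marker in normalized units; ties
  error rather than guess.
- Volumes are float32 throughout; 8/16-bit inputs are promoted; explicit
  min-max normalization replaces ad-hoc contrast adjustment, with bounds
  recorded where written.

## Problem sizes used in validation

The test suite uses a 128×192×192 phantom at 0.1 mm voxels for unit and
integration tests and the 256³/0.05 mm preset with 100 sampled slices for
the full-scale checks; `scripts/acceptance.py` runs the 256³ preset. The
LNCC oracle comparison uses 20 random pairs of 64–128 px images at
windows 15 and 45; registration recovery uses planted transforms up to
10 px / 5° at 10% noise.

## Limitations

- Upright-cone assumption: large marker tilts are only partially absorbed
  by the center-drift model; tilted-cone geometry is out of scope.
- Linear taper only; no nonlinear or nonparametric width models.
- Histology preprocessing defaults are tuned to the phantom renderer;
  real stains and microscopes need per-setup parameters (exposed in the
  config).
- Rigid registration only; the plane embedding and rigid result are
  exported for external elastic refinement.
- MSE registration assumes overall similar contrast polarity between the
  (normalized) images; strongly inverted real stains may need the tissue
  mask option or an external metric.
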