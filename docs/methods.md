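# Methods

## The measurement model

An active-stereo RGB-D camera reports, per pixel, an integer depth in
sensor units (millimeters under the default `depth_scale = 0.001` m/unit);
zero encodes a failed measurement (dropout). Internally all geometry is in
meters, with the pixel origin at the top-left (x = column, y = row) and
the camera frame X right, Y down, Z along the optical axis. Pixel
coordinates stay continuous everywhere; rounding to the integer grid
happens only when a depth frame is indexed, by nearest neighbor. Lens
distortion is not modeled: frames are assumed rectified by the sensor
stack before any of these equations apply, which matches how consumer
RGB-D modules expose their streams.

Depth from a rectified stereo pair is `Z = f·B/d` with `f` the shared
focal length (pixels), `B` the baseline (m) and `d` the disparity
(pixels); `d ≤ 0` is an error (point at infinity / matcher failure), not a
value. Depth→color alignment is the composition *deproject (depth
intrinsics) → rigid transform [R|T] → project (color intrinsics)*, applied
per depth pixel; the inverse (color→depth) mapping is deliberately not
provided. Rotation matrices are validated orthonormal with det +1 at
construction (tolerance 1e-9), so a malformed calibration fails loudly
rather than silently skewing points.

## Robust depth extraction

The localizer turns a detection box into one depth value by:

1. **Region**: shrink the box about its center by `region_scale`
   (default 0.5) and clip to the frame, snapping outward to whole pixels
   with a 1-px minimum per side. The clipped rectangle's own center is
   used from then on. Halving the box keeps the samples on the fruit
   surface even for loose boxes.
2. **Sampling**: `n_samples` (default 100) pixels drawn uniformly *with
   replacement* (keeps n fixed for tiny regions) under a caller seed.
3. **Filtering**: zero-depth samples are discarded; an empty remainder is
   the `no_valid_depth` status, not an exception.
4. **Clustering**: 1-D k-means with `k = 2` (k-means++ init, Lloyd to
   convergence, seeded; backed by scikit-learn with centers recomputed as
   exact member means so center == mean holds to 1e-9). Fewer distinct
   values than k yields that many groups. Clustering is strictly on depth
   values — 3-D clustering is intentionally out of scope.
5. **Aggregation**: the median of the most populous cluster (mean of the
   two middle order statistics for even sizes). A size tie goes to the
   cluster with the *smaller* center: the fruit sits in front of whatever
   contaminates the region.
6. **Gating and deprojection**: extracted depth below `blind_zone_m`
   (default 0.3 m) reports `blind_zone` with no point — the sensor cannot
   measure there; depth above `accurate_max_m` (default 1.2 m) returns the
   deprojected point flagged `beyond_accurate_range`, since out-of-range
   readings are still reported by the hardware, just degraded; otherwise
   `ok`. The 3D point deprojects the **box-center pixel** at the cluster
   depth — the one pixel a detection unambiguously designates.

With up to 49 % of samples contaminated by far outliers, the majority
cluster is the inlier mode and its median moves by less than the inlier
spread; this is the property the k = 2 split buys over a plain median.
Its cost is a small bias on *unimodal* data, where k-means splits the one
mode in half and the majority-half median sits a fraction of a standard
deviation off center — a few millimeters at the noise levels involved, and
inherent to the strategy.

Per-trial localization errors are reported as nearest-integer millimeters
per axis; summary statistics (mean/max/min per axis) are computed on
unrounded errors and rounded to 2 decimals at the end. Trials without a
detection are excluded and counted.

## The embedded field-trial table

The 11-row benchmark of real vs. detected 3D coordinates is stored
verbatim in `scenes.table4_fixture()`. Two rows (targets inside the blind
zone) have no detection. One detected X coordinate carries an obvious
comma-for-decimal typo and is stored as the value consistent with its
printed 5 mm error. The two far-range rows print Z coordinates of
~0.12–0.13 m alongside 39/46 mm Z errors; the errors are consistent with
1.199/1.238 and 1.293/1.339 m, so a ×10 alternate reading is stored next
to the verbatim one and *neither* is asserted — X/Y statistics (means
12.33 and 11.11 mm) are pinned, Z is not. Independently, the published
per-trial Z errors average 17.0 mm while the published mean is 16.33 mm;
that figure is therefore also left unasserted. Printed-value comparisons
in the tests allow one unit in the last printed digit, because the source
rounds some entries and truncates others (its 0.929 F1 is a truncation of
0.92976; its 59.94 % a truncation of 59.946 %).

## Detector graph

The audit engine models the detector declaratively: every block knows its
closed-form parameter count (`k²·c_in·c_out` per convolution plus
`2·c_out` norm terms, or `c_out` bias when unnormalized), its exact output
shape, and a numpy forward pass (im2col convolutions, SiLU activations,
normalization treated as the identity affine at initialization, He-style
fan-in-scaled random weights under a fixed seed). Only structural
properties are ever asserted of the forward pass — finiteness, the
residual identity — never output values.

BasicRFB branch internals: each branch is a 1×1 channel reduction
(`inter_ratio`, default 1/8 of the input width, the original
receptive-field-block convention) followed by 3×3 convolutions whose
terminal dilation rates are 1, 3 and 5; branch 1 has one 3×3, branches 2
and 3 prepend a plain 3×3 before the dilated one. The nominal receptive
fields (3, 9, 13 by the standard recursion) are strictly ordered. The
"1×1, 3×3, 5×5" framing sometimes used for such blocks is read as a
receptive-field-equivalent description of the same three dilated branches.
The shortcut is the identity when widths match, else a 1×1 projection;
the fusion 1×1 and the shortcut are linear (no activation) so the residual
sum is clean. The graph replaces the terminal backbone SPPF with exactly
one RFB node and changes nothing else; an SPPF spec is retained solely so
audits can assert its absence and baselines can be built for comparison.

Scales use the standard (depth, width, max-channel) multiplier table
(`n`/`s`/`m`/`l`/`x`); no scale is privileged, since a serialized model
size does not identify one unambiguously. Odd input sizes are legal:
stride-2 stages round up (`ceil(H/2)`), and concatenations corner-crop
inputs differing by at most 1 px — larger disagreements are real wiring
errors and raise with the offending edge named. Decoupled heads emit
`4·reg_max + n_classes` channels at strides 8/16/32. Losses, target
assignment, training augmentations (Mosaic, Mixup, EMA, HSV) and
deployment runtimes are out of scope; the training hyperparameters exist
only as documentation.

## Detection metrics

mAP is interpreted as mAP@IoU 0.5 with all-points interpolation — the
modern single-stage convention — with greedy confidence-ordered one-to-one
matching (ties by larger IoU, then input order). `0/0` precision is 0 with
an explicit flag. The default is single-class; multi-class data is
evaluated per class and averaged. The package does not attempt to
reproduce published detection accuracies (they require the authors'
private imagery and GPU training); instead metric *correctness* is
certified against structure: perfect synthetic detections must score
mAP = 1, the interpolated AP must equal a brute-force
enumerate-every-recall-step oracle, and appending false positives must
never raise AP.

## Synthetic scenes

The simulator emulates a calibrated depth camera viewing ellipsoid targets
(default radii 0.09 × 0.12 × 0.05 m, a face-on bunch) against a background
plane (default 3 m): per-pixel depth is the closed-form near ray-ellipsoid
intersection, plus Gaussian noise (σ in mm), i.i.d. per-pixel dropout, and
quantization to integer millimeters. Default noise/dropout for evaluation
scenes are σ = 5 mm and 20 % — representative of a consumer active-stereo
module at indoor range. Evaluation scenes use a 640×480, f = 380 px
camera and 100 scenes with target depth uniform in [0.35, 1.15] m; these
sizes keep the full suite and the acceptance script in seconds while the
binomial/means being tested are already stable.

The ground-truth 3D point is the **surface point hit by the box-center
ray** — what a laser rangefinder aimed at the bunch measures, and what the
depth extractor estimates — not the ellipsoid centroid (also stored, for
reference). Exact noiseless recovery is checked on near-flat targets;
curved targets carry an inherent few-mm bias (the region's median front
surface is slightly behind the center-ray surface) that the ≤ 10 mm
end-to-end bound absorbs. What passing simulator tests do *not* show:
robustness to structured dropout (speckle, occlusion shadows), IR
multipath, specular foliage, or detector box-quality effects — real-scene
validation still requires real scenes.

## Known limitations

- The forward pass is an audit tool; it carries random weights and cannot
  produce meaningful detections.
- Dropout is i.i.d.; real sensors drop pixels in structured patches. The
  extraction contract (zero-filter + majority cluster) does not depend on
  the pattern, but failure rates on real data will differ.
- The localizer returns one point per box (the box center at the cluster
  depth); no temporal smoothing, multi-camera fusion or grasp planning.
- Lens distortion, rolling shutter and exposure effects are unmodeled.
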