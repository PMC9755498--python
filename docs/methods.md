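# Methods

`aopnet` measures the angle of progression (AoP) — the clinical index of
fetal head descent in labor — from 2-D transperineal ultrasound frames.
The measurement has three stages: semantic segmentation of the pubic
symphysis (PS) and fetal head (FH), constrained least-squares ellipse
fitting to each segmented region, and a three-key-point angle
construction. A synthetic phantom generator provides exact ground truth
for every stage, so the whole pipeline is testable without clinical data.

## Geometric measurement

**Ellipse fitting.** Boundary pixels of the largest 8-connected component
of each class (a component pixel with at least one 4-neighbor outside the
component; the image border counts as outside) are fitted by direct least
squares on the algebraic conic residual

    F(a, x) = A x² + B xy + C y² + D x + E y + F,

minimizing `Σ F(a, xᵢ)²` under the quadratic constraint `4AC − B² = 1`,
which forces an elliptical solution. The generalized eigenproblem is
solved in the numerically stable 3+3 block form (Halir–Flusser), with the
data centered on its centroid for conditioning. Fitting uses boundary
pixel centers without smoothing; restricting to the largest component
suppresses spurious islands a segmenter may emit.

**Key points.** The PS conic is converted to center/axes/orientation
form; the major-axis endpoints are `center ± a·(cos θ, sin θ)`. The
*inferior* endpoint `Lp` is the one nearer the FH-ellipse center (the
inferior symphysis end abuts the descending head); this rule is rotation-
invariant, unlike an image-axis rule, which matters under rotation
augmentation. Ties break to larger x, then larger y. The tangent points
from `Lp` to the FH ellipse are computed in closed form via the polar
line (chord of contact) of `Lp`; a brute-force scan over densely sampled
boundary points is retained as a test oracle only. Of the two tangency
points the pipeline keeps the one maximizing the angle ∠(Up, Lp, T) —
the clinical tangent runs along the leading head contour, and the
max-angle rule reproduces it in every phantom layout while remaining
orientation-invariant. A `tangent_rule="right-x"` option selects the
larger-x candidate instead (the literal reading for standard acquisition
orientation); the two coincide there.

**Angle.** `AoP = arccos[(Up−Lp)·(Tp−Lp) / (‖Up−Lp‖‖Tp−Lp‖)]` in
degrees. The quantity is invariant under rotation, translation, and
uniform scaling, so the pixel-coordinate convention (0-based indices,
x rightward, y downward, geometry on pixel centers) is internally
consistent.

**Known constraint of the rule set.** With `Lp` defined by proximity to
the head center and the max-angle tangent rule, the computed angle is
always ≥ 90°: writing δ for the PS-axis tilt against the direction to the
head center (|δ| ≤ 90° under the proximity rule) and ψ < 90° for the
tangent half-cone angle, the construction yields 180° − ||δ| − ψ|.
Clinical angles below 90° (high head station) arise exactly when the head
center lies nearer the superior endpoint — the configuration the
proximity rule relabels. The phantom generator therefore produces angles
in ≈[115°, 170°]; angles below 90° require the `right-x` tangent rule
together with anatomically labeled endpoints, which the synthetic ground
truth does not exercise.

## Network

The dual-branch segmentation network is a U-shaped encoder–decoder with
an auxiliary low-resolution decoder. For base width `b` (default 32;
tests and the scaled harness use 8):

* shared encoder of five double-conv blocks (3×3 conv + group norm +
  ReLU, twice), widths `b…16b`, 2×2 max pooling after the first four, so
  the bottleneck is at 1/16 resolution;
* a lower branch of four double-conv blocks halving widths
  (`16b → b`) at constant 1/16 resolution, with a 1×1-conv + softmax
  head producing a coarse 3-class probability map;
* an upper branch whose first block fuses the pre-pool level-4 encoder
  skip with the upsampled, conv-projected first lower block, and whose
  remaining three blocks each fuse the matching encoder skip, the
  upsampled previous block, and an attention-gated copy of the matching
  lower-branch output. The gate is additive (1×1 projections, ReLU, 1×1
  to one channel, sigmoid) and is driven by a deformable-convolution
  projection of the previous block, letting the sampling grid follow the
  curved targets. Offset-predicting convolutions are zero-initialized so
  training starts as ordinary convolution.

The loss is `w_U·Dice(upper) + w_L·Dice(lower)` with `w_U = 1`,
`w_L = 0.2`, where Dice pools the two foreground classes in a single
ratio (the background channel is excluded). The lower-branch target is
the mask downsampled 16×. A plain per-cell majority vote would erase the
thin PS entirely at small frames (the structure never covers half of a
coarse cell), turning the auxiliary loss into an anti-signal for the
class; the downsampler therefore assigns a cell to PS whenever PS covers
at least 1/8 of it and votes by majority otherwise.

Ablation flags reproduce the reduced variants: no attention gates
(projected lower features are concatenated instead of gated), no lower
branch (the bottleneck feeds the first upper block directly; a plain
U-Net-like decoder), and no deformable convolution (ordinary 3×3 in the
gate path). Parameter counts are strictly ordered
no-lower-branch < no-gates ≤ full, and the no-deformable variant equals
the full model minus its offset-predictor parameters.

The numerical core (`aopnet.nn`) is a compact reverse-mode autograd over
NumPy float32 arrays — im2col/GEMM convolutions, group norm, bilinear
resampling expressed as separable interpolation matrices, and Numba
kernels for the deformable sampling gather/scatter. Loss reductions
accumulate in float64, which makes the weighted-sum decomposition of the
collaborative loss exact to machine precision. Training protocol
defaults follow the full-scale recipe: Adam at learning rate 1e-4,
Kaiming-initialized weights, 200 epochs, batch size 1, rotation (±30°)
plus horizontal-flip augmentation applied identically to image, mask,
and key points, and patient-grouped 5-fold cross-validation in which all
frames of a patient fall on one side of every split.

## Synthetic phantoms

Each phantom places two ellipses in a fan-shaped speckled field: a small
bright filled blob (PS) and a large bright rim with a darker interior
(the skull echo). Layouts are rejection-sampled: the head right of
center with a near-horizontal long axis; the symphysis up-and-left of
the head at 1.25–1.9 head-radii with its long axis pointing at the head
±57°; both ellipses fully inside the frame *and* fully inside the fan
sector (apex half the frame height above the top edge, 85° opening, with
a 2° angular margin) — a structure outside the insonated sector would be
rendered black while still carrying a mask label, which makes it
unlearnable; interiors disjoint; the
analytic angle within [60°, 170°]; and the inferior PS endpoint kept at
quadratic form ≥ 1.15 of the head ellipse — the soft-tissue gap seen in
real anatomy, without which the tangent direction is numerically
hypersensitive to sub-pixel endpoint error. Axis ranges are defined at
the reference 512-wide frame (PS semi-axes 25–45 × 8–16 px, FH 90–150 ×
70–120 px) and scale linearly with frame width, as does the rendering
blur, so a small phantom is a photometrically consistent shrink.

Intensity levels are tissue 0.32 plus half-normal speckle (σ = 0.13),
rim amplitude 0.75, PS amplitude 1.5 — the symphysis is rendered as the
uniquely brightest echo. This mirrors its strongly echogenic clinical
appearance and, at the small training frames, is what makes the
foreground-pooled Dice loss able to pick the class up inside a short
schedule: with PS and rim at near-equal brightness the two structures
are locally ambiguous at 2–3 px width, and the minority class needs
roughly 30 optimizer passes per image to emerge, versus about 6 with the
brightness separation (a single-image overfit reaches PS Dice 0.96
either way, so the limit is optimization speed, not representability).

The ground-truth mask rasterizes the exact ellipse interiors at pixel
centers; key points and the reference angle are computed analytically
from the exact parameters through the same geometric construction the
measurement applies to masks — an independent oracle for the full
pipeline. On exact rasterized masks the measured angle agrees with the
analytic one to ≤ 2° at the default 512 × 384 frame (mean ≈ 0.4°); at
the 128 × 96 training frame the rasterization floor is ≈ 2° mean, which
bounds what any segmenter can achieve there.

What the phantoms do *not* model: acoustic shadowing, depth-dependent
attenuation and resolution, probe-pressure deformation, neighboring
bony or soft-tissue structures, and the full intensity overlap between
the symphysis and the skull rim. Passing the end-to-end recovery test
therefore demonstrates that the architecture, loss, and geometry are
implemented correctly and can be trained — not that the trained weights
transfer to clinical images.

## Scaled experimental harness

The acceptance-scale experiment runs the full protocol at reduced size:
200 phantoms at 128 × 96 over 20 synthetic patients, a patient-grouped
80/20 split (fold 0 of the seeded 5-fold assignment), base width 8, and
15 epochs. Two settings are calibrated to this shorter schedule and
documented as such: the learning rate is 1e-3 (a probe grid showed 3e-3
collapses the PS channel and 1e-4 barely moves in 2,400 steps; the
full-scale default remains 1e-4), and problem sizes were chosen so the
whole run trains in minutes on one CPU. Everything else — optimizer,
loss weights, augmentation, initialization, split discipline — follows
the full protocol.

## Numerical choices and degenerate inputs

* Conic normalization `4AC − B² = 1` is enforced on every fitted conic
  (checked to 1e-8); sign fixed so A > 0, making the algebraic residual
  negative inside the ellipse.
* Circles (axes equal within 1e-9 relative) take orientation θ = 0 so
  output is deterministic.
* Fewer than 5 boundary points, collinear scatter, or a non-elliptical
  eigen-solution raise a fit error, which the mask-level entry point
  converts to a per-image failure status (`ps_fit_failed`,
  `fh_fit_failed`, `lp_inside_fh`, `empty_class`) rather than an
  exception; batch prediction never aborts on one bad frame.
* The empty-union Dice (class absent from both masks) is defined as 1;
  the average surface distance is undefined (error) when a class has an
  empty surface, and per-image values are averaged over the images where
  the metric is defined.
* The angle-difference summary uses the population (÷ n) standard
  deviation; the sample form is available by argument. `dice_all` pools
  PS and FH counts in one ratio (micro); per-class averaging is
  available as `aggregation="mean"`.
* All segmentation metrics are computed at the processing resolution of
  the masks given; reports record pixel units at that grid.

## Limitations

* The synthetic angle range ([≈115°, 170°]) does not cover high-station
  geometries (< 90°); see the geometric note above.
* The phantom appearance model is a visual stand-in; no claim of
  transfer to clinical ultrasound is made or tested.
* The parameter count of the full-width network is architecture-faithful
  but not calibrated to reproduce any particular published size; gate
  internals follow the standard additive-attention convention.
* Checkpoints store float32 weights with the exact network configuration
  and refuse to load into a mismatched configuration rather than
  partially loading.
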