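# Methods

`kvtrack` implements a patient-specific, markerless prostate-tracking
pipeline for kilovoltage (kV) projection imaging on conventional
C-arm linacs. The central idea: everything needed to train a
segmentation network for a given patient already exists before their
first treatment — the planning CT and the physician's prostate contour.
Forward-projecting both volumes over the treatment arc yields synthetic
kV-like images paired with perfectly aligned prostate masks; a
conditional GAN trained on these pairs can then segment the prostate in
incoming projection images at any gantry angle, and the mask centroid
tracks the target without implanted fiducial markers.

Because clinical planning CTs and treatment kV images cannot ship with a
software package, the pipeline is developed and validated against a
synthetic digital-pelvis phantom with exactly known geometry. Every
stage is still the real algorithm; only the input data is synthetic.

## Coordinate conventions and beam geometry

Patient coordinates: `x` lateral, `y` superior–inferior (SI), `z`
anterior–posterior (AP); the isocentre is the origin. The gantry
rotates in the axial x–z plane about the SI axis. At gantry angle θ the
unit vector from isocentre to the x-ray source is
`e(θ) = (cos θ, 0, sin θ)`, so at θ = 0 the source lies on the +x axis.
The flat detector sits perpendicular to the beam axis at distance SID
from the source (SAD from source to isocentre), with in-plane axes
`u(θ) = (sin θ, 0, −cos θ)` (transverse, reported as AP/LAT because the
two directions alternate as the gantry turns) and `v = (0, 1, 0)` (SI).

A small 3D displacement `(x̂, ŷ, ẑ)` of a point near the isocentre moves
its detector projection by

    (û, v̂) = SID / (SAD − (x̂ cos θ + ẑ sin θ)) · (x̂ sin θ − ẑ cos θ, ŷ)

which the package exposes as `project_shift`. Its small-shift limit is
pure magnification by M = SID/SAD, and motion along the beam axis is
invisible at θ = 0 — both covered by tests. Detector measurements are
converted to mm of motion at the isocentre plane by
`pixels × pitch × SAD/SID`; with the clinical defaults (pitch 0.39 mm,
SAD 1000 mm, SID 1500 mm, M = 1.5) one detector pixel corresponds to
0.26 mm at the isocentre, and all tracking errors are reported on that
scale.

Default geometry: SAD 1000 mm, SID 1500 mm, 512 × 512 detector at
0.39 mm pitch. `desk_geometry(n)` shrinks the pixel count while
preserving the ~200 mm physical panel (pitch grows accordingly), so
reduced-resolution runs see the same field of view. Desk-scale work in
the tests and the acceptance script uses 64 × 64 (3.12 mm pitch,
2.08 mm isocentre pixels).

## Digital-pelvis phantom

The phantom is an additive attenuation model on a regular voxel grid
(linear attenuation in consistent mm⁻¹ units; no Hounsfield calibration,
since the projector only forms line integrals):

* a soft-tissue body ellipsoid (default semiaxes 85 × 90 × 80 mm,
  μ = 0.020 mm⁻¹);
* an ellipsoidal prostate (default semiaxes 20 × 15 × 18 mm,
  μ = 0.026 mm⁻¹) strictly inside the body;
* bone-like ellipsoids (two femoral heads, one sacral block,
  μ = 0.040–0.045 mm⁻¹) that give each projection angle a distinct
  appearance;
* optional spherical gold-marker surrogates (default radius 0.6 mm,
  μ = 0.30 mm⁻¹) inside the prostate. Markers are spheres rather than
  cylinders: their orientation is irrelevant to the masking/inpainting
  logic the pipeline needs them for.
* mild seeded Gaussian texture (σ = 2% of the soft-tissue value, clipped
  at 0) inside the body, so that projections are not piecewise flat and
  a network cannot trivially memorise constant regions.

The binary prostate contour marks exactly the voxels whose centres fall
inside the prostate ellipsoid, so its voxel count converges to the
analytic ellipsoid volume as spacing shrinks — a tested invariant. The
default grid is 64³ at 3 mm; the heavy full-arc cardinality runs use
40³ at 4.5 mm, which spans the same anatomy at lower resolution.

## Forward projector

DRRs are computed as cone-beam line integrals: for each detector pixel,
the ray from the point source through the pixel centre is clipped to the
volume bounding box and sampled by the midpoint rule at a uniform step
of half the minimum voxel spacing (the final step is shortened so the
quadrature covers the clipped segment exactly), with trilinear
interpolation of the attenuation grid. The kernel is JIT-compiled
(numba) and single-threaded; a full 64 × 64 arc over 360 angles takes a
few seconds on one CPU core.

Projector correctness is established against an independent
dense-sampling integrator (scipy map_coordinates at 0.06 mm steps):
agreement within 2% relative error on randomly drawn rays, plus exact
linearity in the volume and rotation equivariance (projecting a volume
rigidly rotated by φ about the SI axis equals projecting the original at
θ + φ, up to interpolation error).

Volumes are cropped to the bounding box of their nonzero support before
projection during training-set assembly; this leaves the line integrals
unchanged and makes contour projections (a small object in a large
grid) several times cheaper.

## Training-set synthesis and augmentation

Before training, the planning volumes are perturbed by rigid transforms
sampled uniformly per component: translations up to 10 mm and rotations
up to 10° (about the isocentre, applied in x→y→z order), emulating
setup error and whole-patient motion. Uniform sampling is the simplest
reading of an "up to" bound; the draws are recorded in the training
manifest for auditability. Each sampled transform is applied
identically to the CT and the contour; both are resampled trilinearly
(zero fill outside the grid) and projected over the full arc. With the
default 100 transforms and a 1° step this yields 36,000 paired images.

The contour projection is binarised at a projected path length of
0.1 mm, which suppresses trilinear interpolation fringe while keeping
every ray that meaningfully crosses the prostate. Anatomy DRRs are
normalised to [0, 1] by a single set-wide maximum (not per image), so
inter-angle intensity relationships survive normalisation.

Deformable augmentation is deliberately out of scope: the pipeline
models rigid whole-patient motion only.

## Ground-truth construction for test images

Two test-set modes mirror the two ways ground truth can be built for
clinical kV images:

* **masked** — markers are embedded in the CT, projected, then removed
  from the projections by harmonic inpainting and Poisson noise is
  added; the ground-truth mask is the marker-free contour projection.
  Marker footprints are known analytically here (projected sphere,
  dilated by 1 pixel); no image-based marker detection is performed.
* **markerless** — clean projections are shifted in 2D according to a
  known 3D couch shift through `project_shift`; the ground truth is the
  identically shifted contour projection. This emulates ground truth
  derived from CT↔CBCT soft-tissue registration, where only an average
  prostate position is known.

Harmonic inpainting solves the discrete Laplace equation (4-neighbour
stencil in 2D, 6-neighbour in 3D) over the masked pixels with Dirichlet
boundary values from the adjacent unmasked pixels, via a sparse direct
solve (conjugate gradients above 20,000 unknowns), with a verified
residual below 1e-6 of the image maximum. Constants and linear ramps
are reproduced exactly, and the discrete maximum principle holds: filled
values never leave the range of their boundary values. Masks touching
the image border are rejected (the boundary condition is undefined).

Poisson noise uses a scale-to-photon-count parameterisation: pixel p
becomes `Poisson(p/max · N) · max/N` with N = 10⁴ photons at the
brightest pixel by default. The expectation is unchanged and relative
noise shrinks as 1/√N; N is configuration, not physics.

## The conditional GAN

Generator G: an encoder–decoder UNet with skip connections; 4 × 4
convolutions, stride 2, LeakyReLU(0.2) encoder, ReLU decoder, instance
normalisation on all but the outermost layers, sigmoid output bounded
in [0, 1]. Channel widths double per level from `base_channels`,
capped at 8×. Discriminator D: a PatchGAN that scores overlapping
patches of the 2-channel (image, mask) pair through three convolution
levels; its output grid is strictly smaller than the input.

Training minimises

    G* = arg min_G max_D  L_cGAN(G, D) + λ · L_L1(G),   λ = 100

with `L_cGAN = E[log D(x,y)] + E[log(1 − D(x,G(x)))]` and
`L_L1 = E‖y − G(x)‖₁`. The generator's adversarial term uses the
standard non-saturating form `−log D(x, G(x))`; the λ·L1 term is
unchanged, and with λ = 100 it dominates, so training behaves like a
regression stabilised by the adversary. Discriminator scores are
clamped to [1e-7, 1 − 1e-7] before logarithms. Parameters are
initialised from a zero-mean normal (σ = 0.02, seeded); optimisation is
Adam at learning rate 2e-4 with GAN-customary moments (0.5, 0.999),
batch size 4, 20 epochs by default, alternating one D and one G update
per batch. Training is deterministic given the seed.

The networks run on a compact reverse-mode automatic-differentiation
engine written for this package (NumPy arrays, im2col/col2im
convolutions over BLAS matmuls, float64). It implements exactly the
operations the two networks need, and every operation's gradient is
verified against central finite differences in the test suite. With
λ → ∞ the generator's update direction provably reduces to pure-L1
regression (cosine similarity > 0.99, tested).

Two conditioning measures stabilise training on imbalanced binary
targets (the prostate occupies only a few percent of each image, so the
L1 term's optimal *blind* output is all-background, an attractor in
which the sigmoid saturates and gradients die):

* the generator standardises its input through a fixed affine layer set
  from the training set's mean and standard deviation (the [0, 1]
  min–max interface normalisation leaves anatomy compressed into a
  narrow high-intensity band with little contrast) and its output bias
  is initialised at the logit of the foreground rate, so training
  starts at the base rate rather than at 0.5;
* the trainer detects collapse — after three epochs the generator's
  predictions are probed and, if essentially nothing exceeds the
  segmentation threshold, the attempt is abandoned and training
  restarts with a reseeded initialisation (up to six restarts, all
  derived deterministically from the seed, in the spirit of `n_init`
  restarts in clustering). With input standardisation in place,
  restarts are a rarely-needed safety net.

A scikit-learn-style estimator, `CGANSegmenter` (fit/predict/
predict_proba, `get_params`/`set_params`), wraps the same training loop
for use in sklearn pipelines and model selection.

### Desk-scale training conditions

The learnability check trains on the 64 × 64 desk geometry with an
eight-angle arc (45° step) and the standard 100-fold augmentation —
800 pairs — for 10 epochs (2000 optimiser updates) at the default
optimiser settings. Evaluation uses the eight unaugmented held-out
angles midway between training angles (22.5° offsets). This
configuration reaches a held-out mean DSC of ≈ 0.88 and sub-pixel mean
centroid error in about four minutes on one CPU core, consistently
across seeds. Fewer optimiser updates (tens of augmentations or fewer
at this angle count) leave the generator in the all-background local
minimum described above, so the step budget matters more than the
image count.

## Tracking workflow

At inference each incoming kV-like image (normalised with the training
set's scale) passes through the generator; the prediction is binarised
at 10% of the output range (an absolute 0.1 cut, since outputs live in
[0, 1] — thresholding against a per-image maximum was rejected because
an all-noise prediction would then always produce a mask); 8-connected
components are labelled and only the largest survives (ties break
towards the component containing the smallest row-major pixel index);
its centroid is the arithmetic mean of member pixel coordinates.
Empty predictions are flagged and excluded from summary statistics
rather than imputed; the dropped-frame count is reported.

Centroid error is predicted minus ground truth, converted to isocentre
mm, with the detector-u component reported as AP/LAT and v as SI.

## Evaluation statistics

* Dice similarity coefficient `2|A∩B| / (|A|+|B|)`; undefined (error)
  when both masks are empty.
* Mean surface distance: symmetric average of the two directed mean
  nearest-boundary distances; boundaries are member pixels with a
  non-member 4-neighbour; distances are Euclidean in isocentre mm.
* Summaries per direction: mean, sample SD, MAD, and 5th/95th
  percentiles with linear interpolation. MAD here is the mean of
  absolute errors (mean absolute error), not the median-based variant.
* Pearson correlation and Bland–Altman agreement (bias ± 1.96 SD of the
  differences) between observed motion and centroid error. Observed
  motion, where needed, is the ground-truth centroid displacement from
  the arc's reference position per direction.
* Per-imager-angle tables of means and 5/95th percentiles, with empty
  bins reported as such (sample counts per angle are generally
  variable).

Dice, MSD, centroid and the summaries are tested against brute-force
enumerations on seeded random masks.

## What the phantom does and does not show

Passing tests on the phantom demonstrate that the pipeline's machinery
is correct end to end: geometry, projection, augmentation alignment,
inpainting, objective, optimisation, thresholding, component selection,
and statistics all compose to track a target whose true position is
known exactly. The phantom does not contain scatter, beam hardening,
detector response, collimation, anatomical deformation, bladder/rectum
filling changes, or genuinely low-contrast boundaries of real pelvic
anatomy — so phantom accuracy numbers say nothing quantitative about
clinical accuracy, and the package makes no such claim. Clinical-scale
accuracy requires patient data and is outside what an offline synthetic
study can establish.

## Numerical choices and degenerate inputs

* Ray step: half the minimum voxel spacing, midpoint rule, shortened
  final step; rays missing the volume give exactly 0.
* Laplace solver: direct sparse solve up to 20,000 unknowns, conjugate
  gradients beyond; residual tolerance 1e-6 of image max, enforced.
* Interpolation: trilinear everywhere (volume resampling, image
  shifting), zero fill outside grids; identity transforms short-circuit
  to bit-exact copies.
* Thresholds: mask binarisation at 0.1 mm projected path; segmentation
  threshold 0.10 of output range; both configurable.
* Empty masks: centroid and MSD raise; tracking converts these into
  flagged, excluded records.
* Determinism: every stochastic stage takes an explicit seed
  (numpy Generator); fixed seeds reproduce volumes, manifests, training
  histories and summaries bit-for-bit in a fixed environment.

## Known limitations

* 2D only: the tracker reports detector-plane positions; inferring 3D
  target coordinates from 2D segmentations is explicitly future work.
* The phantom's realism is deliberately minimal (see above).
* The marker-masking path uses analytically known marker positions;
  detecting markers in images is a separate problem the package does
  not address.
* The NumPy training engine is CPU-bound and intended for the reduced
  problem sizes used here; full 512 × 512 clinical-scale training would
  require a GPU framework.
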