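# Methods

`spineridge` quantifies dendrite and dendritic-spine morphology in 2-D
fluorescence micrographs through a cascade of five stages: morphological
preprocessing, density-ridge backbone extraction, perpendicular boundary
location, spine detection and measurement, and twin-SVM shape
classification on Hu-moment features. This note describes each model, the
parameters that matter, the synthetic data the package is validated on,
and the numerical choices made where the design was open.

## Preprocessing

The input is a grayscale raster normalized to [0, 1] with a physical pixel
pitch (default 0.24 µm/px, the pitch of 63x confocal imaging of
GFP-labelled cortical neurons; z-stacks are collapsed by
maximum-intensity projection). Photomultiplier acquisition produces
salt-and-pepper noise, so the chain is: 3x3 median filter, optional
Perona–Malik anisotropic diffusion (exponential conductance, explicit
4-neighbour scheme, stable for dt ≤ 0.25), grayscale opening (disk of
radius 2 by default; a white top-hat is available instead), Otsu
thresholding, and a 3x3 majority vote (a pixel survives iff its 3x3
window holds more than `n` positives, centre included).

The pipeline derives **two** masks from one threshold. The backbone mask
uses opening + a strict majority (n = 4): protrusions thinner than the
structuring element are deliberately erased so they cannot disturb ridge
extraction. The spine mask binarizes the **unsmoothed** image with a
lenient majority (n = 2): both the 3x3 median and the opening erase 1–2 px
spine necks, which are precisely the structures the spine stage must keep;
the lenient majority still removes isolated impulse pixels.

## Backbone as a density ridge

Foreground pixels are treated as samples of a 2-D density; the backbone
is the one-dimensional ridge of a Gaussian kernel density estimate
(bandwidth matrix H = h²I, default h = 3 px, about one tube half-width;
samples are deterministically thinned to at most 20,000). A point lies on
the ridge where the density gradient is orthogonal to the
strong-curvature Hessian eigenvector.

Modes are found by mean-shift ascent from a deterministic subsample of
starting points (ascent is monotone in the density; modes closer than
10x the tolerance are merged). From each mode a predictor–corrector
tracer follows the ridge bidirectionally: the predictor advances one step
(default 1.5 px) along the weak-curvature eigenvector, the corrector is
subspace-constrained mean shift (mean-shift displacement projected onto
the strong-curvature eigenvector), which converges to the ridge without
drifting along it. Tracing stops when the density falls below the
threshold theta (default 0.1 x the median mode density), on leaving the
padded image domain, or when progress stalls (no elongation, e.g. an
isotropic blob). A trace seeded on a side structure runs onto
already-traced ridge; the overlap is trimmed and only novel runs kept.

Curves are split wherever the density dips below theta, and junctions are
resolved by angular continuity: at a point where a curve endpoint meets
another curve, the pair of incident branches closest to 180° is kept as
the main through-curve; other branches are detached, and detached
branches shorter than 15 px are deleted. These short spurs are exactly
the ridge remnants of attached spines. In the full pipeline, any
remaining curve shorter than 25 px is also dropped before boundary
location — genuine side-dendrites are longer, and keeping spine-scale
ridge fragments would let the boundary stage swallow the spines they came
from.

All backbone steps are deterministic given the mask and configuration.

## Boundary and dendrite region

At each backbone point the local line direction is the eigenvector of
the Gaussian-smoothed image Hessian (scale 2 px) with the smallest
absolute eigenvalue; degenerate (blob-like) points fall back to the
backbone tangent. Marching perpendicular in 0.25 px steps with bilinear
interpolation, the boundary is where the intensity first crosses the
threshold alpha; the crossing is refined by linear interpolation between
the bracketing samples, which removes the half-step bias (recovered
half-widths on a noiseless Gaussian tube are accurate to ~0.001 px). The
default alpha is the Otsu threshold of intensities sampled along the
perpendicular profiles. Width = left + right crossing distance x pixel
pitch; points whose own intensity is below alpha are flagged.

A ray through an attached spine never drops below alpha, so its raw
half-width is an outlier. Because dendrite caliber varies smoothly, the
per-ray half-widths used for the dendrite *region* are capped at the
per-curve median + 0.5 px and median-smoothed along the curve (window 15,
wide enough that the several consecutive rays crossing one wide spine
cannot dominate the window). The region itself is a distance field — a
pixel is dendrite iff its distance to the nearest backbone point is
within that point's side-resolved smoothed half-width plus a 1.5 px
margin — rather than a filled polygon, which eliminates rasterization
slivers along the rails. The margin absorbs the ~1 px dilation introduced
by the majority vote on the spine mask. (A quad-fill polygon mask per the
boundary rails is also provided.)

## Spine detection, measurement, classification

Candidates are 8-connected components of (spine mask AND NOT dendrite
region), after a 3x3 closing that reconnects noise-fragmented
protrusions. A component must have >= 4 px, reach deeper than 1 px beyond
the boundary (shallower components are boundary discretization residue),
and approach the region edge within the attachment gap (2 px + the
region margin); its attachment is the nearest marched boundary point.

Length is the geodesic distance through the 8-connected pixel graph
(diagonal = sqrt 2) from the attachment-adjacent pixel to the farthest
pixel, counted inclusively (a single-pixel region has length 1 px); this
is robust to curved spines, unlike the Euclidean tip distance. Area is
the pixel count. Both are reported in µm / µm². Dendrite length is the
summed polyline arc length of the backbone. A min–max normalization
N = R/(L−S) is provided for comparing measurement distributions.

Shape features are the seven Hu invariants of the binary region mask,
computed from normalized central moments (x = column, y = row), scaled as
f_i = sign(H_i) · log10(|H_i| + 1e-30) to compress their ~10-order
dynamic range (an intensity-weighted variant is available). The features
are invariant to translation, rotation and scale up to discretization.

The twin SVM fits one plane (or Gaussian-kernel surface) per class by
solving two small convex QPs; prediction is by the nearer plane,
normalized by the plane norm (kernel mode: the kernel-metric norm of the
coefficient vector), ties to the positive class. The duals are
box-constrained QPs solved by spectral projected gradient
(Barzilai–Borwein) with a projected-Newton active-set phase and cyclic
coordinate-ascent polish; termination is on a scale-relative KKT
residual, and a solve that stalls near the optimum returns its best
iterate with a warning rather than failing (model quality is controlled
by held-out accuracy; on small well-conditioned problems the solver
agrees with a generic reference QP solve to ~1e-14 in objective). Matrix
inverses carry a ridge term: 1e-8 in linear mode, 1e-2 in kernel mode,
where the Gram normal matrices are low-rank and a small ridge produces
duals no solver can meaningfully polish; held-out accuracy is flat across
ridge values from 1e-4 to 1e-1.

Pseudo-spines (noise and membrane-texture protrusions) are removed by a
binary kernel TSVM; surviving spines are classified
mushroom/stubby/thin. Multiclass uses **one-vs-one** pairwise models
combined by majority vote with a distance-ratio tie-break: one-vs-rest
distances are not commensurable across models (each surface pair has its
own scale) and validated consistently worse. Classifier models z-score
the features internally (the scaler is serialized with the model) because
the raw log-Hu features differ in spread by a factor of ~25, which breaks
the median-heuristic kernel width. The pairwise kernels use 2x the
median-heuristic width (selected by held-out accuracy on several seeded
datasets). Models ship as JSON; no pretrained weights are distributed —
training data comes from the synthetic generator or user-provided labelled
masks.

## Synthetic data

The generator has two layers. The **point model** draws samples from a
mixture: with probability 1−eta uniform clutter on the image rectangle,
otherwise a point on dendrite curve i (chosen with weight w_i, parameter
uniform on the curve) plus isotropic Gaussian noise (sigma, default 2 px).
Its analytic density is available for validation (empirical histograms
correlate with it at r > 0.95).

The **image renderer** draws each curve (straight segment or cubic
Bézier) as a tube with Gaussian cross-section, peak 1 and half-max at the
nominal half-width (default 3 px = 0.72 µm), stamps spines, then adds
Gaussian background noise of amplitude 1/SNR and salt-and-pepper noise,
and clips to [0, 1]. Spine classes follow the field's taxonomy, with
geometry ranges chosen for 0.5–2 µm spines at 0.24 µm/px: thin = narrow
capsule (length 8–20 px, width 1–2 px), stubby = short wide bump (length
2–5 px, width 3–6 px, length <= 1.5 x width), mushroom = thin neck
(3–8 x 1–2 px) with a disc head (radius 3–6 px, always wider than the
neck). Pseudo-spines are gently but consistently curling chains of small
discs (optionally with a counter-curling branch): the steady curvature
prevents a chain from straightening into a thin-spine mimic, and the
gentle turn rate keeps it an open arc that cannot smooth into a
stubby-like blob. Nothing is rendered narrower than 1.5 px — a
diffraction floor; a sub-pixel-wide capsule would otherwise rasterize
into a broken pixel chain no microscope produces. Ground truth
(centerlines, per-spine masks/labels/bases, clutter mask) is emitted
aligned with the image.

The classifier training set is not drawn as idealized canvas shapes:
each training shape is rendered on a miniature noisy tube and pushed
through the same thresholding / majority / dendrite-subtraction chain the
detection stage applies, with the truncation depth and the boundary's
sub-pixel jitter randomized as augmentation. Training on the deployment
distribution is worth 15–30 % deployed accuracy relative to clean canvas
shapes.

What the generator does **not** model: optical PSF anisotropy and depth
attenuation, fluorophore density variation (all structures render at peak
1), overlapping or touching spines (the cascade contains no de-clumping
stage, so benchmark layouts space objects apart), and 3-D structure.
Passing benchmarks on this data shows the cascade's geometry and
classification logic are correct under the stated noise model, not that
the fixed defaults transfer to any particular microscope without
recalibrating the threshold, bandwidth and alpha.

## Benchmark problem sizes

The built-in evaluation (shared by the acceptance tests and
`scripts/acceptance.py`) uses sizes chosen to exercise every stage while
keeping a full run in a few minutes on one core: backbone recovery on ten
200x200 tube images (straight / curved / Y-branched at SNR 8, plus one
image with three planted 13 px perpendicular spurs); spine
detection/filtering on two 530x530 two-tube images with 10 spines + 10
clutter chains each (SNR 10, 1 % salt-and-pepper); classification with
200 training and 100 held-out shapes per class; Hu stability on 50
chiral four-lobe blobs of ~30 px lobe radius (shapes are resampled if any
invariant lands within numerical noise of zero, since a multiplicative
stability check is only meaningful for invariants bounded away from
zero); solver equivalence on 20 random binary problems (n ≤ 30, dim ≤ 7)
against an L-BFGS-B reference.

## Known limitations

- Spines shorter than ~2.5 px beyond the boundary (the smallest stubby
  class members) are sub-detectable by any boundary-subtraction scheme
  with a ~1 px margin; the detection benchmark's residual misses are of
  this kind.
- The boundary march assumes an approximately convex tube cross-section;
  strongly varicose dendrites would defeat the median-based caliber cap.
- Hu features describe a region's silhouette only; a chance protrusion
  shaped exactly like a spine is accepted by construction.
- The KDE ridge bends toward large attached structures (e.g. mushroom
  heads surviving the opening); the curve-length filter removes the
  resulting fragments but the main curve can locally deviate by ~1 px.
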