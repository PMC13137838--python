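# Methods

`junctiondyn` quantifies the morphology and dynamics of endothelial
monolayers from junction-marker fluorescence images (VE-cadherin-type
staining) and related recordings: per-cell shape, junctional protein
concentration, border-displacement rates, field-level orientation
coherency, post-ablation recoil mechanics, and trans-endothelial
resistance (TER) normalisation.  Because such studies rarely deposit raw
microscopy, every stage is validated against a synthetic generator with
exact ground truth; this note describes the models, the defaults and why,
and what the synthetic validation does and does not establish.

## Conventions

Images are `(row, col)` arrays; stacks are `(frame, row, col)`.  Geometry
is computed in pixels and converted to micrometres only when reported,
via `pixel_size_um`.  Orientations are in degrees measured from the +x
(column) axis towards +y (row), reported in the half-open interval
[-90, 90) (period 180).

## Synthetic monolayers

Confluent endothelium is emulated as an anisotropic Voronoi tessellation:
seed points on a jitter-perturbed grid (jitter uniform within ±0.35 of the
grid spacing — large enough to break the grid symmetry, small enough to
keep cells convex-ish, as in confluent monolayers), assigned per pixel by
the nearest seed under a per-cell metric rotated to the cell's programmed
orientation and scaled area-preservingly by its aspect ratio.  Per-cell
orientations are drawn from a von Mises distribution on the doubled angle,
so `orientation_concentration = 0` is exactly isotropic.

The junction channel renders a band with a Gaussian cross-profile around
the 1-px inter-label boundary: intensity at distance d from the border is
`background + amplitude * exp(-d^2 / (2 sigma^2))`, so the integral across
the band per unit border length is `amplitude * sigma * sqrt(2 pi)`
(verified to 2% against the rendered images).  Camera noise is
scaled-Poisson shot noise followed by additive Gaussian read noise, the
standard fluorescence camera model; the source study states no noise or
PSF parameters, so the defaults here are fixture choices, not claims about
any particular microscope.  Defaults (256x256 px at 0.53 um/px, 20 cells)
put the density near 1.1e5 cells/cm^2, inside the 7-12 x 10^4 cells/cm^2
range typical of confluent HUVEC cultures; `DENSITY_PRESETS` expose
sub-confluent (7.5e4), confluent (9.5e4) and dense (11.5e4) presets.

Two field models are available.  By default exactly `n_cells` whole cells
tile the field (ground-truth label counts are then exact).  With
`crop_from_larger_field=True` the tessellation extends one cell ring
beyond the field, so edge cells are genuinely truncated by the crop as in
real microscopy; this is the right model when testing the density
estimator, which counts edge cells with weight 1/2 precisely because it
assumes truncation.

Motion programs move the tessellation seeds between frames and re-render:
`static` (zero motion), `rigid_translation` (fixed step per frame),
`border_jitter` (every cell steps a fixed programmed length in a random
direction each frame — a random walk whose per-frame true border
displacement is exactly the programmed amplitude), and
`intermediate_state`, which multiplies the jitter amplitude by
`1 - reduction` (default 0.20, the reported magnitude of the transient
displacement drop at shear onset) between the onset and release frames.
Because the programmed step length is exact, the ground-truth ratio of
displacement inside vs outside the window is exactly `1 - reduction`.

What the generator does **not** emulate: junction-associated intermittent
lamellipodia and VE-cadherin plaques, interrupted/reticular junction
morphologies, intensity heterogeneity along a border, photobleaching,
drift, and 3D structure.  Passing tests therefore demonstrate algorithmic
correctness on clean, convex-cell monolayers with Gaussian-profile
junctions — not performance on difficult real recordings.

## Segmentation

Junction images are ridge-like: bright bands along cell-cell contacts,
dark interiors.  The pipeline builds a flooding surface as a blend of the
smoothed intensity (weight 0.7) and a Hessian-eigenvalue ridge response
(Sato filter at `ridge_sigma_px`, weight 0.3), both min-max normalised.
The ridge term sharpens the basin divides onto the band centre-line; the
intensity term supplies deep, smooth catchment basins.  A pure ridge
surface was rejected because its response speckles in band-overlap
regions and fragments cells.  Markers are the h-minima of the surface
(`h_minima`, as a fraction of the normalised range, default 0.20), and a
marker-based watershed assigns one basin per cell.

Two merge steps follow.  Regions below `min_cell_area_px` (default 400 px,
about 112 um^2 at the default calibration — well below any plausible
endothelial cell) are merged into the neighbour with the longest shared
boundary, smallest region first.  Then boundary-evidence merging removes
watershed divides that lack junction signal: a divide whose mean image
intensity is below `boundary_merge_frac` (default 0.5) of the median
divide intensity crosses a dark interior rather than following a bright
band, and the two basins are merged, weakest divide first.

The final label image is canonicalised: the 1-px border skeleton is the
upper/left-side inter-label boundary, redundant border pixels (clumps at
vertices) are reassigned so that every interior skeleton pixel touches at
least two distinct cells, and cells remain 4-connected.  Cells touching
the field edge are flagged and excluded from per-cell morphometrics by
default, since truncated geometry biases perimeter and aspect ratio.

Segmentation accuracy is scored with a boundary F-measure at 1-px
tolerance.  Exact-pixel matching is ill-posed for pixel-thin boundaries —
the skeleton can legitimately sit on either flanking pixel of the same
interface, which caps exact-pixel F1 near 0.65 even for visually perfect
results — so a match is counted when a border pixel lies within 1 px of
the other set (`border_f1`, the convention of boundary-quality benchmarks).

Frame-to-frame cell matching is greedy maximum-overlap on the Jaccard
index (acceptance threshold 0.5, ties broken by lower cell id), which is
injective by construction.

## Morphometrics

Area is the pixel count times the pixel area.  The perimeter uses the
Crofton formula with 4 directions (`skimage.measure.perimeter_crofton`):
plain chain-length estimators carry a known positive digitisation bias on
smooth outlines (about +5% for a sqrt(2)-weighted chain on a digital
circle), while the Crofton estimator is accurate to well under 1% on a
radius-40 disk.  Aspect ratio and orientation come from the eigenstructure
of the second central moments of the filled mask with the unit-square
pixel correction (+1/12 per axis), which makes an axis-aligned a x b
rectangle come out at exactly a/b; `AR = sqrt(lambda_max / lambda_min)`.

The junctional concentration statistic follows the band-ROI convention:
the region of interest extends `w` pixels (default 5, Euclidean distance)
on each side of the segmentation line, and the statistic is the integrated
intensity in the ROI divided by the border length.  Border length is a
weighted pixel count: N pixels plus `sqrt(2) - 1` per purely diagonal
link, so a straight horizontal border of N pixels has length exactly N
(making the analytic uniform-image case `11 c` at `w = 5` exact) while
diagonal staircases are not over-counted.  The "total cell length" is
taken as the skeleton length rather than the ROI outline length, matching
the segmentation-line reading.  A border pixel contributes fully to each
adjacent cell's profile: the statistic is normalised per cell, so this
double counting across cells is intended.  Note that near tricellular
vertices a band pixel can lie within `w` of three (rarely four) cells'
borders, so the sum of per-cell integrated intensities equals the
field-level integral weighted by that per-pixel multiplicity — between 1x
and ~2.2x the field total on typical tessellations, not bounded by 2x.

Monolayer density is `(interior cells + edge cells / 2) / field area` in
cells/cm^2; the half weight is the standard unbiased correction for cells
truncated by the field boundary.

Analysis is strictly 2D; maximum-intensity projection across z is assumed
done upstream.

## Border displacement dynamics

The displacement readout reproduces the border-tracker convention: for
frame t, `d_mean(t)` combines the border distance to the previous and next
frames and the rate is `d_mean(t) / (2 dt)`.  The border distance d(A, B)
is the symmetric mean nearest-neighbour distance between the two skeleton
pixel sets (mean over A of the distance to the nearest pixel of B,
averaged with the reverse direction) — robust, parameter-free, and
symmetric, so the rate series is invariant under time reversal.  A
symmetric Hausdorff variant is available behind `metric="hausdorff"`.
Whether `d_mean` sums or averages the two neighbour-frame distances is
ambiguous in the d-mean/(2 dt) notation; both are supported
(`dmean_aggregation: sum | mean`), with `sum` the default so that rigid
motion of delta px/frame yields a rate of exactly
`delta * pixel_size / dt`.  Skeleton pixels within 1 px of the field edge
are excluded from the distance sets to avoid boundary artifacts.  The
first and last frames have no centred window and are flagged NaN.

The intermediate-state detector finds a contiguous stretch of clearly
reduced displacement.  Rates are first smoothed with a 3-frame moving
median (robust to single-frame noise, shifts window edges by at most one
frame).  The baseline is the median rate of frames not obviously reduced.
The reported window is the maximum-sum contiguous subarray of
`threshold - rate` with `threshold = (1 - f/2) * baseline` (f the target
reduction, default 0.20): frames well below the half-reduction threshold
pull the window in, frames above push it out, and single borderline
frames cannot split an otherwise clear window.  The half-`f` margin is
deliberate: the mean nearest-neighbour distance carries a small additive
quantisation floor, so a programmed 20% drop measures as roughly a 15-19%
drop; a per-frame threshold at the full `1 - f` would sit exactly on the
reduced level and detection would be a coin flip per frame.

Migration tracks: accumulated distance is the sum of step lengths,
Euclidean distance the straight-line start-to-end distance, velocity the
accumulated distance over elapsed time.

TER series are normalised as TER(t) / TER(t0) with t0 the treatment time;
the minimum and its time are reported.

## Orientation coherency

The structure tensor uses Gaussian-derivative gradients
(`gradient_sigma_px`, default 1) whose outer products are smoothed with a
Gaussian window (`window_sigma_px`, default 4; reflective boundaries).
The image-level tensor is the sum of per-pixel tensors over the interior
(a 3-sigma margin is excluded so padding never dominates), which weights
pixels by gradient energy — matching the dominant-direction behaviour of
the standard orientation-analysis plugins; a mean-of-pixelwise-coherency
alternative is exposed as `aggregation="mean_coherency"`.  Coherency is
`(l1 - l2) / (l1 + l2)` of the summed tensor, defined as 0 when the trace
is 0 (constant image); the dominant direction is the orientation of the
summed tensor's minor eigenvector (along the texture), so a grating whose
stripes run at theta reports theta.  The defaults were chosen for
cell-scale texture at 10-60x magnifications; the source plugin settings
are not stated anywhere, so these are this package's own choices.

## Ablation recoil and the Kelvin-Voigt fit

A kymograph is sampled bilinearly at 1-px steps along a scan line,
averaged over `width_px` perpendicular offsets; columns are frames.  The
recoiling edge is tracked per post-cut frame as the first position,
scanning outward from the cut point, where intensity recovers to half the
local pre-cut plateau, localised at sub-pixel precision by linear
interpolation (0.02 px error on rendered test movies).  Losing the edge
raises `EdgeLostError` carrying the failing frame and the partial
measurement.  The default frame interval is 0.2 s.

Displacement is fitted to the Kelvin-Voigt recoil
`L(t) = D (1 - exp(-t / tau))`, where D is the force/elasticity ratio
(the plateau) and tau the relaxation time; smaller tau indicates higher
pre-cut tension.  The model must keep its bounded form — an unbounded
exponential is not a valid substitute.  The least-squares fit uses
variable projection: for fixed tau the amplitude D is linear and solved in
closed form, leaving a 1-D minimisation over log tau (80-point log-grid
scan bracketing a bounded scalar minimisation, xatol 1e-12), which is
insensitive to initialisation and exact on noiseless data (relative error
~1e-10).  `converged` is flagged false when the record is shorter than the
fitted tau.  Optional residual-resampling bootstrap (seeded) yields
percentile confidence intervals; at 5% noise, 95% intervals cover the
truth for 94-96% of replicates.  The fit applies to whichever single
displacement series is supplied — one cut end or the opening width —
since the two differ only by a factor absorbed into D.

## End-to-end scenario and problem sizes

The `demo-intermediate-state` scenario generates a 45-cell, 384x384-px
time-lapse (30 frames, 1 min interval, 1 um/frame border jitter, moderate
Poisson/read noise) with the jitter reduced by 20% during frames 10-20,
segments every frame, computes the displacement-rate series, detects the
reduced window, and normalises the shear-rise TER preset (which plateaus
at 1.30 x baseline, the reported barrier strengthening under shear with
ROCK inhibition).  45 cells gives the detector enough borders per frame
that a 20% drop is detected with window Jaccard >= 0.8 across seeds;
validation replicate counts elsewhere (200 recoil replicates with 200
bootstrap resamples, 20-cell segmentation fields, 5 seeds) were sized to
keep the full validation suite around a minute of CPU while leaving
comfortable statistical margins.

## Known limitations

- Segmentation assumes a closed bright junction network; interrupted
  junctions produce merged cells by design (no gap-closing heuristic).
- The nearest-neighbour border distance underestimates true displacement
  for strongly deforming borders (correspondence-free matching) and
  carries a sub-pixel quantisation floor; relative comparisons are
  reliable, absolute rates are a lower-bound proxy.
- Relative junctional concentrations are comparable only at fixed
  magnification, since border length is measured in pixels by default
  (micrometre conversion available via `length_in_um`).
- The recoil tracker assumes a single monotonic edge along the scan line;
  it does not handle reclosure or multiple fragments.
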