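# Methods

This note documents the models and numerical choices behind `lsfmtrack`,
what the synthetic generator does and does not emulate, and the known
limitations of the approach.

## Coordinate and time conventions

Voxel indices are 0-based; `(x, y)` are column/row of the image plane, `z`
is the slice index, and physical coordinates refer to voxel centres.
Frame `k` corresponds to elapsed time `k·dt` minutes, so a 10-hour
acquisition at 30-minute intervals has 21 frames (k = 0…20).  The default
calibration is 0.589 μm/px laterally, 2.0 μm/slice axially and 30 min/frame;
all four values are strictly positive, finite and user-settable
(`dx_um`, `dy_um`, `dz_um`, `dt_min`).

## Illumination (vignetting) model

The correction is retrospective — estimated from the image collection
itself, with no calibration frames.  The model is affine per pixel:

    observed(y, x) = gain(y, x) · signal(y, x) + offset(y, x)

- **offset**: Gaussian-smoothed per-pixel 5% quantile across the training
  collection, clamped to the per-pixel minimum (so it never exceeds any
  observed value).  For a constant collection the quantile equals the
  constant, so the offset is exactly that constant.
- **gain**: Gaussian-smoothed per-pixel *median* of the offset-subtracted
  planes, normalised to unit mean.  The median (rather than the mean)
  makes the estimate robust to bright cells passing through a pixel.
- **smoothing**: σ = 2% of the image diagonal, enforcing the smooth,
  low-frequency character of real shading.  If the residual field is
  degenerate (constant input) the gain falls back to a uniform 1.

Correction inverts the model, `(observed − offset)/gain`, clipped at 0 and
applied per z-slice for 3D input.  Because the offset is subtracted and not
re-added, the corrected mean is lower than the raw mean by roughly the mean
offset; the mean is preserved only when the offset is small relative to the
signal.  This follows from requiring that correcting `gain·s + offset`
return exactly `s`.

The collection should sample many z-slices and time points so the true
signal decorrelates across planes while the shading stays fixed; the
pipeline samples up to 100 planes evenly across the 4D data.

## Rigid alignment

Each frame is registered to a user-chosen reference frame with a
translation (Δx, Δy, Δz) and an optional user-supplied in-plane rotation.

The central difficulty is that the registration must follow the *static*
scene content (the carrier, background structure) and not the moving
cells, which are the brightest objects in the field.  Three measures
address this:

- MIPs are smoothed (σ = 2 px) and clipped to their [25th, 75th]
  percentile band before phase correlation.  The upper clip flattens
  compact bright movers; the lower clip removes the weight of dark fill
  borders left by an earlier resampling.
- The axial profile is the slice-wise mean of the stack clipped at
  median + 10 robust standard deviations (MAD·1.4826), so cells barely
  perturb it; profile values below their 10th percentile (zero-filled
  slices) are floored.  The axial lag maximises the per-lag normalised
  cross-correlation over the overlap, searched within ±n_z/4 and kept at
  0 unless a lag beats it by 0.01; ties break to the smallest |lag|.
- **Do-no-harm gate**: an estimated lateral shift is applied only if it
  *raises* the normalised correlation of the preprocessed MIPs (border
  cropped by the shift magnitude) by at least `min_improvement` (default
  0.005) over applying no shift; otherwise a warning is issued and a zero
  shift recorded.  On drift-free data with moving cells this gate rejects
  spurious estimates; on genuinely drifted data the true shift clears it
  easily.

Resampling is linear (order 1) with zero fill; the reference frame is
returned untouched; identity transforms skip resampling.  Sub-pixel
refinement uses upsampled phase correlation (factor 10).  For sparse
scenes with no static structure at all, per-frame drift estimation is
fundamentally ambiguous; the gate then degrades gracefully to zero shifts
with warnings rather than corrupting the data.

## Projection

The default projection is the per-pixel maximum over z, stored together
with the `argmax_z` map (smallest slice index attaining the maximum), so
`stack[argmax_z[y,x], y, x]` reproduces the MIP exactly.  The
extended-depth-of-field alternative selects, per pixel, the slice with the
highest intensity variance in an odd `patch`×`patch` window (default 9),
median-filtering the slice-label map with the same window before sampling.
The local-variance rule is a simple sharpness proxy, adequate for
point-like sources; wavelet-based full-focus operators are out of scope.

## 2D tracking

**Detection** — Gaussian smoothing (default σ = 2 px), thresholding (Otsu
by default, absolute as an option), 8-connected component labelling, an
[min_area, max_area] size gate (default [4, 10000] px), and
intensity-weighted centroids computed on the smoothed image.  Detections
are ordered by (y, x) so results are reproducible.  A featureless frame
yields no detections.

**Linking** — per frame transition, the assignment between open tracks and
new detections minimising the total squared displacement is solved exactly
with the Hungarian algorithm on a square matrix padded with "no-match"
entries of cost `gate_px²`; pairs beyond the gate are forbidden.  A track
unseen for `g ≤ max_gap` frames may capture a detection within
`gate_px·(g+1)`, and the missing frames are bridged with linearly
interpolated points flagged `gap-filled`; these are excluded from
path-length accumulation by default so interpolation never fabricates
motion.  Longer absences close the track; unmatched detections open new
ones.

The cost reference point is configurable: displacement from the track's
last position (the plain model, and the one the brute-force test oracle
replicates), or from a constant-velocity extrapolation of the last step
(`predict="velocity"`).  Prediction matters when the step length per frame
is comparable to inter-cell distances: for persistent movers whose
projected paths cross, position-only assignment freely rotates identities
among nearby cells, while extrapolation keeps each track on its own
heading.  The pipeline default is `velocity`; the cost remains a pure
squared Euclidean distance — no intensity or appearance terms.

**Seeded mode** — from each user seed the position is updated per frame to
the intensity-weighted centroid inside a search disk (default radius
10 px) around the previous position, stopping when the local maximum falls
below the detection threshold (per-frame Otsu unless given).  **Manual
mode** ingests (id, time_index, x, y) tables verbatim, flagging points
`manual`; duplicate (id, time) rows are rejected.

## z-recovery

For each track point, `score(z)` is the mean intensity in a disk of
`window_radius_px` (default 3 px) around the rounded (x, y) on slice z; the
estimate is the lowest slice attaining the maximum score.  Radius 0
reduces to the literal per-pixel column argmax.  Optional parabolic
refinement through (z−1, z, z+1) gives sub-slice estimates for interior
peaks and is off by default (integer slice selection is the plain reading
of the method).  Each point carries `z_confidence`, the winning score over
the median score of the column — near 1 means the column is featureless
and the estimate uninformative.

`max_dz_per_frame` (pipeline default 10 slices = 20 μm/frame) restricts
the search to a window around the previous estimate.  When two cells cross
in projection, the brightest plane at the shared (x, y) can belong to the
*other* cell — on a sphere, typically on the opposite hemisphere — and the
unconstrained argmax then jumps by tens of slices and back, inflating 3D
path lengths by far more than the lateral error.  The continuity bound is
generous relative to any plausible cell speed (the reference fixture's
cells move ≤ 7.5 slices/frame) and leaves genuine motion untouched.

## Motility measures

All measures are computed on retained points (valid, and not gap-filled
unless requested) in anisotropic physical units:

- path length `L = Σᵢ ‖pᵢ₊₁ − pᵢ‖` (μm); single point → 0;
- net displacement `D = ‖p_last − p_first‖`; straightness `D/L` (1 when
  `L = 0`);
- distance from origin per time point, first value 0;
- instantaneous speed per step (step length over step duration) and mean
  speed (`L` over elapsed time), μm/min.

These satisfy, for every track: `d(t) ≤` cumulative path at `t` (triangle
inequality), `D ≤ L`, invariance under global translation, and
path-length invariance under time reversal — all enforced by tests on
random walks.  Measures default to full 3D; a 2D mode ignoring z is
provided for comparison with projection-only analyses.  Cohort summaries
average each measure per time point over the tracks defined at that time
(no imputation).  Export writes per-point and per-track CSVs with fixed
float formatting (byte-identical on re-export), an XLSX workbook, and a
JSON manifest recording geometry, parameters, seed and software version.

## Synthetic generator

**Motion** (surface mode): cells start uniformly at random on the sphere.
Each cell carries a unit tangent heading; per frame the heading becomes
the normalised mixture `persistence·h + (1 − persistence)·r` with `r` a
uniform random tangent direction, and the cell advances along the great
circle in that direction by a *chord* of exactly `step_um_per_frame`
(rotation by θ = 2·arcsin(s/2R)).  Persistence 0 gives an undirected
wander whose displacement saturates below the sphere diameter; persistence
1 gives a geodesic with path length exactly `k·s` after k steps — both
closed forms are used as test oracles.  Cells are confined to the surface
(they do not penetrate the scaffold); a free-space persistent walk is kept
for unit tests.

**Rendering**: each cell is an anisotropic 3D Gaussian (defaults
σ_xy = 2 μm, σ_z = 4 μm — the axial point-spread of a light sheet is
broader) of amplitude 2000 counts over a background of 100; a faint
spherical shell of the carrier (amplitude 30, radial width 3 μm) is
rendered by default — real acquisitions always contain the carrier's
static structure, and rigid alignment relies on it; the expected image is
multiplied per plane by a radial vignetting gain `1 − strength·(r/r_max)²`
(default strength 0.4), Poisson shot noise is drawn on the expected counts,
Gaussian read noise (σ = 5) added, and the result quantised to uint16.
A fixed seed reproduces the voxel data bit-exactly.

**Default volume**: 720 × 720 × 230 voxels (~424 × 424 × 460 μm), the
smallest round volume containing the default 400 μm carrier at the
standard voxel sizes.  The *reference validation fixture*
(`benchmark.desk_scale_config`) uses 512 × 512 × 150 voxels with the
carrier scaled to 240 μm so the sphere still fits, while keeping the
full-scale motion (15 μm/frame, persistence 0.9, ~300 μm paths over 20
steps); it runs in a few minutes in a few GB of memory.

**What is not emulated**: depth-dependent attenuation and scattering
(transparent carriers are assumed), light-sheet stripe artefacts,
dual-side illumination fusion and multi-view reconstruction, cell
division, death, shape change or adhesion kinetics, and multi-channel
staining.  Occlusion of the far hemisphere is therefore *emergent* only
through projection overlap, not through optics; passing tests show the
pipeline recovers what the image model contains, not that it is robust to
every real-world artefact.

## Validation fixture results

On the reference fixture the pipeline is evaluated by one-to-one
Hungarian matching of recovered tracks to true cells (mean projected
distance as cost): fraction of points within 5 px of the assigned cell
(identity), pooled median lateral and axial errors over camera-facing
cells (true mean z in the camera-side half of the volume; far-hemisphere
cells are reported separately since projection overlap degrades them), and
per-cell path-length error with the true path restricted to the frames the
track covers.  `scripts/acceptance.py` recomputes all of these.

## Numerical choices and degenerate inputs

- Argmax ties (projection, z-recovery) break to the lowest slice index.
- Correlation-peak ties (alignment) break to the smallest-magnitude shift.
- Flat/featureless inputs: Otsu detection returns no detections; alignment
  treats flat images as trivially registered (zero shift); z-recovery of a
  uniform stack returns slice 0.
- Non-match cost in linking is exactly `gate_px²`, making the objective
  (matched cost + gate²·unmatched) well-defined and brute-force checkable.
- Exports use `%.6f` float formatting for byte-stable reproducibility.

## Limitations

- Tracking is 2D-first: two cells that overlap in projection for several
  frames can exchange identity or merge detections; the velocity prior and
  the axial continuity bound mitigate but cannot eliminate this.  Isolated
  cells are tracked essentially exactly.
- Per-frame drift estimation has no information source in scenes with no
  static structure; the do-no-harm gate then leaves frames unaligned (with
  warnings) rather than guessing.
- The illumination model is affine per pixel with a single global
  smoothing scale; it does not model spatially varying PSFs or
  z-dependent shading.
- No mitosis handling, no appearance models, no MSD/diffusion fitting, no
  inter-cohort hypothesis testing.
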