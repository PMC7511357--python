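# Methods

This note documents the models and procedures implemented in `lamella`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the underlying method left
the design open.

## Coordinate and unit conventions

Images are `(T, C, Y, X)` arrays with 0-based pixel-centre coordinates;
`x` is the column index, `y` the row index (y grows downward).  Physical
calibration is carried explicitly: `pixel_size` in µm/px and
`frame_interval` in s.  Edge velocities are reported in µm/min (the scale
on which protrusion and retraction rates of endothelial cells are usually
discussed, ~1-2 µm/min), single-cell migration speeds in µm/h, decay times
in s.  Velocity kymograph rendering bounds default to ±0.65 µm/s, stored
separately from the data and never applied to it.

## Preprocessing

**Channel registration.**  A least-squares affine map is fitted to paired
control points (≥ 3, non-collinear) and applied to the moving channel with
bilinear interpolation.  On control points generated from an exact affine
map the residual is at numerical precision (< 1e-6 px); residuals above
0.5 px raise a warning in the returned report, not an error, since the
caller may accept imperfect optics.

**Cell segmentation.**  "Automated intensity thresholding" is concretized
as Gaussian smoothing (σ = 2 px) → Otsu threshold → hole filling → discard
components below `min_area` → keep the largest component.  Otsu is the
natural default for bimodal reporter images; the smoothing σ only needs to
exceed the noise correlation length and is not sensitive.

**Local background.**  The median of a ring outside the (slightly dilated)
cell mask, default width 10 px, subtracted and clipped at zero.  A ring
median is robust to stray debris and needs no model of the illumination
field; a linear illumination gradient leaves a residual bounded by the
gradient's variation across the ring.

**Ratio images.**  Pixel-wise numerator/denominator on the mask, with
pixels whose denominator does not exceed a floor (default 1 intensity
unit) marked invalid rather than producing unstable ratios.  The stored
3rd/99th percentiles are for colormap scaling only.  Multiplying both
channels by a common gain leaves the ratio unchanged (tested).

## Edge dynamics

**Boundary extraction.**  The outer 0.5-level contour of the (hole-filled)
mask, oriented consistently, resampled to N points at equal arc length
(default N = 400), then smoothed along the contour with a periodic
Gaussian (σ = 2 points).  The smoothing exists for a specific reason:
single-pixel rasterization ripple creates local "valleys" that a
minimum-distance matcher preferentially targets, biasing recovered normal
velocities low by ~5%; after smoothing, a uniformly expanding synthetic
cell is recovered within 0.5%.

**Order-preserving matching.**  Between consecutive frames the contours
(equal N) are matched by the cyclically monotone map minimizing the summed
squared distance.  The map may be many-to-one (boundary length is created
and destroyed during protrusion and retraction); it wraps exactly once.
For each of the N cyclic anchors the inner problem is solved by an
O(N²) dynamic program (prefix-minimum recurrence), and the best anchor is
taken, so the result is the exact optimum over the class.  A brute-force
enumerator over all anchors × monotone index sequences (feasible to
N ≈ 12) is kept in the package as an independent oracle; the DP agrees
with it exactly on every random instance tried (a standing property test).

**Velocity.**  The displacement of each matched pair is projected on the
outward normal at the source point (normals from central differences,
oriented away from the centroid).  Projection removes tangential slip: a
pure re-parameterization of the same contour yields |v| < 0.005 µm/min.
Degenerate normals mark the point invalid (NaN) rather than zero.

**Windows.**  The edge band is the set of mask pixels within `depth_px`
(default 10) of the boundary, partitioned into W contiguous equal
arc-length sectors (default W = 55) by assigning each band pixel to its
nearest boundary point.  Window identity is kept stable over time by
carrying the anchor index through the frame-to-frame matching.  R[w,t] is
the mean ratio over the window's pixels, V[w,t] the mean per-point
velocity over its arc; empty windows are NaN, never zero.

**Cross-correlation.**  The protrusion indicator is ternary: +1 where
V > +v_min, -1 where V < -v_min, 0 otherwise, with v_min = 0.02 µm/s by
default (an event threshold has to be chosen somewhere; it is surfaced as
a parameter and recorded in outputs).  r(ℓ) is the Pearson correlation of
signal at offset ℓ against the indicator over all window/time pairs where
both are defined; ends are NaN-padded so the sample count shrinks with |ℓ|
instead of truncating and biasing the tails.  Lags with < 3 valid pairs
are undefined.

## Line kymographs

Bilinear sampling along the line at 1-px steps, averaged over `width_px`
parallel offsets.  Rates from traced fronts are OLS slopes converted as
px/frame × µm/px × 60/(s/frame); a 2 px/frame trace at 0.325 µm/px and
10 s frames is exactly 3.9 µm/min.  Episode boundaries (where a protrusion
starts and ends on the kymograph) are inherently a judgment call, so traces
are accepted as (distance, frame) polylines; the bundled automatic tracer
(per-row outermost position above a per-kymograph Otsu threshold,
requiring two adjacent super-threshold samples to reject isolated noise,
lightly median-filtered) is a convenience for synthetic round-trips and is
labelled as such.

## ICQ colocalization

Over the region pixels where **both** channels reach the signal threshold
(default 1 intensity unit), with channel means computed over that same
set: ICQ = (fraction of pixels whose deviations share a sign) - 0.5.
Products exactly zero count as non-positive (strict inequality).  Applying
the threshold to both channels keeps the statistic symmetric in A and B;
whether the original formulation thresholded one or both channels is not
documented, so the choice is recorded in output metadata.  ICQ is
invariant under positive-scale affine transforms of either channel, and
bounded in [-0.5, +0.5] on arbitrary inputs (fuzz-tested).  The null
scrambles one channel's in-region pixels uniformly (seeded) and reports
the null mean and central 95% interval.

## Nuclei tracking

Segmentation is smoothing + Otsu + hole filling with an area gate
(min/max) and intensity-weighted centroids.  Linking is greedy by
ascending distance with a hard displacement gate — deterministic, and
provably swap-free when the minimum pairwise separation stays above twice
the largest per-frame displacement (property-tested on random scenes).
Mitosis: a leftover detection within the gate of a track that also
received a normal match opens a daughter track with a lineage record
(daughter id, mother id, split frame); the mother's id continues through
the other daughter.  Tracks shorter than 5 frames are excluded from
velocity reports (noise guard; a parameter, not a measured constant).
Speeds are mean consecutive-frame displacements × calibration, µm/h, with
a t-based 95% CI across cells.  Scratch closure is the fraction of the
t=0 scratch region covered by the mask per frame.

## Ladder micropatterns

**Geometry.**  The stripe-normal orientation is estimated from
Gaussian-derivative gradients (σ = 2 px; plain central differences carry a
degree-scale orientation bias on diagonal edges) via the mode of the
energy-weighted orientation histogram, then refined by directly maximizing
the variance of the 1-D profile obtained by projecting the image onto the
candidate normal — the profile is sharpest exactly when the projection is
parallel to the stripes.  The profile is Otsu-thresholded into runs and
edges are refined at the half-maximum level, which is symmetric under blur;
recovered widths and gaps on synthetic ladders (2 µm stripes, 4-16 µm
gaps) are exact to within half a pixel at any orientation.

**Contact.**  "Full contact" is quantified as the cell mask covering at
least 50% of the stripe segment under the cell's footprint (the stripe
rows spanned by the mask), sustained for 2 consecutive frames.  Both
numbers are parameters surfaced in outputs; the qualitative notion of
contact does not pin them down.

**Spreading.**  Δarea = area(contact + 1 h) - area(contact) in µm²; the
relative-area curve is normalized to 1 at contact.  A cell is excluded,
with the reason recorded, if during the horizon it touches another cell
(masks within 1 px), another cell overlaps a stripe adjacent to the
contacted one, the cell reaches the field border or vanishes, or the movie
ends early.  Exclusion is monotone: adding a collision can only remove a
cell from the analysis.  Gap group is the gap size of the lane entered
from the contacted stripe.  Stripes-occupied delta counts stripes passing
the same overlap criterion just before treatment and 45 min after; cells
present for less than 30 min before treatment, or ever touching another
cell, are excluded.

## Profiles, decay, lengths

Profiles are sampled by bilinear interpolation at a fixed µm step along
edge-to-lamellum lines, normalized per line and channel to the line
maximum (the minimal assumption when the normalizer is unspecified), and
summarized by the per-position median across cells.  LOWESS (statsmodels,
span default 0.3) smooths before landmark extraction; on noise-free linear
data it reproduces the line to numerical precision.  The edge is the first
local maximum of the F-actin curve from position 0; myosin onset is the
first position at or behind the edge where the MYL9 slope exceeds
θ × (its maximum positive slope), θ = 0.2 by default — a literal
second-derivative inflection is noise-fragile, while the θ-crossing has a
closed form on logistic test fronts and degrades gracefully.  Onset ≥ edge
whenever both are defined.  Decay half-times are the first linear-
interpolated crossing of 0.5 after normalizing to the activation frame;
traces that never cross (pharmacologically frozen actin) report none.  ROI
polyline lengths are arc length × pixel size with a t-based 95% CI.

## Synthetic generators

The generators define the conditions under which the pipeline is
validated; all randomness flows from one integer seed per call through a
single `numpy` generator, and identical inputs give byte-identical output.

- **Protruding cell**: a star-convex boundary r(θ, t) integrating flat-top
  angular velocity bumps (µm/min), rasterized into a reference channel
  (foreground 1000, background 100) and a reporter whose
  background-subtracted signal is ×`enrichment_ratio` inside a 10-px band
  over the protrusive sectors.  Truth stores exact boundary polygons, the
  per-angle radial rate (identical to the outward-normal rate for uniform
  expansion, and equal by construction to the finite difference of the
  stored boundaries), and the protrusive-sector indicator.  Enrichment is
  applied to the background-subtracted signal, not the raw counts, so the
  scripted ratio is what an ideally background-corrected pipeline should
  recover.
- **Nuclei**: Gaussian blobs (σ = 2.5 px, amplitude 900 over background
  80) on straight trajectories; whole trajectories are rejection-sampled
  so pairwise separations exceed max(4× the per-frame displacement,
  6 blob σ) at every frame, keeping the tracking problem well-posed for
  the whole movie.  Mitoses split a blob into two daughters diverging
  perpendicular to the path, already resolvable (≥ 5σ apart) at the split
  frame so recovered lineage frames match the script.
- **Ladder**: vertical stripes at scripted spacings plus disk-shaped cells
  following scripted area curves; scripted collisions render a touching
  neighbour; unscripted overlap raises.  Truth stores both the scripted
  and the actually rasterized area curves — disk rasterization quantizes
  areas, and exactness claims are against the rendered pixels.
- **Coloc pairs**: jointly Gaussian latents with correlation ρ mapped to
  positive intensities; ρ = ±1 are strictly monotone transforms (ICQ
  ±0.5), ρ = 0 independent.
- **Decay traces**: i₀·exp(-t/τ) (constant when frozen) plus optional
  noise.

**What the generators do not emulate** — and therefore what passing tests
do not demonstrate about real microscopy: optical PSF blur and diffraction
(noise is additive Gaussian, clipped at zero; no photon-counting
statistics), uneven illumination, photobleaching, focus drift,
non-star-convex cell shapes (ruffles, severe concavities), touching or
overlapping nuclei beyond scripted mitoses, and textured cytoplasmic
signal.  Results on real data will additionally depend on segmentation
quality in ways these tests cannot probe.

## Problem sizes

Validation runs use sizes chosen to exercise every code path at desk
scale: 200-point boundaries over 5-8 frames for edge dynamics, 50 nuclei
over 15 frames for tracking, 40-frame kymographs, 10⁵ pixels for ICQ
independence checks, 1000 permutations for the scrambled null, and 200
random contour pairs (N ≤ 12) for the matching oracle.  The matching DP is
O(N³) per frame pair; N = 400 (the library default) takes well under a
second per pair, so hour-long movies remain practical.

## Known limitations

- The DP matching searches all N cyclic anchors exhaustively; for very
  large N a bounded anchor search around the previous frame's offset would
  be faster, at the cost of a global-optimality guarantee.
- Greedy nearest-neighbour linking has no gap closing: a missed detection
  terminates a track and opens a new one.
- The windowed analysis assumes one connected cell mask per frame; movies
  with touching cells need prior instance segmentation.
- Stripe detection assumes a single dominant stripe orientation per field.
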