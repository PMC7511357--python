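# lamella

Quantitative image analysis for live-cell studies of membrane protrusion,
cell spreading across micropatterned extracellular-matrix (ECM) gaps, and
single-cell migration.

Migrating cells push their membrane forward with branched actin networks in
lamellipodia and bundled actin in filopodia.  Experiments that probe this
machinery — two-channel reporter movies of the leading edge, kymographs of
protrusion/retraction cycles, STED colocalization of actin-binding
proteins, scratch-wound nuclei tracking, and "ladder" micropatterns of
fibronectin stripes separated by non-adhesive PLL-PEG gaps — all need the
same family of measurements.  `lamella` implements that family as a tested,
reusable library, plus a synthetic-movie generator that provides exact
ground truth for every stage, so each measurement is validated end to end
without external data.

## What it measures

**Windowed edge dynamics.**  The cell boundary is segmented per frame,
resampled to *N* points, and divided (with a 10-px-deep band) into ~55
windows along the periphery.  Boundary points are tracked between frames by
an order-preserving matching: the cyclically monotone map *m* minimizing

    sum_i || a_i - b_m(i) ||^2

solved exactly by dynamic programming over all cyclic anchors.  The signed
edge velocity of a window is the matched displacement projected on the
outward normal (positive = protrusion), in µm/min; the reporter signal is
the mean background-subtracted ratio (e.g. reporter / F-tractin) over the
window's band pixels.  The two matrices V[w,t] and R[w,t] form window
kymographs, and a NaN-padded lagged Pearson correlation r(ℓ) relates
enrichment to protrusion events.

**Line kymographs and rates.**  Intensities sampled along a line across the
edge, stacked over time; traced fronts are converted to rates by ordinary
least squares: rate = slope(px/frame) × pixel size × 60/frame interval.

**Colocalization (ICQ).**  For pixels i in a region,
`ICQ = #{(A_i - Ā)(B_i - B̄) > 0} / N - 0.5`, in [-0.5, +0.5], with a null
distribution from scrambling one channel's pixels within the region.

**Nuclei tracking.**  Smoothing + Otsu segmentation, greedy
nearest-neighbour linking with a displacement gate, mitosis handling (one
daughter keeps the mother's id, the other opens a lineage-recorded track),
and per-cell speeds in µm/h.

**Ladder gap bridging.**  Stripe geometry recovered from the pattern
channel; first sustained "full contact" frame per cell; cell-area change
1 h after contact with the stated exclusion rules (cell-cell contact,
occupied neighbour stripe, leaving the field); relative-area time courses;
and the change in stripes occupied 45 min after a treatment.

**Profiles and decay.**  Edge-to-lamellum intensity profiles with LOWESS
smoothing and two landmarks (first F-actin peak = edge; first
fraction-of-max MYL9 slope = myosin onset); photoactivation decay
half-times; ROI polyline lengths for protrusion width/depth.

## Worked example

```python
import numpy as np
from lamella import synth, preprocess, edge, profiles, icq
from lamella.synth import Bump, SyntheticCellMovieSpec

# a cell whose whole boundary protrudes at exactly 1.5 µm/min
spec = SyntheticCellMovieSpec(
    n_frames=8, frame_interval=30.0, pixel_size=0.325, base_radius=12.0,
    bumps=(Bump(0.0, 7.0, 1.5, 0, 8),), noise_sd=8.0, seed=3,
    n_boundary_points=300,
)
stack, truth = synth.make_protruding_cell_movie(spec)
masks = np.stack([preprocess.segment_cell(stack.pixels[t, 0]).mask
                  for t in range(stack.n_frames)])
kym = edge.window_signals(np.where(masks, 1.0, np.nan), masks,
                          stack.pixel_size, stack.frame_interval,
                          n_windows=55, band_depth_px=10, n_points=200)
print(f"true edge velocity:      {truth.normal_velocity.mean():.3f} um/min")
print(f"recovered mean velocity: {np.nanmean(kym.velocity):.3f} um/min")

a = np.random.default_rng(0).uniform(10, 1000, 10_000)
res = icq.scrambled_null(a, 0.6 * a + 50.0, n_perm=500, seed=0)
lo, hi = res.null_interval()
print(f"ICQ (co-varying pair):   {res.icq:+.3f}  null mean {res.null_mean:+.4f} "
      f"[{lo:+.4f}, {hi:+.4f}]")

t, y = synth.make_decay_trace(28.854, n_samples=60, dt=1.0)
print(f"PAGFP half-time:         {profiles.decay_halftime(y, 1.0).half_time_s:.1f} s")
```

Output:

```
true edge velocity:      1.500 um/min
recovered mean velocity: 1.494 um/min
ICQ (co-varying pair):   +0.500  null mean -0.0005 [-0.0104, +0.0095]
PAGFP half-time:         20.0 s
```

The recovered edge velocity matches the scripted 1.5 µm/min within 0.5%; a
perfectly co-varying channel pair sits at the ICQ upper bound (+0.5) while
its scrambled null brackets zero; and an exponential decay with
τ = 28.854 s crosses 50% at ln 2 · τ ≈ 20 s.

A `lamella` command-line tool wraps the shell-friendly workflows
(`lamella synth cell-movie|nuclei`, `segment`, `ratio`, `edge`, `kymo`,
`icq`, `track` — see `lamella --help`).

## Layout

- `src/lamella/synth.py` — ground-truthed synthetic generators
- `src/lamella/stack.py`, `preprocess.py` — calibrated I/O, registration,
  segmentation, background subtraction, ratio images
- `src/lamella/edge.py` — boundary matching, window kymographs, lagged
  correlation
- `src/lamella/kymo.py`, `icq.py`, `tracking.py`, `ladder.py`,
  `profiles.py` — the remaining stages
- `docs/methods.md` — models, parameter choices, and limitations
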