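"""Cell-edge dynamics: boundary tracking, windowed kymographs, correlation.

The cell boundary is traced per frame, resampled to a fixed number of
points, and tracked between frames by an order-preserving (cyclically
monotone) point matching that minimizes the summed squared distance between
matched points.  Signed edge velocities are the matched displacements
projected on the outward normal (+ = protrusion).  A 10-px-deep band along
the edge is divided into ~55 contiguous windows; per-window mean reporter
ratio and mean edge velocity form the window kymographs, and a lagged
Pearson correlation (NaN-padded, pairwise-complete) relates reporter
enrichment to protrusion events.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.measure import find_contours, label

__all__ = [
    "BoundaryTrace",
    "BoundaryMatch",
    "WindowKymograph",
    "CrossCorrelationCurve",
    "extract_boundary",
    "match_boundaries",
    "bruteforce_match_cost",
    "compute_edge_velocity",
    "window_signals",
    "protrusion_indicator",
    "cross_correlate",
]


@dataclass
class BoundaryTrace:
    """Closed cell contour for one frame, arc-length resampled.

    ``points`` is an ``(N, 2)`` array of (x, y) pixel coordinates with a
    consistent counterclockwise orientation (positive shoelace area in the
    x/y frame).  The polygon is closed implicitly (last point connects back
    to the first).
    """

    points: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class BoundaryMatch:
    """Order-preserving correspondence from contour A to contour B."""

    index_map: np.ndarray  # (N,) int: point i of A matches point index_map[i] of B
    cost: float  # summed squared distance of matched pairs
    offset: int  # index_map[0]


@dataclass
class WindowKymograph:
    """Per-window edge velocity and reporter-ratio matrices over time.

    ``velocity`` has shape (W, T-1) in µm/min, signed (+ = outward);
    ``ratio`` has shape (W, T).  Invalid entries (empty windows, degenerate
    normals) are NaN.  ``display_bounds`` is the rendering scale for
    velocity kymographs (±0.65 µm/s expressed in µm/min) and never affects
    the stored data.
    """

    velocity: np.ndarray
    ratio: np.ndarray
    n_windows: int
    band_depth_px: int
    display_bounds: tuple[float, float] = (-39.0, 39.0)


@dataclass
class CrossCorrelationCurve:
    lags_frames: np.ndarray
    lags_s: np.ndarray
    r: np.ndarray  # Pearson r per lag, NaN where < 3 valid pairs
    n_pairs: np.ndarray


# --------------------------------------------------------------------------
# boundary extraction
# --------------------------------------------------------------------------


def extract_boundary(
    mask: np.ndarray, n_points: int = 400, smooth_sigma: float = 2.0
) -> BoundaryTrace:
    """Trace the outer contour of a connected mask and resample it.

    The mask's holes are filled first; a mask that is empty or splits into
    several components is rejected.  Points are placed at equal arc-length
    spacing along the sub-pixel 0.5-level contour, then lightly smoothed
    along the contour (periodic Gaussian, ``smooth_sigma`` in points) to
    suppress single-pixel rasterization ripple, which otherwise biases the
    minimum-distance point matching toward its valleys.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no boundary to trace")
    filled = ndi.binary_fill_holes(mask)
    if label(filled).max() != 1:
        raise ValueError("mask has multiple components; segment first")
    contours = find_contours(filled.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col)
    pts = contour[:, ::-1]  # -> (x, y)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # enforce positive (counterclockwise) shoelace orientation
    x, y = pts[:, 0], pts[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pts = pts[::-1]
    pts = _resample_closed(pts, n_points)
    if smooth_sigma > 0:
        pts = ndi.gaussian_filter1d(pts, smooth_sigma, axis=0, mode="wrap")
    return BoundaryTrace(points=pts)


def _resample_closed(pts: np.ndarray, n_points: int) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(target, s, closed[:, 0])
    out[:, 1] = np.interp(target, s, closed[:, 1])
    return out


# --------------------------------------------------------------------------
# order-preserving cyclic matching
# --------------------------------------------------------------------------


def _sq_dist_matrix(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    diff = pa[:, None, :] - pb[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def match_boundaries(
    ba: BoundaryTrace, bb: BoundaryTrace, offset_chunk: int = 64
) -> BoundaryMatch:
    """Optimal cyclic monotone matching of two equal-length contours.

    Finds the map ``m`` from A-indices to B-indices that is cyclically
    nondecreasing (order-preserving along the periphery, many-to-one
    allowed), wraps around exactly once, and minimizes
    ``sum_i ||a_i - b_m(i)||^2``.  Every cyclic anchor ``m(0)`` is searched
    exhaustively; for each anchor the inner problem is solved by dynamic
    programming, so the result is the global optimum over the class.
    """
    pa, pb = ba.points, bb.points
    n = len(pa)
    if len(pb) != n:
        raise ValueError(f"point counts differ: {n} vs {len(pb)}")
    d2 = _sq_dist_matrix(pa, pb)

    rel = np.arange(n)
    best_cost = np.inf
    best_offset = -1
    for lo in range(0, n, offset_chunk):
        offsets = np.arange(lo, min(lo + offset_chunk, n))
        idx = (offsets[:, None] + rel[None, :]) % n  # (n_off, n)
        dp = np.full((len(offsets), n), np.inf)
        dp[:, 0] = d2[0, offsets]
        for i in range(1, n):
            np.minimum.accumulate(dp, axis=1, out=dp)
            dp += d2[i, idx]
        costs = dp.min(axis=1)
        k = int(np.argmin(costs))
        if costs[k] < best_cost:
            best_cost = float(costs[k])
            best_offset = int(offsets[k])

    index_map = _backtrack(d2, best_offset)
    return BoundaryMatch(index_map=index_map, cost=best_cost, offset=best_offset)


def _backtrack(d2: np.ndarray, offset: int) -> np.ndarray:
    """Re-run the DP for one anchor with prefix-argmin backpointers."""
    n = d2.shape[0]
    cols = (offset + np.arange(n)) % n
    dp = np.full((n, n), np.inf)
    dp[0, 0] = d2[0, offset]
    arg = np.zeros((n, n), dtype=int)
    for i in range(1, n):
        prev = dp[i - 1]
        run_min = np.minimum.accumulate(prev)
        run_arg = np.zeros(n, dtype=int)
        better = prev < np.concatenate([[np.inf], run_min[:-1]])
        # run_arg[j] = argmin over prev[:j+1]
        idxs = np.where(better, np.arange(n), 0)
        run_arg = np.maximum.accumulate(idxs)
        dp[i] = run_min + d2[i, cols]
        arg[i] = run_arg
    rel = np.empty(n, dtype=int)
    rel[-1] = int(np.argmin(dp[-1]))
    for i in range(n - 1, 0, -1):
        rel[i - 1] = arg[i, rel[i]]
    return cols[rel]


@functools.lru_cache(maxsize=16)
def _monotone_combos(n: int) -> np.ndarray:
    """All nondecreasing relative index sequences for points 1..n-1."""
    return np.array(
        list(itertools.combinations_with_replacement(range(n), n - 1)), dtype=np.intp
    )


def bruteforce_match_cost(ba: BoundaryTrace, bb: BoundaryTrace) -> float:
    """Exhaustive minimum cost over all cyclic monotone winding-1 maps.

    Reference implementation by direct enumeration (anchors x all
    nondecreasing index sequences); exponential in N, intended for
    validating :func:`match_boundaries` on small contours (N <= 12).
    """
    pa, pb = ba.points, bb.points
    n = len(pa)
    if len(pb) != n:
        raise ValueError("point counts differ")
    if n > 13:
        raise ValueError("bruteforce oracle is limited to N <= 13")
    d2 = _sq_dist_matrix(pa, pb)
    combos = _monotone_combos(n)
    # lookup[i][rel, o] = d2[i, (o + rel) % n]; evaluating all offsets at once
    # turns the cost sum into fast contiguous row gathers
    lookup = np.empty((n, n, n))
    cols = np.arange(n)
    for rel in range(n):
        lookup[:, rel, :] = d2[:, (cols + rel) % n]
    acc = np.zeros((len(combos), n))
    for i in range(1, n):
        acc += lookup[i][combos[:, i - 1]]
    acc += d2[0][None, :]
    return float(acc.min())


# --------------------------------------------------------------------------
# edge velocity
# --------------------------------------------------------------------------


def outward_normals(trace: BoundaryTrace) -> np.ndarray:
    """Unit outward normals per boundary point (NaN where degenerate)."""
    pts = trace.points
    tangent = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    normals = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = normals / norm[:, None]
    normals[norm < 1e-12] = np.nan
    # orient away from the centroid
    out = pts - trace.centroid()
    flip = np.einsum("ij,ij->i", normals, out) < 0
    normals[flip] *= -1
    return normals


def compute_edge_velocity(
    ba: BoundaryTrace,
    bb: BoundaryTrace,
    match: BoundaryMatch,
    pixel_size: float,
    frame_interval: float,
) -> np.ndarray:
    """Signed per-point edge velocity in µm/min (+ = outward).

    The displacement of each matched point pair is projected on the outward
    normal at the source point, which removes tangential slip introduced by
    re-parameterization of the contour.
    """
    disp = bb.points[match.index_map] - ba.points
    normals = outward_normals(ba)
    v_px_per_frame = np.einsum("ij,ij->i", disp, normals)
    return v_px_per_frame * pixel_size * (60.0 / frame_interval)


# --------------------------------------------------------------------------
# windowed signals
# --------------------------------------------------------------------------


def _window_labels(n_points: int, n_windows: int, anchor: int) -> np.ndarray:
    rel = (np.arange(n_points) - anchor) % n_points
    return (rel * n_windows) // n_points


def window_signals(
    ratios: np.ndarray,
    masks: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    n_windows: int = 55,
    band_depth_px: int = 10,
    n_points: int = 400,
) -> WindowKymograph:
    """Build per-window velocity and ratio kymographs for a movie.

    ``ratios`` is a (T, Y, X) float array (NaN outside the valid ratio
    region), ``masks`` the matching (T, Y, X) boolean cell masks.  The edge
    band is the set of mask pixels within ``band_depth_px`` of the
    boundary; each band pixel joins the window of its nearest boundary
    point.  Windows are equal arc-length sectors whose anchor is carried
    from frame to frame through the boundary matching, keeping window
    identity stable as the cell deforms.
    """
    ratios = np.asarray(ratios, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    n_t = masks.shape[0]
    if ratios.shape != masks.shape:
        raise ValueError("ratios and masks must have the same (T, Y, X) shape")

    traces = [extract_boundary(masks[t], n_points) for t in range(n_t)]
    ratio_mat = np.full((n_windows, n_t), np.nan)
    vel_mat = np.full((n_windows, max(n_t - 1, 1)), np.nan)

    anchor = 0
    anchors = []
    matches = []
    for t in range(n_t - 1):
        m = match_boundaries(traces[t], traces[t + 1])
        matches.append(m)
    for t in range(n_t):
        anchors.append(anchor)
        if t < n_t - 1:
            anchor = int(matches[t].index_map[anchor])

    for t in range(n_t):
        labels_pts = _window_labels(n_points, n_windows, anchors[t])
        # band pixels -> nearest boundary point -> window
        dist_in = ndi.distance_transform_edt(masks[t])
        band = masks[t] & (dist_in <= band_depth_px)
        by, bx = np.nonzero(band)
        if by.size:
            tree = cKDTree(traces[t].points)
            _, nearest = tree.query(np.column_stack([bx, by]))
            win = labels_pts[nearest]
            vals = ratios[t, by, bx]
            for w in range(n_windows):
                sel = vals[win == w]
                sel = sel[np.isfinite(sel)]
                if sel.size:
                    ratio_mat[w, t] = sel.mean()
        if t < n_t - 1:
            v = compute_edge_velocity(
                traces[t], traces[t + 1], matches[t], pixel_size, frame_interval
            )
            for w in range(n_windows):
                sel = v[labels_pts == w]
                sel = sel[np.isfinite(sel)]
                if sel.size:
                    vel_mat[w, t] = sel.mean()

    return WindowKymograph(
        velocity=vel_mat,
        ratio=ratio_mat,
        n_windows=n_windows,
        band_depth_px=band_depth_px,
    )


def protrusion_indicator(
    velocity: np.ndarray, v_min_um_per_s: float = 0.02
) -> np.ndarray:
    """Ternary protrusion state from a velocity matrix in µm/min.

    +1 where velocity exceeds +``v_min`` (protrusion), -1 below -``v_min``
    (retraction), 0 otherwise; NaN velocities stay NaN.
    """
    thr = v_min_um_per_s * 60.0
    out = np.where(velocity > thr, 1.0, np.where(velocity < -thr, -1.0, 0.0))
    out = np.asarray(out, dtype=float)
    out[~np.isfinite(velocity)] = np.nan
    return out


# --------------------------------------------------------------------------
# lagged cross-correlation
# --------------------------------------------------------------------------


def cross_correlate(
    signal: np.ndarray,
    protrusion: np.ndarray,
    max_lag: int,
    frame_interval: float = 1.0,
) -> CrossCorrelationCurve:
    """Pearson correlation of a window signal with protrusion at time offsets.

    For each lag L in [-max_lag, max_lag], correlates ``signal[w, t+L]``
    with ``protrusion[w, t]`` over all window/time pairs where both are
    defined.  Ends are NaN-padded so the sample count shrinks with |L|
    instead of biasing the estimate; lags with fewer than 3 valid pairs are
    returned as NaN.
    """
    s = np.asarray(signal, dtype=float)
    p = np.asarray(protrusion, dtype=float)
    if s.shape != p.shape:
        raise ValueError("signal and protrusion matrices must share a shape")
    n_t = s.shape[1]
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.size, np.nan)
    n_pairs = np.zeros(lags.size, dtype=int)
    pad = np.full((s.shape[0], max_lag), np.nan)
    s_pad = np.concatenate([pad, s, pad], axis=1)
    for k, lag in enumerate(lags):
        shifted = s_pad[:, max_lag + lag : max_lag + lag + n_t]
        valid = np.isfinite(shifted) & np.isfinite(p)
        xs, ys = shifted[valid], p[valid]
        n_pairs[k] = xs.size
        if xs.size < 3:
            continue
        xc, yc = xs - xs.mean(), ys - ys.mean()
        denom = math.sqrt((xc**2).sum() * (yc**2).sum())
        if denom > 0:
            r[k] = float((xc * yc).sum() / denom)
    return CrossCorrelationCurve(
        lags_frames=lags,
        lags_s=lags * frame_interval,
        r=r,
        n_pairs=n_pairs,
    )
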