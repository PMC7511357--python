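"""Synthetic ground-truthed movies for every pipeline stage.

Real two-channel protrusion movies, Hoechst nuclei movies, fibronectin-ladder
assays and STED colocalization pairs are not bundled with the package, so
every analysis stage is validated against synthetic data whose ground truth
is known by construction:

* a deforming star-convex cell whose radial boundary integrates scripted
  local protrusion velocities, with a reporter channel enriched in a band
  at the protruding edge sectors;
* Gaussian-blob nuclei on straight trajectories with scripted mitoses;
* fluorescent ladder micropatterns (stripes + defined gaps) with scripted
  spreading cells and scripted cell-cell collisions;
* image pairs with controlled pixel-wise co-dependence for ICQ analysis;
* photoactivation decay traces.

All randomness in a generator flows from a single integer seed through one
``numpy.random.Generator``, so identical specs give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stack import TimeLapseStack

__all__ = [
    "Bump",
    "SyntheticCellMovieSpec",
    "ScriptedCell",
    "GroundTruth",
    "make_protruding_cell_movie",
    "make_nuclei_movie",
    "make_ladder_assay",
    "make_coloc_pair",
    "make_decay_trace",
]


# --------------------------------------------------------------------------
# specs and truth containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Bump:
    """One scripted protrusion/retraction episode.

    The bump drives the boundary radius at angles within ``width/2`` of
    ``center`` outward at ``velocity`` (µm/min, negative = retraction) for
    frames ``start <= t < end``.  The angular velocity profile is flat-top,
    which keeps the protrusive-sector ground truth exact.
    """

    center: float  # rad
    width: float  # rad, > 0; >= 2*pi means the whole boundary
    velocity: float  # µm/min, + = outward
    start: int
    end: int


@dataclass(frozen=True)
class SyntheticCellMovieSpec:
    n_frames: int
    frame_interval: float  # s
    pixel_size: float  # µm/px
    base_radius: float  # µm
    bumps: tuple[Bump, ...] = ()
    enrichment_ratio: float = 2.0  # reporter/reference inside protrusive band
    noise_sd: float = 10.0  # intensity units
    seed: int = 0
    n_boundary_points: int = 400
    band_depth_px: int = 10
    field_size: Optional[tuple[int, int]] = None  # (Y, X) px; auto if None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.enrichment_ratio < 0:
            raise ValueError("enrichment_ratio must be >= 0")
        for b in self.bumps:
            if b.width <= 0:
                raise ValueError("bump widths must be positive")


@dataclass(frozen=True)
class ScriptedCell:
    """Script for one cell in a ladder assay.

    ``area_curve_px2`` gives the mask area (px²) for every frame from
    ``contact_frame`` to the end of the movie.  ``collision_frame`` marks a
    scripted cell-cell contact: a neighbour cell is rendered touching this
    one from that frame on.
    """

    contact_frame: int
    area_curve_px2: tuple[float, ...]
    stripe_index: int
    y_px: float
    collision_frame: Optional[int] = None


@dataclass
class GroundTruth:
    """Truth table paired with a generated movie.

    Only the fields relevant to the generator that produced it are filled.
    Lengths are µm, velocities µm/min unless noted; pixel coordinates follow
    the image convention (x = column, y = row, 0-based pixel centres).
    """

    # protruding-cell movie
    boundaries_px: Optional[np.ndarray] = None  # (T, N, 2) xy
    boundary_radius_um: Optional[np.ndarray] = None  # (T, N)
    normal_velocity: Optional[np.ndarray] = None  # (T-1, N) µm/min
    protrusive: Optional[np.ndarray] = None  # (T, N) bool
    enrichment_ratio: Optional[float] = None
    center_px: Optional[tuple[float, float]] = None  # (x, y)
    # nuclei movie
    tracks: Optional[pd.DataFrame] = None  # track_id, frame, x, y, mother_id
    # ladder assay
    stripe_intervals_um: Optional[list[tuple[float, float]]] = None
    stripe_width_um: Optional[float] = None
    gap_sizes_um: Optional[list[float]] = None
    cells: Optional[list[dict]] = None  # per-cell scripted record
    # coloc pair
    dependence: Optional[float] = None
    expected_icq_sign: Optional[int] = None


# --------------------------------------------------------------------------
# protruding cell movie
# --------------------------------------------------------------------------


def _bump_velocity_field(
    spec: SyntheticCellMovieSpec, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return (v, active) with v: (T-1, N) µm/min and active: (T, N) bool."""
    n_t, n = spec.n_frames, theta.size
    v = np.zeros((n_t - 1, n))
    active = np.zeros((n_t, n), dtype=bool)
    for b in spec.bumps:
        if b.width >= 2 * math.pi:
            sector = np.ones(n, dtype=bool)
        else:
            d = np.angle(np.exp(1j * (theta - b.center)))
            sector = np.abs(d) <= b.width / 2
        for t in range(max(b.start, 0), min(b.end, n_t)):
            active[t, sector] |= True
            if t < n_t - 1:
                v[t, sector] += b.velocity
    return v, active


def make_protruding_cell_movie(
    spec: SyntheticCellMovieSpec,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Render a two-channel movie of a deforming star-convex cell.

    Channel 0 is the reference (F-tractin-like, uniform within the cell),
    channel 1 is a reporter whose background-subtracted signal is
    ``enrichment_ratio`` times the reference inside a ``band_depth_px``-deep
    band over protrusive angular sectors and equal to it elsewhere, so the
    downstream ratiometric pipeline should recover ``enrichment_ratio``
    exactly on average.

    Returns the stack together with exact boundary polygons, per-point
    radial expansion velocities (µm/min, the outward-normal rate for the
    uniform-expansion case) and the protrusive-sector indicator.
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.linspace(0.0, 2 * math.pi, spec.n_boundary_points, endpoint=False)
    dt_min = spec.frame_interval / 60.0

    v, active = _bump_velocity_field(spec, theta)
    r = np.empty((spec.n_frames, theta.size))
    r[0] = spec.base_radius
    for t in range(spec.n_frames - 1):
        r[t + 1] = r[t] + v[t] * dt_min
    if np.any(r <= 0):
        t_bad = int(np.argwhere(r <= 0)[0, 0])
        raise ValueError(f"boundary radius collapses to <= 0 at frame {t_bad}")

    r_px = r / spec.pixel_size
    if spec.field_size is None:
        half = int(math.ceil(r_px.max())) + spec.band_depth_px + 8
        shape = (2 * half + 1, 2 * half + 1)
    else:
        shape = spec.field_size
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    margin = min(cx, cy, shape[1] - 1 - cx, shape[0] - 1 - cy)
    over = np.argwhere(r_px.max(axis=1) > margin - 1)
    if over.size:
        raise ValueError(
            f"boundary exceeds image bounds at frame {int(over[0, 0])}; "
            "enlarge field_size or shrink the bumps"
        )

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rho = np.hypot(xx - cx, yy - cy)
    ang = np.mod(np.arctan2(yy - cy, xx - cx), 2 * math.pi)
    # periodic linear interpolation of r(theta) on the pixel grid
    step = 2 * math.pi / theta.size
    idx0 = np.floor(ang / step).astype(int) % theta.size
    frac = ang / step - np.floor(ang / step)
    idx1 = (idx0 + 1) % theta.size

    bg, fg = 100.0, 1000.0
    pixels = np.empty((spec.n_frames, 2, *shape), dtype=np.float32)
    for t in range(spec.n_frames):
        r_pix = r_px[t, idx0] * (1 - frac) + r_px[t, idx1] * frac
        inside = rho <= r_pix
        band = inside & (rho >= r_pix - spec.band_depth_px)
        prot = active[t, idx0]  # nearest-sector indicator
        reference = np.where(inside, fg, bg)
        factor = np.where(band & prot, spec.enrichment_ratio, 1.0)
        reporter = bg + (reference - bg) * factor
        pixels[t, 0] = reference
        pixels[t, 1] = reporter
    if spec.noise_sd > 0:
        pixels += rng.normal(0.0, spec.noise_sd, size=pixels.shape).astype(np.float32)
        np.clip(pixels, 0, None, out=pixels)

    bx = cx + r_px * np.cos(theta)[None, :]
    by = cy + r_px * np.sin(theta)[None, :]
    truth = GroundTruth(
        boundaries_px=np.stack([bx, by], axis=-1),
        boundary_radius_um=r,
        normal_velocity=(r[1:] - r[:-1]) / dt_min,
        protrusive=active,
        enrichment_ratio=spec.enrichment_ratio,
        center_px=(cx, cy),
    )
    stack = TimeLapseStack(
        pixels,
        pixel_size=spec.pixel_size,
        frame_interval=spec.frame_interval,
        channel_names=("reference", "reporter"),
    )
    return stack, truth


# --------------------------------------------------------------------------
# nuclei movie
# --------------------------------------------------------------------------


def make_nuclei_movie(
    n_cells: int,
    velocity: float,  # µm/h, same magnitude for every cell
    mitosis_events: Sequence[tuple[int, int]] = (),  # (track_id, frame)
    field_size: tuple[int, int] = (256, 256),  # (Y, X) px
    seed: int = 0,
    *,
    n_frames: int = 20,
    frame_interval: float = 600.0,  # s (wound-healing movies: 10 min)
    pixel_size: float = 0.65,  # µm/px
    blob_sigma: float = 2.5,  # px
    noise_sd: float = 8.0,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Render Gaussian-blob nuclei moving on straight paths.

    Initial positions are rejection-sampled so that pairwise separations
    exceed 4x the per-frame displacement (and at least 6 blob sigmas, so no
    two nuclei overlap at t=0).  At each scripted mitosis one blob splits
    into two blobs that diverge perpendicular to the path; the mother track
    id continues with one daughter, the other gets a fresh id and a
    ``mother_id`` entry in the truth table.
    """
    rng = np.random.default_rng(seed)
    h, w = field_size
    step_px = velocity * (frame_interval / 3600.0) / pixel_size
    min_sep = max(4.0 * step_px, 6.0 * blob_sigma)
    margin = 4.0 * blob_sigma + abs(step_px) * n_frames

    if margin * 2 >= min(h, w):
        raise ValueError("field too small for the requested motion")
    # sample full straight trajectories, rejecting any that come within
    # min_sep of an accepted one at ANY frame (keeps tracking well-posed
    # for the whole movie, not just at t = 0)
    frames_idx = np.arange(n_frames)[:, None]
    trajs = np.empty((n_cells, n_frames, 2))
    for i in range(n_cells):
        for _attempt in range(5000):
            p = rng.uniform([margin, margin], [w - margin, h - margin])
            theta = rng.uniform(0, 2 * math.pi)
            v = np.array([math.cos(theta), math.sin(theta)]) * step_px
            cand = p[None, :] + frames_idx * v[None, :]
            if np.any(cand < 3 * blob_sigma) or np.any(
                cand > [w - 3 * blob_sigma, h - 3 * blob_sigma]
            ):
                continue
            if i and np.min(
                np.hypot(*(trajs[:i] - cand[None]).transpose(2, 0, 1))
            ) <= min_sep:
                continue
            trajs[i] = cand
            break
        else:
            raise ValueError(
                "could not place nuclei without overlap; field too crowded"
            )
    pos0 = trajs[:, 0]
    vel = trajs[:, 1] - trajs[:, 0] if n_frames > 1 else np.zeros((n_cells, 2))

    events = {int(tid): int(f) for tid, f in mitosis_events}
    for tid, f in events.items():
        if not (0 <= tid < n_cells):
            raise ValueError(f"mitosis event names unknown track {tid}")
        if not (1 <= f < n_frames):
            raise ValueError(f"mitosis frame {f} outside movie")

    rows: list[tuple[int, int, float, float, object]] = []
    next_id = n_cells
    # per-track state: (position at current frame, velocity, mother or None)
    state: dict[int, dict] = {
        i: {"pos": pos0[i].copy(), "vel": vel[i], "mother": None} for i in range(n_cells)
    }
    blobs_per_frame: list[list[tuple[float, float]]] = []
    for t in range(n_frames):
        # handle splits scheduled for this frame
        for tid, f in list(events.items()):
            if f == t and tid in state:
                s = state[tid]
                perp = np.array([-s["vel"][1], s["vel"][0]])
                nrm = np.hypot(*perp)
                perp = perp / nrm if nrm > 1e-12 else np.array([0.0, 1.0])
                s["split"] = {"frame": t, "perp": perp}
                did = next_id
                next_id += 1
                state[did] = {
                    "pos": s["pos"].copy(),
                    "vel": s["vel"].copy(),
                    "mother": tid,
                    "split": {"frame": t, "perp": -perp},
                }
                del events[tid]
        blobs = []
        for tid in sorted(state):
            s = state[tid]
            p = s["pos"].copy()
            if "split" in s:
                k = t - s["split"]["frame"]
                # daughters are resolvable (>= ~5 blob sigmas apart) from
                # the split frame on, so lineage frames match the script
                sep = 8.0 + 3.0 * min(k, 3)  # px offset from the split axis
                p = p + s["split"]["perp"] * sep
            rows.append((tid, t, p[0], p[1], s["mother"]))
            blobs.append((p[0], p[1]))
            s["pos"] += s["vel"]
        blobs_per_frame.append(blobs)

    yy, xx = np.mgrid[0:h, 0:w]
    pixels = np.empty((n_frames, 1, h, w), dtype=np.float32)
    amp, bgl = 900.0, 80.0
    for t in range(n_frames):
        img = np.full((h, w), bgl, dtype=np.float64)
        for x0, y0 in blobs_per_frame[t]:
            img += amp * np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * blob_sigma**2)
            )
        pixels[t, 0] = img
    if noise_sd > 0:
        pixels += rng.normal(0, noise_sd, size=pixels.shape).astype(np.float32)
        np.clip(pixels, 0, None, out=pixels)

    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "mother_id"])
    tracks = tracks.sort_values(["track_id", "frame"], ignore_index=True)
    stack = TimeLapseStack(
        pixels, pixel_size=pixel_size, frame_interval=frame_interval,
        channel_names=("hoechst",),
    )
    return stack, GroundTruth(tracks=tracks)


# --------------------------------------------------------------------------
# ladder assay
# --------------------------------------------------------------------------


def make_ladder_assay(
    gap_sizes: Sequence[float],  # µm, gaps between consecutive stripes
    stripe_width: float,  # µm
    cells: Sequence[ScriptedCell],
    seed: int = 0,
    *,
    pixel_size: float = 0.5,  # µm/px
    frame_interval: float = 30.0,  # s
    n_frames: Optional[int] = None,
    field_height_px: int = 220,
    margin_um: float = 8.0,
    noise_sd: float = 5.0,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Render a ladder micropattern plus scripted spreading cells.

    Channel 0 shows vertical fluorescent stripes of ``stripe_width`` µm
    separated by the given gaps; channel 1 shows each scripted cell as a
    disk whose area follows its script.  Cells with a ``collision_frame``
    get a touching neighbour disk from that frame on.  Unscripted overlap
    between distinct cells raises an error.
    """
    if stripe_width <= 0 or any(g <= 0 for g in gap_sizes):
        raise ValueError("stripe width and gaps must be positive")
    rng = np.random.default_rng(seed)
    if n_frames is None:
        n_frames = max(c.contact_frame + len(c.area_curve_px2) for c in cells)

    n_stripes = len(gap_sizes) + 1
    centers_um = [margin_um + stripe_width / 2]
    for g in gap_sizes:
        centers_um.append(centers_um[-1] + stripe_width + g)
    width_um = margin_um * 2 + centers_um[-1] + stripe_width / 2
    w = int(math.ceil(width_um / pixel_size))
    h = field_height_px

    xx = np.arange(w)[None, :] * pixel_size  # µm at pixel centres
    pattern = np.full((h, w), 60.0)
    intervals = []
    for c in centers_um:
        lo, hi = c - stripe_width / 2, c + stripe_width / 2
        intervals.append((lo, hi))
        pattern[:, ((xx[0] >= lo) & (xx[0] < hi))] = 1000.0

    for c in cells:
        if not (0 <= c.stripe_index < n_stripes):
            raise ValueError(f"stripe_index {c.stripe_index} out of range")

    yy, xxpx = np.mgrid[0:h, 0:w]
    cell_chan = np.zeros((n_frames, h, w), dtype=np.float32)
    owner = np.full((n_frames, h, w), -1, dtype=np.int16)  # which cell painted
    records = []
    for ci, c in enumerate(cells):
        cx = centers_um[c.stripe_index] / pixel_size
        areas = np.asarray(c.area_curve_px2, dtype=float)
        rendered = np.zeros(len(areas))
        for k, area in enumerate(areas):
            t = c.contact_frame + k
            if t >= n_frames:
                break
            rad = math.sqrt(area / math.pi)
            disk = (xxpx - cx) ** 2 + (yy - c.y_px) ** 2 <= rad**2
            clash = disk & (owner[t] >= 0)
            if clash.any():
                other = int(owner[t][clash][0])
                oc = cells[other]
                ok = (c.collision_frame is not None and t >= c.collision_frame) or (
                    oc.collision_frame is not None and t >= oc.collision_frame
                )
                if not ok:
                    raise ValueError(
                        f"scripted cells {other} and {ci} overlap at frame {t} "
                        "without a collision mark"
                    )
            owner[t][disk] = ci
            cell_chan[t][disk] = 800.0
            rendered[k] = int(disk.sum())
            if c.collision_frame is not None and t >= c.collision_frame:
                # touching neighbour appearing below the subject
                nrad = max(rad * 0.6, 5.0)
                ny = c.y_px + rad + nrad - 1.0  # overlaps by ~1 px
                ndisk = (xxpx - cx) ** 2 + (yy - ny) ** 2 <= nrad**2
                cell_chan[t][ndisk] = 800.0
        records.append(
            {
                "cell_id": ci,
                "contact_frame": c.contact_frame,
                "stripe_index": c.stripe_index,
                "area_curve_px2": areas,
                "area_curve_um2": areas * pixel_size**2,
                "area_rendered_px2": rendered,  # actually painted pixels
                "area_rendered_um2": rendered * pixel_size**2,
                "collision_frame": c.collision_frame,
                "gap_group_um": (
                    gap_sizes[c.stripe_index]
                    if c.stripe_index < len(gap_sizes)
                    else gap_sizes[-1]
                ),
            }
        )

    pixels = np.empty((n_frames, 2, h, w), dtype=np.float32)
    pixels[:, 0] = pattern
    pixels[:, 1] = cell_chan
    if noise_sd > 0:
        pixels += rng.normal(0, noise_sd, size=pixels.shape).astype(np.float32)
        np.clip(pixels, 0, None, out=pixels)

    truth = GroundTruth(
        stripe_intervals_um=intervals,
        stripe_width_um=stripe_width,
        gap_sizes_um=list(gap_sizes),
        cells=records,
    )
    stack = TimeLapseStack(
        pixels, pixel_size=pixel_size, frame_interval=frame_interval,
        channel_names=("fibronectin", "cells"),
    )
    return stack, truth


# --------------------------------------------------------------------------
# coloc pair and decay traces
# --------------------------------------------------------------------------


def make_coloc_pair(
    n_pixels: int, dependence: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw pixel pairs with controlled co-dependence.

    ``B``'s standardized latent is ``rho*Az + sqrt(1-rho^2)*W`` with ``W``
    independent noise, so ``rho=1`` makes B a strictly increasing (affine)
    transform of A, ``rho=-1`` a strictly decreasing one, and ``rho=0``
    independent.  Returns ``(A, B, expected ICQ sign)``.
    """
    if n_pixels < 100:
        raise ValueError("n_pixels must be >= 100")
    rho = float(dependence)
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("dependence must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    az = rng.standard_normal(n_pixels)
    wn = rng.standard_normal(n_pixels)
    bz = rho * az + math.sqrt(max(0.0, 1.0 - rho**2)) * wn
    a = 500.0 + 80.0 * az
    b = 500.0 + 80.0 * bz
    sign = 0 if rho == 0 else (1 if rho > 0 else -1)
    return a, b, sign


def make_decay_trace(
    tau: Optional[float],  # s; None = frozen (no decay)
    n_samples: int = 60,
    dt: float = 1.0,  # s
    i0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Photoactivation trace: ``i0 * exp(-t/tau)`` (constant if tau is None)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * dt
    y = np.full(n_samples, float(i0)) if tau is None else i0 * np.exp(-t / tau)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n_samples)
    return t, y
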