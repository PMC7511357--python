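"""Nuclei segmentation, nearest-neighbour tracking, and migration metrics.

Built for scratch-wound movies of Hoechst-stained nuclei: nuclei are
segmented frame by frame (smoothing + Otsu + area gating), linked into
tracks by a deterministic greedy nearest-neighbour rule with a maximum
displacement gate, with mitoses handled by keeping the mother's id on one
daughter and opening a lineage-recorded track for the other.  Single-cell
speeds are mean frame-to-frame nuclear displacements in µm/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "TrackSet",
    "VelocityReport",
    "segment_nuclei",
    "link_tracks",
    "compute_velocities",
    "scratch_closure",
]


@dataclass
class TrackSet:
    """Per-nucleus trajectories with lineage records.

    ``tracks`` maps id -> list of (frame, x, y); frames within a track are
    strictly increasing and no two tracks share a detection.  ``lineage``
    lists (daughter_id, mother_id, split_frame) triples.
    """

    tracks: dict[int, list[tuple[int, float, float]]]
    lineage: list[tuple[int, int, int]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        mothers = {d: m for d, m, _ in self.lineage}
        rows = [
            (tid, f, x, y, mothers.get(tid))
            for tid, pts in sorted(self.tracks.items())
            for f, x, y in pts
        ]
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "mother_id"])


@dataclass
class VelocityReport:
    per_cell: pd.DataFrame  # track_id, speed_um_per_h, n_steps
    mean_um_per_h: float
    ci95_um_per_h: tuple[float, float]
    min_track_len: int


def segment_nuclei(
    frame: np.ndarray,
    sigma: float = 2.0,
    min_area: int = 20,
    max_area: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect nuclei in one frame; returns (centroids_xy, areas_px).

    Smoothing + Otsu threshold + hole filling, then components outside the
    [min_area, max_area] px² range are dropped.  Centroids are
    intensity-weighted on the raw frame.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise ValueError("no threshold separable: frame is constant")
    smooth = gaussian(frame, sigma=sigma, preserve_range=True)
    mask = ndi.binary_fill_holes(smooth > threshold_otsu(smooth))
    lab = label(mask)
    centroids, areas = [], []
    for rp in regionprops(lab, intensity_image=frame):
        if min_area <= rp.area <= max_area:
            cy, cx = rp.centroid_weighted
            centroids.append((cx, cy))
            areas.append(rp.area)
    return (
        np.asarray(centroids, dtype=float).reshape(-1, 2),
        np.asarray(areas, dtype=float),
    )


def link_tracks(
    detections: Sequence[np.ndarray],
    max_displacement: float,
) -> TrackSet:
    """Link per-frame detections into tracks with mitosis handling.

    Greedy ascending-distance assignment of detections to tracks open at
    the previous frame, gated at ``max_displacement`` px.  A leftover
    detection within the gate of a track that also received a normal match
    this frame is taken as the second daughter of a division: it opens a
    new track carrying a lineage record.  Other leftover detections open
    plain new tracks; tracks with no match are closed (no gap bridging).
    """
    if len(detections) < 2:
        raise ValueError("need detections from at least 2 frames")
    tracks: dict[int, list[tuple[int, float, float]]] = {}
    lineage: list[tuple[int, int, int]] = []
    next_id = 0
    open_ids: list[int] = []
    open_pos = np.empty((0, 2))

    for t, det in enumerate(detections):
        det = np.asarray(det, dtype=float).reshape(-1, 2)
        if t == 0:
            for p in det:
                tracks[next_id] = [(0, p[0], p[1])]
                open_ids.append(next_id)
                next_id += 1
            open_pos = det.copy()
            continue

        n_open, n_det = len(open_ids), len(det)
        assigned_det = np.full(n_det, -1)  # detection -> track id
        matched_track: dict[int, int] = {}  # track id -> detection index
        if n_open and n_det:
            diff = open_pos[:, None, :] - det[None, :, :]
            dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            order = np.argsort(dist, axis=None, kind="stable")
            used_tr = np.zeros(n_open, dtype=bool)
            used_de = np.zeros(n_det, dtype=bool)
            for flat in order:
                i, j = divmod(int(flat), n_det)
                if dist[i, j] > max_displacement:
                    break
                if used_tr[i] or used_de[j]:
                    continue
                used_tr[i] = used_de[j] = True
                tid = open_ids[i]
                assigned_det[j] = tid
                matched_track[tid] = j
        else:
            dist = None

        # mitosis check for leftover detections
        for j in np.nonzero(assigned_det < 0)[0]:
            mother = None
            if dist is not None:
                cands = [
                    (dist[i, j], open_ids[i])
                    for i in range(n_open)
                    if open_ids[i] in matched_track and dist[i, j] <= max_displacement
                ]
                if cands:
                    mother = min(cands)[1]
            tid = next_id
            next_id += 1
            tracks[tid] = []
            assigned_det[j] = tid
            if mother is not None:
                lineage.append((tid, mother, t))

        for j, tid in enumerate(assigned_det):
            tracks[int(tid)].append((t, det[j, 0], det[j, 1]))

        open_ids = [int(tid) for tid in assigned_det]
        open_pos = det.copy()

    return TrackSet(tracks=tracks, lineage=lineage)


def compute_velocities(
    track_set: TrackSet,
    pixel_size: float,
    frame_interval: float,
    min_track_len: int = 5,
) -> VelocityReport:
    """Per-cell mean speeds in µm/h with a population summary.

    Speed per cell is the mean over consecutive-frame displacements,
    converted with the calibration; tracks shorter than ``min_track_len``
    frames are excluded as noise.
    """
    from scipy import stats

    per_h = 3600.0 / frame_interval
    rows = []
    for tid, pts in sorted(track_set.tracks.items()):
        if len(pts) < min_track_len:
            continue
        arr = np.asarray(pts, dtype=float)
        steps = np.diff(arr[:, 1:3], axis=0)
        dt = np.diff(arr[:, 0])
        disp = np.hypot(steps[:, 0], steps[:, 1]) / dt  # px per frame
        speed = float(disp.mean() * pixel_size * per_h)
        rows.append((tid, speed, len(pts) - 1))
    if not rows:
        raise ValueError(f"no tracks of length >= {min_track_len}")
    df = pd.DataFrame(rows, columns=["track_id", "speed_um_per_h", "n_steps"])
    speeds = df["speed_um_per_h"].to_numpy()
    mean = float(speeds.mean())
    if len(speeds) > 1:
        sem = stats.sem(speeds)
        half = sem * stats.t.ppf(0.975, len(speeds) - 1)
    else:
        half = float("nan")
    return VelocityReport(
        per_cell=df,
        mean_um_per_h=mean,
        ci95_um_per_h=(mean - half, mean + half),
        min_track_len=min_track_len,
    )


def scratch_closure(
    masks: np.ndarray,
    scratch_region: np.ndarray,
) -> np.ndarray:
    """Fraction of the scratch region covered by cells per frame.

    ``masks`` is a (T, Y, X) boolean cell/nuclei-density mask series and
    ``scratch_region`` the (Y, X) boolean scratch area defined at t = 0.
    """
    masks = np.asarray(masks, dtype=bool)
    region = np.asarray(scratch_region, dtype=bool)
    total = int(region.sum())
    if total == 0:
        raise ValueError("empty scratch region")
    return masks[:, region].sum(axis=1) / total
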