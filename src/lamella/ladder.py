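"""Micropattern ladder assays: stripe geometry, contact, and gap bridging.

Ladder patterns are parallel adhesive fibronectin stripes (nominally 2 µm
wide) separated by non-adhesive PLL-PEG gaps of 4-16 µm.  This module
recovers the stripe geometry from the fluorescent-pattern channel, finds
the frame where a spreading cell first makes full contact with a stripe,
and quantifies bridging: the cell-area change 1 h after contact (with the
exclusion rules for cell-cell contact, occupied neighbour stripes, and
cells leaving the field), relative-area time courses, and the change in the
number of stripes occupied after a treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = [
    "PatternLayout",
    "SpreadingRecord",
    "OccupancyDelta",
    "detect_stripes",
    "detect_contact",
    "area_change_after_contact",
    "stripes_occupied_delta",
]


@dataclass
class PatternLayout:
    """Geometry of a ladder pattern.

    Stripes are described by intervals along the stripe-normal axis in µm
    (the projected coordinate ``x*cos(a) + y*sin(a)``, ``a`` =
    ``normal_angle_rad``).  Gaps are clear spacings between consecutive
    stripe intervals.
    """

    normal_angle_rad: float
    intervals_um: list[tuple[float, float]]  # sorted, non-overlapping
    pixel_size: float

    @property
    def centers_um(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.intervals_um])

    @property
    def widths_um(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in self.intervals_um])

    @property
    def gaps_um(self) -> np.ndarray:
        iv = self.intervals_um
        return np.array([iv[k + 1][0] - iv[k][1] for k in range(len(iv) - 1)])

    def gap_group(self, stripe_index: int) -> float:
        """Gap size (µm) of the lane entered from the given stripe."""
        gaps = self.gaps_um
        return float(gaps[min(stripe_index, len(gaps) - 1)])

    @classmethod
    def from_intervals(
        cls, intervals_um: Sequence[tuple[float, float]], pixel_size: float,
        normal_angle_rad: float = 0.0,
    ) -> "PatternLayout":
        return cls(normal_angle_rad, [tuple(iv) for iv in intervals_um], pixel_size)

    # projected coordinates for an image of the given shape
    def normal_coordinate(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        a = self.normal_angle_rad
        return (xx * math.cos(a) + yy * math.sin(a)) * self.pixel_size

    def along_coordinate(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        a = self.normal_angle_rad
        return (-xx * math.sin(a) + yy * math.cos(a)) * self.pixel_size

    def stripe_masks(self, shape: tuple[int, int]) -> list[np.ndarray]:
        c = self.normal_coordinate(shape)
        return [(c >= lo) & (c < hi) for lo, hi in self.intervals_um]


@dataclass
class SpreadingRecord:
    cell_id: int
    contact_frame: Optional[int]
    gap_group_um: Optional[float]
    area_at_contact_um2: Optional[float] = None
    area_after_um2: Optional[float] = None
    delta_area_um2: Optional[float] = None
    relative_area: Optional[np.ndarray] = None  # 1.0 at the contact frame
    times_min: Optional[np.ndarray] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None


@dataclass
class OccupancyDelta:
    cell_id: int
    treatment_label: str
    stripes_pre: Optional[int] = None
    stripes_post: Optional[int] = None
    delta: Optional[int] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None


# --------------------------------------------------------------------------
# stripe detection
# --------------------------------------------------------------------------


def _profile_variance(img: np.ndarray, angle: float) -> float:
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    c = xx * math.cos(angle) + yy * math.sin(angle)
    c = c - c.min()
    bins = np.round(c).astype(int)
    nbins = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=img.ravel(), minlength=nbins)
    counts = np.bincount(bins.ravel(), minlength=nbins)
    ok = counts > 0
    prof = sums[ok] / counts[ok]
    return float(prof.var())


def _refine_angle(img: np.ndarray, coarse: float, half_range: float) -> float:
    best, best_score = coarse, -np.inf
    for a in np.arange(coarse - half_range, coarse + half_range, math.radians(0.05)):
        score = _profile_variance(img, a)
        if score > best_score:
            best, best_score = a, score
    return float(best)


def detect_stripes(
    pattern: np.ndarray, pixel_size: float, min_width_um: float = 0.5
) -> PatternLayout:
    """Recover stripe geometry from a fluorescent-pattern image.

    The stripe-normal orientation is the dominant gradient direction
    (structure tensor over the whole image); intensities are then projected
    onto that axis, the 1-D profile is Otsu-thresholded, and above-threshold
    runs become stripe intervals with sub-bin edge interpolation.
    """
    img = np.asarray(pattern, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("blank pattern image")
    # coarse stripe-normal direction from Gaussian-derivative gradients
    # (central differences carry a degree-scale orientation bias on
    # diagonal edges); mode of the energy-weighted orientation histogram is
    # immune to the minority of orthogonal gradients at field borders
    gx = ndi.gaussian_filter(img, 2.0, order=(0, 1))
    gy = ndi.gaussian_filter(img, 2.0, order=(1, 0))
    mag2 = gx * gx + gy * gy
    ori = np.mod(np.arctan2(gy, gx), math.pi)
    hist, edges = np.histogram(ori, bins=360, range=(0, math.pi), weights=mag2)
    peak = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2
    # refine by maximizing the contrast of the projected 1-D profile: the
    # sharpest profile is obtained exactly when projecting along the stripes
    angle = _refine_angle(img, peak, half_range=math.radians(3.0))
    # normalize so cos(angle) > 0: projected coordinate increases with x,
    # keeping stripe order stable
    if angle > math.pi / 2:
        angle -= math.pi
    elif angle <= -math.pi / 2:
        angle += math.pi

    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    c = xx * math.cos(angle) + yy * math.sin(angle)  # px along the normal
    c = c - c.min()
    nbins = int(math.ceil(c.max())) + 1
    bins = np.clip(np.round(c).astype(int), 0, nbins - 1)
    sums = np.bincount(bins.ravel(), weights=img.ravel(), minlength=nbins)
    counts = np.bincount(bins.ravel(), minlength=nbins)
    valid = counts > 0
    profile = np.full(nbins, np.nan)
    profile[valid] = sums[valid] / counts[valid]
    prof = profile[valid]
    pos = np.arange(nbins)[valid].astype(float)

    thr = threshold_otsu(prof)
    above = prof > thr
    # edge refinement at the half-maximum level: symmetric w.r.t. blur, so
    # stripe centers and widths stay unbiased even on rotated/resampled images
    lo_level = float(np.median(prof[~above])) if (~above).any() else float(prof.min())
    hi_level = float(np.median(prof[above]))
    half = (lo_level + hi_level) / 2.0
    intervals_px = []
    k = 0
    while k < len(prof):
        if above[k]:
            j = k
            while j + 1 < len(prof) and above[j + 1]:
                j += 1
            lo, hi = pos[k], pos[j]
            if k > 0 and prof[k] > prof[k - 1]:
                lo = pos[k - 1] + (half - prof[k - 1]) / (prof[k] - prof[k - 1]) * (
                    pos[k] - pos[k - 1]
                )
                lo = float(np.clip(lo, pos[k - 1], pos[k]))
            if j + 1 < len(prof) and prof[j] > prof[j + 1]:
                hi = pos[j] + (prof[j] - half) / (prof[j] - prof[j + 1]) * (
                    pos[j + 1] - pos[j]
                )
                hi = float(np.clip(hi, pos[j], pos[j + 1]))
            intervals_px.append((lo, hi))
            k = j + 1
        else:
            k += 1

    intervals_um = [
        (lo * pixel_size, hi * pixel_size)
        for lo, hi in intervals_px
        if (hi - lo) * pixel_size >= min_width_um
    ]
    if len(intervals_um) < 2:
        raise ValueError(f"only {len(intervals_um)} stripes found (need >= 2)")
    return PatternLayout(
        normal_angle_rad=angle, intervals_um=intervals_um, pixel_size=pixel_size
    )


# --------------------------------------------------------------------------
# contact detection
# --------------------------------------------------------------------------


def _overlap_fractions(
    mask: np.ndarray, layout: PatternLayout, stripe_masks: list[np.ndarray],
    along: np.ndarray,
) -> np.ndarray:
    """Per-stripe fraction of the stripe segment under the cell footprint."""
    out = np.zeros(len(stripe_masks))
    if not mask.any():
        return out
    u = along[mask]
    umin, umax = u.min(), u.max()
    footprint = (along >= umin) & (along <= umax)
    for k, sm in enumerate(stripe_masks):
        seg = sm & footprint
        denom = int(seg.sum())
        if denom:
            out[k] = int((mask & seg).sum()) / denom
    return out


def detect_contact(
    cell_masks: np.ndarray,
    layout: PatternLayout,
    overlap_min: float = 0.5,
    persist: int = 2,
) -> tuple[Optional[int], Optional[int]]:
    """First frame of sustained full contact with a stripe.

    Contact requires the cell mask to cover at least ``overlap_min`` of the
    stripe segment under its footprint for ``persist`` consecutive frames.
    Returns ``(contact_frame, stripe_index)``; ``(None, None)`` when no
    contact occurs within the movie.
    """
    masks = np.asarray(cell_masks, dtype=bool)
    shape = masks.shape[1:]
    stripe_masks = layout.stripe_masks(shape)
    along = layout.along_coordinate(shape)
    fracs = np.stack(
        [_overlap_fractions(masks[t], layout, stripe_masks, along) for t in range(len(masks))]
    )  # (T, S)
    hits = fracs >= overlap_min
    for t in range(len(masks) - persist + 1):
        sustained = hits[t : t + persist].all(axis=0)
        if sustained.any():
            stripe = int(np.argmax(np.where(sustained, fracs[t], -1)))
            return t, stripe
    return None, None


# --------------------------------------------------------------------------
# spreading quantification
# --------------------------------------------------------------------------


def _touches(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    """Masks touching within 1 px (merge or contact)."""
    if not (mask_a.any() and mask_b.any()):
        return False
    return bool((ndi.binary_dilation(mask_a) & mask_b).any())


def area_change_after_contact(
    cell_masks: np.ndarray,
    contact_frame: int,
    stripe_index: int,
    layout: PatternLayout,
    pixel_size: float,
    frame_interval: float,
    horizon_s: float = 3600.0,
    other_masks: Sequence[np.ndarray] = (),
    cell_id: int = 0,
) -> SpreadingRecord:
    """Cell-area change over ``horizon_s`` (default 1 h) after first contact.

    The cell is excluded (with the reason recorded) if, during the horizon,
    it touches another cell, another cell occupies a stripe neighbouring
    the contacted one, it leaves the field, or the movie ends early.
    The relative-area curve (1.0 at contact) is always reported.
    """
    masks = np.asarray(cell_masks, dtype=bool)
    n_t = masks.shape[0]
    h_frames = int(round(horizon_s / frame_interval))
    end = contact_frame + h_frames
    gap_group = layout.gap_group(stripe_index)

    record = SpreadingRecord(
        cell_id=cell_id, contact_frame=contact_frame, gap_group_um=gap_group
    )
    area = masks.sum(axis=(1, 2)).astype(float) * pixel_size**2
    upto = min(end, n_t - 1)
    rel = area[contact_frame : upto + 1] / area[contact_frame]
    record.relative_area = rel
    record.times_min = (
        np.arange(contact_frame, upto + 1) - contact_frame
    ) * frame_interval / 60.0

    if end >= n_t:
        record.excluded = True
        record.exclusion_reason = "movie ends before horizon"
        return record

    shape = masks.shape[1:]
    stripe_masks = layout.stripe_masks(shape)
    neighbours = [
        stripe_masks[k]
        for k in (stripe_index - 1, stripe_index + 1)
        if 0 <= k < len(stripe_masks)
    ]
    for t in range(contact_frame, end + 1):
        if not masks[t].any() or _on_border(masks[t]):
            record.excluded = True
            record.exclusion_reason = "left field"
            return record
        for om in other_masks:
            other = np.asarray(om, dtype=bool)[t]
            if _touches(masks[t], other):
                record.excluded = True
                record.exclusion_reason = "cell-cell contact"
                return record
            if any((other & nb).any() for nb in neighbours):
                record.excluded = True
                record.exclusion_reason = "neighbor stripe occupied"
                return record

    record.area_at_contact_um2 = float(area[contact_frame])
    record.area_after_um2 = float(area[end])
    record.delta_area_um2 = float(area[end] - area[contact_frame])
    return record


def _on_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def stripes_occupied_delta(
    cell_masks: np.ndarray,
    layout: PatternLayout,
    treatment_frame: int,
    pixel_size: float,
    frame_interval: float,
    horizon_s: float = 2700.0,
    overlap_min: float = 0.5,
    min_pre_s: float = 1800.0,
    other_masks: Sequence[np.ndarray] = (),
    treatment_label: str = "",
    cell_id: int = 0,
) -> OccupancyDelta:
    """Change in the number of stripes contacted after a treatment.

    Counts stripes whose overlap fraction passes ``overlap_min`` just
    before treatment and at treatment + ``horizon_s`` (default 45 min), and
    returns post - pre.  The cell must have been present for at least
    ``min_pre_s`` (default 30 min) before treatment and must never touch
    another cell over the analysed span; otherwise it is excluded with the
    reason recorded.
    """
    masks = np.asarray(cell_masks, dtype=bool)
    n_t = masks.shape[0]
    pre_frames = int(round(min_pre_s / frame_interval))
    post_frame = treatment_frame + int(round(horizon_s / frame_interval))

    record = OccupancyDelta(cell_id=cell_id, treatment_label=treatment_label)
    if treatment_frame - pre_frames < 0 or not all(
        masks[t].any() for t in range(treatment_frame - pre_frames, treatment_frame + 1)
    ):
        record.excluded = True
        record.exclusion_reason = "present < 30 min before treatment"
        return record
    if post_frame >= n_t:
        record.excluded = True
        record.exclusion_reason = "movie ends before horizon"
        return record
    for t in range(treatment_frame - pre_frames, post_frame + 1):
        for om in other_masks:
            if _touches(masks[t], np.asarray(om, dtype=bool)[t]):
                record.excluded = True
                record.exclusion_reason = "cell-cell contact"
                return record

    shape = masks.shape[1:]
    stripe_masks = layout.stripe_masks(shape)
    along = layout.along_coordinate(shape)
    pre = _overlap_fractions(masks[treatment_frame], layout, stripe_masks, along)
    post = _overlap_fractions(masks[post_frame], layout, stripe_masks, along)
    record.stripes_pre = int((pre >= overlap_min).sum())
    record.stripes_post = int((post >= overlap_min).sum())
    record.delta = record.stripes_post - record.stripes_pre
    return record
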