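"""Channel registration, cell segmentation, background subtraction, ratios.

The ratiometric workflow is: register the two channels from paired control
points, segment the cell by automated intensity thresholding, subtract a
local (ring-median) background estimate per channel, then divide reporter
by reference over the cell mask.  The 3rd/99th percentile bounds carried by
:class:`RatioImage` are display clips only; stored values are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label

from .stack import TimeLapseStack

__all__ = [
    "CellMask",
    "RatioImage",
    "RegistrationReport",
    "fit_affine",
    "register_channels",
    "segment_cell",
    "subtract_local_background",
    "compute_ratio_image",
]


@dataclass
class CellMask:
    """Boolean cell mask for one frame (largest connected component)."""

    mask: np.ndarray  # bool (Y, X)
    area_px: int
    largest_component: bool = True


@dataclass
class RatioImage:
    """Pixel-wise numerator/denominator ratio with validity mask.

    ``values`` is defined (finite) only where ``valid`` is True: inside the
    cell mask and where the denominator exceeds its floor.  ``clip_low`` /
    ``clip_high`` are the 3rd and 99th percentiles of the valid values,
    intended for colormap scaling only.
    """

    values: np.ndarray  # float (Y, X), NaN where invalid
    valid: np.ndarray  # bool (Y, X)
    clip_low: float
    clip_high: float


@dataclass
class RegistrationReport:
    matrix: np.ndarray  # 2x3 affine (maps fixed -> moving coordinates)
    residual_px: float  # max control-point residual after the fit
    warning: Optional[str] = None


def fit_affine(
    fixed_points: np.ndarray, moving_points: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares affine map sending fixed (x, y) onto moving (x, y).

    Raises if fewer than 3 pairs are given or the points are collinear.
    """
    fp = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    mp = np.atleast_2d(np.asarray(moving_points, dtype=float))
    if fp.shape != mp.shape or fp.shape[0] < 3 or fp.shape[1] != 2:
        raise ValueError("need >= 3 paired (x, y) control points")
    design = np.column_stack([fp, np.ones(len(fp))])
    if np.linalg.matrix_rank(design, tol=1e-8 * max(1.0, np.abs(design).max())) < 3:
        raise ValueError("control points are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, mp, rcond=None)
    matrix = coef.T  # 2x3, rows = (x', y') in the moving frame
    pred = design @ coef
    residual = float(np.abs(pred - mp).max()) if len(fp) else 0.0
    return matrix, residual


def register_channels(
    stack: TimeLapseStack,
    control_points: tuple[np.ndarray, np.ndarray],
    moving_channel: int = 1,
    residual_tol: float = 0.5,
) -> tuple[TimeLapseStack, RegistrationReport]:
    """Remap one channel onto the other from paired control points.

    ``control_points`` is ``(fixed_xy, moving_xy)``: coordinates of the same
    landmarks seen in the fixed and the moving channel.  The moving channel
    is resampled with bilinear interpolation so its landmarks land on the
    fixed coordinates.
    """
    matrix, residual = fit_affine(*control_points)
    warning = None
    if residual > residual_tol:
        warning = f"control-point residual {residual:.3g} px exceeds {residual_tol} px"

    a = matrix[:, :2]  # x' = a @ (x, y) + b
    b = matrix[:, 2]
    # map_coordinates works in (row, col) = (y, x): build the pullback
    swap = np.array([[0, 1], [1, 0]], dtype=float)
    m_rc = swap @ a @ swap
    off_rc = swap @ b
    out = np.array(stack.pixels, copy=True)
    for t in range(stack.n_frames):
        out[t, moving_channel] = ndi.affine_transform(
            stack.pixels[t, moving_channel].astype(float),
            m_rc,
            offset=off_rc,
            order=1,
            mode="nearest",
        )
    reg = TimeLapseStack(
        out, stack.pixel_size, stack.frame_interval, stack.channel_names
    )
    return reg, RegistrationReport(matrix=matrix, residual_px=residual, warning=warning)


def segment_cell(
    frame: np.ndarray, sigma: float = 2.0, min_area: int = 64
) -> CellMask:
    """Segment the cell by Gaussian smoothing + Otsu + morphological cleanup.

    Holes are filled, components below ``min_area`` px² dropped, and the
    largest connected component retained.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("segment_cell expects a single 2-D frame")
    if np.ptp(frame) == 0:
        raise ValueError("no threshold separable: frame is constant")
    smooth = gaussian(frame, sigma=sigma, preserve_range=True)
    mask = smooth > threshold_otsu(smooth)
    mask = ndi.binary_fill_holes(mask)
    lab = label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = np.nonzero(sizes >= min_area)[0]
    if keep.size == 0:
        raise ValueError("no component above min_area")
    largest = keep[np.argmax(sizes[keep])]
    mask = lab == largest
    return CellMask(mask=mask, area_px=int(mask.sum()))


def subtract_local_background(
    frame: np.ndarray, mask: np.ndarray, ring_width: int = 10, dilate: int = 2
) -> np.ndarray:
    """Subtract the median of a ring just outside the (dilated) cell mask.

    Negative results are clipped to zero.  Raises when the ring is empty
    (mask fills the frame).
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    outer = ndi.binary_dilation(mask, iterations=dilate + ring_width)
    inner = ndi.binary_dilation(mask, iterations=dilate)
    ring = outer & ~inner
    if not ring.any():
        raise ValueError("empty background ring: mask fills the field")
    bg = float(np.median(frame[ring]))
    return np.clip(frame - bg, 0.0, None)


def compute_ratio_image(
    numerator: np.ndarray,
    denominator: np.ndarray,
    mask: np.ndarray,
    denom_floor: float = 1.0,
) -> RatioImage:
    """Pixel-wise numerator/denominator over the mask.

    Pixels where the denominator does not exceed ``denom_floor`` are marked
    invalid (NaN) rather than producing unstable ratios.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    valid = mask & (den > denom_floor)
    if not valid.any():
        raise ValueError("no valid pixels: mask empty or denominator at floor")
    values = np.full(num.shape, np.nan)
    values[valid] = num[valid] / den[valid]
    lo, hi = np.percentile(values[valid], [3, 99])
    return RatioImage(values=values, valid=valid, clip_low=float(lo), clip_high=float(hi))
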