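"""Line kymographs and protrusion/retraction rate fitting.

A kymograph stacks, frame by frame, the intensities sampled along a fixed
line across the cell edge (optionally averaged over a few parallel lines),
so protrusion and retraction episodes appear as slanted fronts whose slope
is the edge speed.  Traced fronts — hand-drawn polylines or the bundled
automatic tracer — are converted to rates in µm/min by an ordinary
least-squares line fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import medfilt
from skimage.filters import threshold_otsu

from .stack import TimeLapseStack

__all__ = [
    "Kymograph",
    "RateEstimate",
    "extract_kymograph",
    "fit_trace_rate",
    "detect_front",
]


@dataclass
class Kymograph:
    """Distance-by-time image sampled along a line.

    ``data`` has one row per frame; columns run along the line from its
    first endpoint.  ``pixel_size`` is µm per sample along the line and
    ``frame_interval`` seconds per row.
    """

    data: np.ndarray  # (T, L)
    pixel_size: float  # µm per column
    frame_interval: float  # s per row
    line: tuple[tuple[float, float], tuple[float, float]]
    width_px: int = 1

    @property
    def duration_min(self) -> float:
        return self.data.shape[0] * self.frame_interval / 60.0


@dataclass
class RateEstimate:
    """Edge speed from a traced front: + protrusion, - retraction."""

    rate_um_per_min: float
    r_squared: float
    n_points: int


def extract_kymograph(
    stack: TimeLapseStack,
    channel: int,
    line: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 1,
) -> Kymograph:
    """Sample intensities along a line in every frame (bilinear).

    ``line`` is ((x0, y0), (x1, y1)) in pixel coordinates.  ``width_px``
    parallel offsets perpendicular to the line are averaged.  Sample
    spacing along the line is one pixel.
    """
    (x0, y0), (x1, y1) = line
    series = stack.channel(channel)
    h, w = series.shape[-2:]
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"line endpoint ({x}, {y}) outside the image")
    length = int(round(np.hypot(x1 - x0, y1 - y0))) + 1
    t_par = np.linspace(0.0, 1.0, length)
    xs = x0 + t_par * (x1 - x0)
    ys = y0 + t_par * (y1 - y0)
    # unit perpendicular for width averaging
    norm = np.hypot(x1 - x0, y1 - y0)
    if norm == 0:
        raise ValueError("line endpoints coincide")
    px, py = -(y1 - y0) / norm, (x1 - x0) / norm
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    data = np.empty((stack.n_frames, length))
    for t in range(stack.n_frames):
        acc = np.zeros(length)
        for off in offsets:
            coords = np.vstack([ys + off * py, xs + off * px])  # (row, col)
            acc += ndi.map_coordinates(
                series[t].astype(float), coords, order=1, mode="nearest"
            )
        data[t] = acc / len(offsets)
    step_um = stack.pixel_size * norm / (length - 1) if length > 1 else stack.pixel_size
    return Kymograph(
        data=data,
        pixel_size=step_um,
        frame_interval=stack.frame_interval,
        line=line,
        width_px=width_px,
    )


def fit_trace_rate(
    trace: np.ndarray,
    pixel_size: float,
    frame_interval: float,
) -> RateEstimate:
    """OLS slope of a traced front, converted to µm/min.

    ``trace`` is an (n, 2) array of (distance_px, frame) points with
    strictly increasing frames.  Rate = slope(px/frame) * pixel_size(µm/px)
    * 60/frame_interval(s).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] < 2 or trace.shape[1] != 2:
        raise ValueError("trace must be (n >= 2, 2) of (distance_px, frame)")
    d, f = trace[:, 0], trace[:, 1]
    if np.any(np.diff(f) <= 0):
        raise ValueError("trace frames must be strictly increasing")
    slope, intercept = np.polyfit(f, d, 1)
    pred = slope * f + intercept
    ss_res = float(((d - pred) ** 2).sum())
    ss_tot = float(((d - d.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rate = slope * pixel_size * (60.0 / frame_interval)
    return RateEstimate(rate_um_per_min=float(rate), r_squared=r2, n_points=len(trace))


def detect_front(
    kymo: Kymograph,
    direction: str = "outward",
    median_size: int = 3,
) -> np.ndarray:
    """Automatic front tracer: per-row outermost super-threshold column.

    The threshold is Otsu's, computed once per kymograph.  ``direction``
    ``"outward"`` takes the outermost super-threshold column per row (front
    moving toward increasing distance); ``"inward"`` the innermost.  A
    position only counts when two adjacent samples are super-threshold,
    which rejects isolated noise pixels.  Positions are lightly
    median-filtered; rows with no super-threshold run are skipped.
    Returns an (n, 2) array of (distance_px, frame) ready for
    :func:`fit_trace_rate`.
    """
    data = kymo.data
    if np.ptp(data) == 0:
        raise ValueError("no front: kymograph is constant")
    thr = threshold_otsu(data)
    above = data > thr
    paired = above[:, 1:] & above[:, :-1]  # runs of length >= 2
    rows, positions = [], []
    for t in range(data.shape[0]):
        cols = np.nonzero(paired[t])[0]
        if cols.size == 0:
            continue
        pos = cols[-1] + 1 if direction == "outward" else cols[0]
        rows.append(t)
        positions.append(pos)
    if len(rows) < 2:
        raise ValueError("no front: fewer than 2 rows above threshold")
    positions = np.asarray(positions, dtype=float)
    if median_size > 1 and len(positions) >= median_size:
        positions = medfilt(positions, kernel_size=median_size | 1)
    return np.column_stack([positions, np.asarray(rows, dtype=float)])
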