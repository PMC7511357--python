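"""Line-intensity profiles, LOWESS landmarks, decay and length measurements.

Profiles are sampled along user-drawn lines running from the outermost cell
edge (position 0) inward toward the lamellum, normalized per cell and
channel to the line maximum, and summarized as the per-position median
across cells.  LOWESS-smoothed curves yield two landmarks: the cell edge
(first F-actin peak from the front) and the onset of myosin activity (the
beginning of the rising MYL9 slope, taken where the slope first exceeds a
fraction of its maximum).  Photoactivation decay traces are normalized to
the activation frame and summarized by the 50% crossing time; ROI polyline
lengths quantify protrusion widths and branched-network depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

__all__ = [
    "LineProfile",
    "ProfileLandmarks",
    "DecayTrace",
    "profile_lines",
    "fit_lowess",
    "find_landmarks",
    "decay_halftime",
    "measure_roi_lengths",
]


@dataclass
class LineProfile:
    """Median per-position intensity profile across cells.

    ``positions`` run from 0 µm (line start, the cell edge) inward.
    ``median`` maps channel name -> per-position median of the per-line
    max-normalized intensities; ``per_line`` keeps the normalized
    single-line profiles.
    """

    positions: np.ndarray  # µm from the edge
    median: dict[str, np.ndarray]
    per_line: dict[str, np.ndarray]  # (n_lines, n_positions)


@dataclass
class ProfileLandmarks:
    edge_um: Optional[float]
    onset_um: Optional[float]
    reason: Optional[str] = None  # set when a landmark is undefined


@dataclass
class DecayTrace:
    times_s: np.ndarray
    normalized: np.ndarray  # 1.0 at activation
    half_time_s: Optional[float]  # None when 0.5 is never crossed


def _sample_polyline(
    image: np.ndarray, polyline: np.ndarray, step_px: float
) -> np.ndarray:
    pts = np.asarray(polyline, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = int(np.floor(s[-1] / step_px)) + 1
    target = np.arange(n) * step_px
    xs = np.interp(target, s, pts[:, 0])
    ys = np.interp(target, s, pts[:, 1])
    h, w = image.shape
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise ValueError("profile line exits the image")
    return ndi.map_coordinates(image.astype(float), np.vstack([ys, xs]), order=1)


def profile_lines(
    images: dict[str, np.ndarray],
    lines: Sequence[np.ndarray],
    sample_step: float,  # µm
    pixel_size: float,
) -> LineProfile:
    """Sample multi-channel intensities along edge-to-lamellum lines.

    Each line is resampled at ``sample_step`` µm with bilinear
    interpolation, each channel normalized to its own per-line maximum, and
    the per-position median taken across lines (truncated to the shortest
    line so every position has a value from every cell).
    """
    if not lines:
        raise ValueError("need at least one profile line")
    step_px = sample_step / pixel_size
    sampled: dict[str, list[np.ndarray]] = {ch: [] for ch in images}
    for line in lines:
        line = np.asarray(line, dtype=float)
        if line.ndim != 2 or len(line) < 2:
            raise ValueError("each line needs >= 2 (x, y) points")
        for ch, img in images.items():
            prof = _sample_polyline(img, line, step_px)
            peak = prof.max()
            sampled[ch].append(prof / peak if peak > 0 else prof)
    n_min = min(len(p) for profs in sampled.values() for p in profs)
    per_line = {ch: np.vstack([p[:n_min] for p in profs]) for ch, profs in sampled.items()}
    return LineProfile(
        positions=np.arange(n_min) * sample_step,
        median={ch: np.median(m, axis=0) for ch, m in per_line.items()},
        per_line=per_line,
    )


def fit_lowess(
    values: np.ndarray, positions: np.ndarray, frac: float = 0.3
) -> np.ndarray:
    """Locally weighted regression smoother on a fixed position grid."""
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    if values.size < 10:
        raise ValueError("need >= 10 positions for a stable fit")
    out = sm_lowess(values, positions, frac=frac, return_sorted=False)
    return np.asarray(out, dtype=float)


def find_landmarks(
    factin: np.ndarray,
    myl9: np.ndarray,
    positions: np.ndarray,
    slope_frac: float = 0.2,
) -> ProfileLandmarks:
    """Edge and myosin-onset positions from fitted profile curves.

    Edge = first local maximum of the F-actin curve walking inward from
    position 0.  Myosin onset = first position at or behind the edge where
    the MYL9 slope exceeds ``slope_frac`` of its maximum positive slope
    (a noise-robust stand-in for the beginning inflection of the rise).
    """
    factin = np.asarray(factin, dtype=float)
    myl9 = np.asarray(myl9, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if not (factin.shape == myl9.shape == positions.shape):
        raise ValueError("curves and positions must share one grid")

    edge_idx = None
    for i in range(1, len(factin) - 1):
        if factin[i] > factin[i - 1] and factin[i] >= factin[i + 1]:
            edge_idx = i
            break
    if edge_idx is None:
        return ProfileLandmarks(None, None, reason="no F-actin local maximum")

    slope = np.gradient(myl9, positions)
    tail = slope[edge_idx:]
    max_slope = tail.max()
    span = float(positions[-1] - positions[0])
    flat_tol = 1e-12 + 1e-9 * float(np.abs(myl9).max()) / span if span > 0 else 0.0
    if max_slope <= flat_tol:
        return ProfileLandmarks(
            float(positions[edge_idx]), None, reason="no positive MYL9 slope"
        )
    rel = np.nonzero(tail >= slope_frac * max_slope)[0]
    onset_idx = edge_idx + int(rel[0])
    return ProfileLandmarks(
        edge_um=float(positions[edge_idx]), onset_um=float(positions[onset_idx])
    )


def decay_halftime(
    intensities: np.ndarray,
    frame_interval: float = 1.0,
    times: Optional[np.ndarray] = None,
) -> DecayTrace:
    """Normalized photoactivation decay and its 50% crossing time.

    The first sample is the activation frame; intensities are divided by
    it, and the half-time is the first crossing of 0.5 found by linear
    interpolation between samples.  Traces that never cross (frozen actin)
    report ``half_time_s = None``.
    """
    y = np.asarray(intensities, dtype=float)
    if y.size < 5:
        raise ValueError("need >= 5 samples")
    if y[0] <= 0:
        raise ValueError("zero or negative initial intensity; cannot normalize")
    t = np.asarray(times, dtype=float) if times is not None else np.arange(y.size) * frame_interval
    norm = y / y[0]
    half = None
    below = np.nonzero(norm < 0.5)[0]
    if below.size:
        k = int(below[0])
        if k == 0:
            half = float(t[0])
        else:
            y0, y1 = norm[k - 1], norm[k]
            half = float(t[k - 1] + (0.5 - y0) / (y1 - y0) * (t[k] - t[k - 1]))
    return DecayTrace(times_s=t, normalized=norm, half_time_s=half)


def measure_roi_lengths(
    polylines: Sequence[np.ndarray], pixel_size: float
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Arc lengths (µm) of drawn ROI polylines with mean and 95% CI.

    Used for protrusion widths (lines across Arp3-positive zones) and
    branched-network depths (leading edge to the back of the network).
    """
    lengths = []
    for pl in polylines:
        pts = np.asarray(pl, dtype=float)
        if pts.ndim != 2 or len(pts) < 2:
            raise ValueError("each polyline needs >= 2 points")
        lengths.append(float(np.hypot(*np.diff(pts, axis=0).T).sum() * pixel_size))
    arr = np.asarray(lengths)
    mean = float(arr.mean())
    if arr.size > 1 and arr.std(ddof=1) > 0:
        half = stats.sem(arr) * stats.t.ppf(0.975, arr.size - 1)
    else:
        half = 0.0
    return arr, mean, (mean - half, mean + half)
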