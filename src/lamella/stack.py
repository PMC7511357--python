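"""Calibrated time-lapse image stacks.

A :class:`TimeLapseStack` holds a ``T x C x Y x X`` intensity array together
with the physical calibration needed to convert pixel displacements into
micrometres and frame indices into seconds.  Stacks are written as plain
multi-page TIFF files (axis order T, C, Y, X) with a JSON sidecar carrying
the calibration, so they stay readable by any standard viewer without
depending on a particular OME metadata dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["TimeLapseStack"]


@dataclass
class TimeLapseStack:
    """Multi-channel time-lapse with physical calibration.

    Parameters
    ----------
    pixels
        Intensity array of shape ``(T, C, Y, X)``.
    pixel_size
        Lateral calibration in µm per pixel (strictly positive).
    frame_interval
        Time between consecutive frames in seconds (strictly positive).
    channel_names
        One name per channel; defaults to ``ch0, ch1, ...``.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be a (T, C, Y, X) array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("stack needs at least one frame and one channel")
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise ValueError("pixel_size and frame_interval must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.pixels.shape[1]))
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return the ``(T, Y, X)`` series for one channel."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"unknown channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.pixels[:, idx]

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        """Write the stack as TIFF plus a ``<stem>.json`` calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.pixels), metadata={"axes": "TCYX"})
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "pixel_size_um": self.pixel_size,
                    "frame_interval_s": self.frame_interval,
                    "channels": list(self.channel_names),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "TimeLapseStack":
        """Read a TIFF written by :meth:`save` (sidecar JSON required)."""
        path = Path(path)
        pixels = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if pixels.ndim == 3:  # single-channel stacks round-trip as T,Y,X
            pixels = pixels[:, None]
        return cls(
            pixels=pixels,
            pixel_size=float(meta["pixel_size_um"]),
            frame_interval=float(meta["frame_interval_s"]),
            channel_names=tuple(meta.get("channels", ())),
        )
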