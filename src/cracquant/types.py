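"""Core in-memory containers shared across the pipeline.

Conventions: pixel coordinates are (row, col), 0-based, origin top-left;
areas are in px^2 unless ``pixel_size_um`` is supplied; intensities are in
arbitrary camera units and are never rescaled on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ChannelAlignmentError

#: Channel labels used throughout the package.
CFP = "CFP"
YFP = "YFP"
A555 = "A555"
F340 = "F340"
F380 = "F380"
OTHER = "OTHER"

KNOWN_CHANNELS = (CFP, YFP, A555, F340, F380, OTHER)


@dataclass
class Image2D:
    """A single-plane grayscale image with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities (a.u.).
    bit_depth : int
        Bit depth of the source data (8 or 16).
    channel : str
        One of :data:`KNOWN_CHANNELS`.
    pixel_size_um : float, optional
        Physical pixel size in micrometres per pixel, if known.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    channel: str = OTHER
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"Image2D requires a 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D pixels must all be finite")
        if np.any(px < 0):
            raise ValueError("Image2D pixels must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.channel not in KNOWN_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FieldOfView:
    """Pixel-registered channel images for one cell in one condition."""

    cell_id: str
    condition: str
    images: dict[str, Image2D] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: im.shape for ch, im in self.images.items()}
        if len(set(shapes.values())) > 1:
            raise ChannelAlignmentError(
                f"channel images of cell {self.cell_id!r} disagree in shape: {shapes}"
            )

    def __getitem__(self, channel: str) -> Image2D:
        return self.images[channel]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape


@dataclass
class FuraTrace:
    """Ratiometric Fura-2 time series for one cell with protocol event times.

    ``ratio`` is F340/F380 after background subtraction; ``valid`` flags
    timepoints with a positive background-subtracted F380 denominator.
    ``t_tg`` is the store-depletion (thapsigargin) addition time and ``t_ca``
    the extracellular Ca2+ re-addition time, both in seconds.
    """

    cell_id: str
    time_s: np.ndarray
    f340: Optional[np.ndarray] = None
    f380: Optional[np.ndarray] = None
    ratio: Optional[np.ndarray] = None
    t_tg: float = 0.0
    t_ca: float = 0.0
    bg340: float = 0.0
    bg380: float = 0.0
    condition: str = ""
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("time_s must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"time must be strictly increasing for cell {self.cell_id!r}")
        self.time_s = t
        for name in ("f340", "f380", "ratio"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != t.shape:
                    raise ValueError(f"{name} length differs from time for cell {self.cell_id!r}")
                setattr(self, name, arr)
        if self.valid is None and self.ratio is not None:
            self.valid = np.ones_like(t, dtype=bool)

    @property
    def n(self) -> int:
        return int(self.time_s.size)
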