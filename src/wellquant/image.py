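"""Multi-channel fluorescence raster container and TIFF I/O.

All geometry in this package is expressed in micrometres; rasters carry a
``pixel_size`` (µm/px) so conversion happens only at the render/measure
boundary.  The coordinate convention is fixed: origin at the *centre* of the
top-left pixel, x rightward (columns), y downward (rows), 0-based indices.
Centroids and positions are reported at sub-pixel precision in µm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: canonical channel order for rendered / written stacks
DEFAULT_CHANNELS = ("dapi", "actin", "tf1", "tf2")


@dataclass
class MultiChannelImage:
    """A 2D multi-channel fluorescence image.

    Parameters
    ----------
    data : ndarray, shape (C, H, W)
        One 2D raster per channel, intensity in arbitrary units.
    channels : tuple of str
        Role name per channel (e.g. ``("dapi", "actin", "tf1", "tf2")``).
    pixel_size : float
        Lateral sampling in µm per pixel.
    meta : dict
        Free-form acquisition metadata (echoed to disk on save).
    """

    data: np.ndarray
    channels: tuple = DEFAULT_CHANNELS
    pixel_size: float = 0.65
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (channels, height, width)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} planes"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.channels = tuple(self.channels)

    @property
    def shape(self):
        """(H, W) of each channel plane."""
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the 2D raster for a channel role."""
        try:
            return self.data[self.channels.index(role)]
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.channels}")

    def with_channel(self, role: str, raster: np.ndarray) -> "MultiChannelImage":
        """Return a copy with one channel plane replaced."""
        data = self.data.copy()
        data[self.channels.index(role)] = raster
        return MultiChannelImage(data, self.channels, self.pixel_size, dict(self.meta))

    # ------------------------------------------------------------------ I/O

    def save_tiff(self, path) -> None:
        """Write a multi-page TIFF, one page per channel, metadata in the
        ImageJ-compatible description tag (JSON)."""
        desc = json.dumps(
            {"channels": list(self.channels), "pixel_size_um": self.pixel_size,
             "meta": self.meta}
        )
        tifffile.imwrite(path, self.data.astype(np.float32), description=desc)

    @classmethod
    def read_tiff(cls, path, channels=None, pixel_size=None) -> "MultiChannelImage":
        """Read a multi-page TIFF.  Channel roles and pixel size are taken
        from the JSON description tag when present, else must be supplied."""
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
        if data.ndim == 2:
            data = data[None]
        meta = {}
        try:
            info = json.loads(desc)
            channels = channels or tuple(info["channels"])
            pixel_size = pixel_size or float(info["pixel_size_um"])
            meta = info.get("meta", {})
        except (json.JSONDecodeError, KeyError, TypeError):
            pass
        if channels is None or pixel_size is None:
            raise ValueError(
                f"{path}: no embedded metadata; pass channels= and pixel_size="
            )
        return cls(np.asarray(data, float), tuple(channels), float(pixel_size), meta)


def pixel_grid(shape, pixel_size):
    """Return (x, y) coordinate arrays in µm for pixel centres of ``shape``."""
    h, w = shape
    x = np.arange(w) * pixel_size
    y = np.arange(h) * pixel_size
    return np.meshgrid(x, y)
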