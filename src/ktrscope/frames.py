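"""Calibrated image containers and OME-TIFF round-trip.

Conventions: images are ``(rows, cols)`` float arrays, 0-based, row-major,
origin at the top-left pixel; physical coordinates are ``x = col *
pixel_size_um``, ``y = row * pixel_size_um``. Time-lapse channels are stacked
``(n_frames, rows, cols)``.
"""

from __future__ import annotations

import xml.etree.ElementTree as _ET
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class FrameStack:
    """Multi-channel, calibrated image time series.

    Parameters
    ----------
    channels
        Mapping of channel name to a ``(n_frames, rows, cols)`` array. All
        channels must share a shape.
    pixel_size_um
        Lateral pixel size in micrometres (> 0).
    frame_interval_h
        Time between consecutive frames in hours (> 0). The default imaging
        cadence downstream is 0.2 h (one frame every 12 minutes).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    frame_interval_h: float = 0.2

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FrameStack needs at least one channel")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError("channel arrays must be (n_frames, rows, cols)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    # -- geometry -----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def frame(self, name: str, index: int) -> np.ndarray:
        return self.channels[name][index]

    # -- IO -----------------------------------------------------------------
    def to_ome_tiff(self, path) -> None:
        """Write as an OME-TIFF with axes TCYX and channel names in metadata."""
        data = np.stack([self.channels[c] for c in self.channel_names], axis=1)
        tifffile.imwrite(
            path,
            data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "TCYX",
                "Channel": {"Name": self.channel_names},
                "PhysicalSizeX": self.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "TimeIncrement": self.frame_interval_h,
                "TimeIncrementUnit": "h",
            },
        )

    @classmethod
    def from_ome_tiff(cls, path) -> "FrameStack":
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            names, px, dt = _parse_ome(tif.ome_metadata)
        # normalise to TCYX
        if axes == "CYX":
            data = data[np.newaxis]
            axes = "TCYX"
        if axes == "TYX":
            data = data[:, np.newaxis]
            axes = "TCYX"
        if axes != "TCYX":
            raise ValueError(f"unsupported OME axes order {axes!r}")
        if not names or len(names) != data.shape[1]:
            names = [f"ch{i}" for i in range(data.shape[1])]
        channels = {n: data[:, i] for i, n in enumerate(names)}
        return cls(channels, pixel_size_um=px, frame_interval_h=dt)


@dataclass
class SectionImage:
    """Single-frame multi-channel section image (e.g. tumor + CD8 stain)."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_ome_tiff(self, path) -> None:
        stack = FrameStack(
            {k: v[np.newaxis] for k, v in self.channels.items()},
            pixel_size_um=self.pixel_size_um,
            frame_interval_h=1.0,
        )
        stack.to_ome_tiff(path)

    @classmethod
    def from_ome_tiff(cls, path) -> "SectionImage":
        stack = FrameStack.from_ome_tiff(path)
        return cls(
            {k: v[0] for k, v in stack.channels.items()},
            pixel_size_um=stack.pixel_size_um,
        )


def _parse_ome(ome_xml: str | None) -> tuple[list[str], float, float]:
    names: list[str] = []
    px = 1.0
    dt = 0.2
    if not ome_xml:
        return names, px, dt
    root = _ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is not None:
        if pixels.get("PhysicalSizeX"):
            px = float(pixels.get("PhysicalSizeX"))
        if pixels.get("TimeIncrement"):
            dt = float(pixels.get("TimeIncrement"))
        for ch in pixels.findall("ome:Channel", ns):
            names.append(ch.get("Name") or f"ch{len(names)}")
    return names, px, dt
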