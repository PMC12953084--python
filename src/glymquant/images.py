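"""Multi-channel fluorescence image container and TIFF I/O.

Images are 2-D float grids, one per named channel (e.g. GFAP, AQP4, DAPI or
p65, MMP-9, DAPI), with a physical pixel size in micrometres.  Coordinates
are (row, col), origin top-left, 0-based; physical distances are obtained by
multiplying pixel distances by ``pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["MultiChannelImage"]


@dataclass
class MultiChannelImage:
    """Named-channel intensity image with physical pixel size.

    Parameters
    ----------
    channels : dict[str, ndarray]
        2-D arrays of non-negative intensities (arbitrary units), all of
        identical shape.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    section_id : str, optional
        Identifier of the tissue section the image came from.
    region_label : str, optional
        Anatomical region ("anterior horn", "posterior horn",
        "central canal").
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    section_id: str | None = None
    region_label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        ref = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError("channels must be 2-D arrays")
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"missing channels {missing}; available: {self.channel_names}")

    # -- I/O ---------------------------------------------------------------

    def to_tiff(self, path) -> None:
        """Write channels as a C×H×W TIFF; names and pixel size go into
        the ImageDescription JSON."""
        stack = np.stack([self.channels[n] for n in self.channel_names]).astype(
            np.float32
        )
        desc = json.dumps(
            {
                "channel_names": self.channel_names,
                "pixel_size_um": self.pixel_size_um,
                "section_id": self.section_id,
                "region_label": self.region_label,
            }
        )
        tifffile.imwrite(path, stack, description=desc)

    @classmethod
    def from_tiff(cls, path, channel_names: list[str] | None = None,
                  pixel_size_um: float | None = None) -> "MultiChannelImage":
        """Read a C×H×W TIFF.  Channel names and pixel size are taken from
        the ImageDescription JSON when present, else must be supplied."""
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
        meta: dict = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if stack.ndim == 2:
            stack = stack[None]
        names = channel_names or meta.get("channel_names")
        if names is None or len(names) != stack.shape[0]:
            raise ValueError(
                "channel names absent from TIFF metadata; pass channel_names "
                f"matching {stack.shape[0]} planes"
            )
        px = pixel_size_um or meta.get("pixel_size_um")
        if px is None:
            raise ValueError("pixel_size_um absent from TIFF metadata; pass it")
        return cls(
            channels={n: np.clip(stack[i].astype(float), 0, None) for i, n in enumerate(names)},
            pixel_size_um=float(px),
            section_id=meta.get("section_id"),
            region_label=meta.get("region_label"),
        )
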