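"""Multichannel raster container and TIFF round-trip helpers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MultiChannelImage:
    """A 2-D multichannel fluorescence image with physical pixel size.

    ``data`` has shape (C, H, W); channels are addressed by index or by
    name through :meth:`channel`. Intensities are stored as non-negative
    floats in memory; :func:`write_tiff` quantizes to 16-bit on export.
    """

    data: np.ndarray
    pixel_size_um: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim == 2:
            d = d[None]
        if d.ndim != 3:
            raise ValueError("data must be (C, H, W) or (H, W)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(d.shape[0])]
        if len(self.channel_names) != d.shape[0]:
            raise ValueError("one name per channel required")
        self.data = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, key: int | str) -> np.ndarray:
        """Return one channel as an (H, W) float array."""
        if isinstance(key, str):
            try:
                key = self.channel_names.index(key)
            except ValueError:
                raise KeyError(
                    f"unknown channel {key!r}; have {self.channel_names}"
                ) from None
        return self.data[key]


def write_tiff(image: MultiChannelImage, path: str | Path) -> None:
    """Write channels as 16-bit planes with pixel size and names in metadata."""
    path = Path(path)
    data = np.clip(np.round(image.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "pixel_size_um": image.pixel_size_um,
            "channel_names": image.channel_names,
        },
    )


def read_tiff(path: str | Path, pixel_size_um: float | None = None) -> MultiChannelImage:
    """Read a (C, H, W) or (H, W) TIFF written by :func:`write_tiff`.

    ``pixel_size_um`` overrides (or supplies, for foreign files) the
    metadata value; 1.0 is assumed when neither is available.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata or tf.imagej_metadata or {}
        if isinstance(meta, (list, tuple)):
            meta = meta[0] if meta else {}
    names = list(meta.get("channel_names", []))
    px = pixel_size_um or float(meta.get("pixel_size_um", 1.0))
    return MultiChannelImage(
        data=np.asarray(data, dtype=float),
        pixel_size_um=px,
        channel_names=names,
    )


def write_json(obj: dict, path: str | Path) -> None:
    """Write a ground-truth / annotation dict as JSON (numpy-aware)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
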