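"""Grayscale and merged RGB rendering of band-RMS maps.

All channels of a composite share one display range (default 0-60
normalised-RMS units) so channel brightness is directly comparable: the
transfer is linear, v -> round(255 * clip((v - lo)/(hi - lo), 0, 1)),
with half-up rounding.  Missing pixels render as 0 and are recorded in a
separate alpha mask rather than interpolated.

Channel semantics default to the standard pairing DNA -> red,
RNA -> green, mitochondrial hemes -> blue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import tifffile

from .bandstats import BandStatMap
from .spectral import SpectralError

__all__ = [
    "DisplayRange",
    "RGBComposite",
    "to_gray",
    "merge_rgb",
    "write_gray_png",
    "write_map_tiff",
    "write_map_csv",
    "write_rgb_png",
]

DEFAULT_CHANNEL_SEMANTICS = {"red": "DNA", "green": "RNA", "blue": "heme"}


@dataclass(frozen=True)
class DisplayRange:
    lo: float = 0.0
    hi: float = 60.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SpectralError("display range needs lo < hi")


@dataclass(frozen=True)
class RGBComposite:
    red: BandStatMap
    green: BandStatMap
    blue: BandStatMap
    range: DisplayRange = DisplayRange()
    channel_semantics: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_SEMANTICS)
    )

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1:
            raise SpectralError(f"channel maps differ in shape: {shapes}")


def to_gray(m: BandStatMap, r: DisplayRange = DisplayRange()) -> tuple[np.ndarray, np.ndarray]:
    """Render a map to 8-bit grayscale plus an alpha (validity) mask.

    Returns ``(gray, alpha)``: gray is uint8, alpha is uint8 (255 where
    the map has a value, 0 where missing).
    """
    v = m.values
    missing = np.isnan(v)
    scaled = np.clip((np.where(missing, r.lo, v) - r.lo) / (r.hi - r.lo), 0.0, 1.0)
    gray = np.floor(scaled * 255.0 + 0.5).astype(np.uint8)  # half-up
    gray[missing] = 0
    alpha = np.where(missing, 0, 255).astype(np.uint8)
    return gray, alpha


def merge_rgb(c: RGBComposite) -> np.ndarray:
    """Overlay the three channel maps into one H x W x 3 uint8 image.

    Each channel is rendered independently through :func:`to_gray` with
    the single shared display range.
    """
    out = np.zeros((*c.red.shape, 3), dtype=np.uint8)
    for i, m in enumerate((c.red, c.green, c.blue)):
        out[:, :, i] = to_gray(m, c.range)[0]
    return out


def write_gray_png(m: BandStatMap, r: DisplayRange, path: str | Path) -> None:
    gray, alpha = to_gray(m, r)
    iio.imwrite(Path(path), np.dstack([gray, alpha]))


def write_rgb_png(c: RGBComposite, path: str | Path) -> None:
    iio.imwrite(Path(path), merge_rgb(c))


def write_map_tiff(m: BandStatMap, path: str | Path) -> None:
    """Float32 TIFF of the raw map values (NaN kept for missing pixels)."""
    tifffile.imwrite(Path(path), m.values.astype(np.float32))


def write_map_csv(m: BandStatMap, path: str | Path) -> None:
    np.savetxt(Path(path), m.values, delimiter=",")
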