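"""Rasterize barcodes into fixed-size RGB images for the classifier.

The image is split into two horizontal bands: connected-component bars
(dim 0, red by default) on top, loop bars (dim 1, blue) below, on a white
background.  Within a band, bars are sorted by (birth, death) and spread
evenly over the band's rows; the x axis maps ``[0, x_range]`` linearly onto
the image width, with infinite bars running to the right edge.  Rendering
is pure numpy and therefore byte-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
from PIL import Image

from .persistence import Barcode

__all__ = ["RenderConfig", "BarcodeImage", "render", "save_png", "image_path"]


@dataclass
class RenderConfig:
    """Barcode rasterization settings.

    ``x_range_rule="per_barcode"`` maps each barcode's own ``eps_max`` to
    the right edge (self-normalized images); a fixed numeric range keeps
    bar lengths comparable across segments, which preserves amplitude
    information in the image.
    """

    size: int = 224
    x_range_rule: Union[Literal["per_barcode"], float] = "per_barcode"
    dim0_color: tuple[int, int, int] = (220, 30, 30)
    dim1_color: tuple[int, int, int] = (30, 30, 220)
    bar_thickness: int = 2
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if isinstance(self.x_range_rule, (int, float)) and self.x_range_rule <= 0:
            raise ValueError("fixed x_range must be positive")
        if self.bar_thickness < 1:
            raise ValueError("bar_thickness must be >= 1")


@dataclass
class BarcodeImage:
    """``H x W x 3`` uint8 raster plus provenance metadata."""

    pixels: np.ndarray
    scale: float  # eps units per pixel along x
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def _draw_band(
    pixels: np.ndarray,
    intervals,
    band: tuple[int, int],
    x_range: float,
    color: tuple[int, int, int],
    thickness: int,
) -> None:
    y0, y1 = band
    height = y1 - y0
    n = len(intervals)
    if n == 0:
        return
    width = pixels.shape[1]
    ordered = sorted(intervals, key=lambda iv: (iv.birth, iv.death))
    thick = min(thickness, max(1, height // n))
    for row, iv in enumerate(ordered):
        yc = y0 + int((row + 0.5) * height / n)
        ya = max(y0, yc - thick // 2)
        yb = min(y1, ya + thick)
        xa = int(round(iv.birth / x_range * (width - 1)))
        if math.isinf(iv.death):
            xb = width - 1
        else:
            xb = int(round(min(iv.death, x_range) / x_range * (width - 1)))
        xb = max(xb, xa + 1)  # every bar at least one pixel long
        pixels[ya:yb, xa : xb + 1] = color


def render(barcode: Barcode, config: RenderConfig | None = None) -> BarcodeImage:
    """Draw a barcode: dim-0 band in the top half, dim-1 band below."""
    if config is None:
        config = RenderConfig()
    size = config.size
    if isinstance(config.x_range_rule, (int, float)):
        x_range = float(config.x_range_rule)
    else:
        x_range = float(barcode.eps_max)
    if x_range <= 0:
        x_range = 1.0

    pixels = np.empty((size, size, 3), dtype=np.uint8)
    pixels[:] = config.background
    half = size // 2
    _draw_band(
        pixels, barcode.by_dim(0), (0, half), x_range, config.dim0_color,
        config.bar_thickness,
    )
    _draw_band(
        pixels, barcode.by_dim(1), (half, size), x_range, config.dim1_color,
        config.bar_thickness,
    )
    return BarcodeImage(
        pixels=pixels,
        scale=x_range / (size - 1),
        meta={
            "n_points": barcode.n_points,
            "eps_max": barcode.eps_max,
            "x_range": x_range,
        },
    )


def image_path(root, subject: str, label: str, start_time: float) -> Path:
    """Directory layout consumed by the classifier stage."""
    return Path(root) / subject / label / f"{start_time:09.2f}.png"


def save_png(image: BarcodeImage, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels).save(path)
    return path
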