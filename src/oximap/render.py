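"""Display rendering: StO2 percent -> monitor RGB, plus WLI|OSI composites.

The display convention assigns StO2 to color in 1 % increments: 100 % is
red, 50 % yellowish green, 0 % dark blue.  Intermediate levels follow a hue
path blue -> cyan -> green -> yellow -> red (cosmetic choice; the exact
anchor RGB triples are configurable).  Invalid pixels render as a neutral
sentinel color.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .errors import ConstructionError, ValidationError
from .estimator import StO2Map

#: Default anchor colors (RGB, 0-255).
ANCHOR_DARK_BLUE = (25, 35, 110)
ANCHOR_YELLOW_GREEN = (170, 210, 40)
ANCHOR_RED = (220, 30, 30)

#: Display color for pixels outside the validity mask.
SENTINEL_GRAY = (128, 128, 128)


@dataclass(frozen=True)
class ColorLUT:
    """101-entry map from integer StO2 % to an RGB triple (uint8).

    All entries are distinct, so every 1 % step is visually coded.
    """

    rgb: np.ndarray
    sentinel: tuple[int, int, int] = SENTINEL_GRAY

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb, dtype=np.uint8)
        if rgb.shape != (101, 3):
            raise ConstructionError("render: color LUT must have 101 RGB entries")
        if len({tuple(row) for row in rgb.tolist()}) != 101:
            raise ConstructionError("render: color LUT entries must be pairwise distinct")
        object.__setattr__(self, "rgb", rgb)

    def __getitem__(self, level: int) -> tuple[int, int, int]:
        return tuple(int(v) for v in self.rgb[level])


def _hsv(rgb: tuple[int, int, int]) -> tuple[float, float, float]:
    return colorsys.rgb_to_hsv(*(v / 255.0 for v in rgb))


def build_color_lut(
    dark_blue: tuple[int, int, int] = ANCHOR_DARK_BLUE,
    yellow_green: tuple[int, int, int] = ANCHOR_YELLOW_GREEN,
    red: tuple[int, int, int] = ANCHOR_RED,
    sentinel: tuple[int, int, int] = SENTINEL_GRAY,
) -> ColorLUT:
    """Piecewise-linear HSV interpolation through the three anchor colors.

    Hue descends monotonically from the blue anchor through cyan, green and
    yellow to red, so adjacent 1 % levels get strictly different colors.
    """
    anchors_pct = np.array([0.0, 50.0, 100.0])
    h, s, v = zip(*(_hsv(c) for c in (dark_blue, yellow_green, red)))
    levels = np.arange(101, dtype=float)
    hh = np.interp(levels, anchors_pct, h)
    ss = np.interp(levels, anchors_pct, s)
    vv = np.interp(levels, anchors_pct, v)
    rgb = np.array(
        [[round(255 * c) for c in colorsys.hsv_to_rgb(a, b, c)] for a, b, c in zip(hh, ss, vv)],
        dtype=np.uint8,
    )
    # exact anchors at the three defining levels
    rgb[0], rgb[50], rgb[100] = dark_blue, yellow_green, red
    return ColorLUT(rgb, sentinel=sentinel)


def render_sto2(sto2_map: StO2Map, lut: ColorLUT | None = None) -> np.ndarray:
    """RGB image of an StO2 map: nearest 1 % bin color, sentinel where invalid."""
    clut = lut or build_color_lut()
    sto2 = sto2_map.sto2_pct
    valid = sto2_map.valid_mask
    out = np.empty(sto2.shape + (3,), dtype=np.uint8)
    out[...] = np.asarray(clut.sentinel, dtype=np.uint8)
    levels = np.rint(np.clip(sto2[valid], 0.0, 100.0)).astype(int)
    out[valid] = clut.rgb[levels]
    return out


def render_wli(frame_pixels: np.ndarray, full_scale: float) -> np.ndarray:
    """Grayscale-to-RGB rendering of a white-light (445 nm) frame."""
    g = np.clip(frame_pixels / full_scale, 0.0, 1.0)
    g8 = np.rint(255 * g).astype(np.uint8)
    return np.stack([g8, g8, g8], axis=-1)


def color_bar(lut: ColorLUT, height: int, width: int = 24) -> np.ndarray:
    """Vertical color bar, 100 % at the top, 0 % at the bottom."""
    levels = np.rint(np.linspace(100, 0, height)).astype(int)
    return np.repeat(lut.rgb[levels][:, None, :], width, axis=1)


def compose_side_by_side(
    wli_rgb: np.ndarray, osi_rgb: np.ndarray, lut: ColorLUT | None = None, gap: int = 8
) -> np.ndarray:
    """WLI | OSI panel with a color bar, mirroring the dual-monitor display."""
    if wli_rgb.shape != osi_rgb.shape:
        raise ValidationError("render: WLI and OSI panels must share a shape")
    clut = lut or build_color_lut()
    h = wli_rgb.shape[0]
    spacer = np.full((h, gap, 3), 255, dtype=np.uint8)
    return np.concatenate(
        [wli_rgb, spacer, osi_rgb, spacer, color_bar(clut, h)], axis=1
    )


def save_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(path, rgb)
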