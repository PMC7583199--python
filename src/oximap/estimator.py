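"""Per-pixel StO2 estimation from a 445/473 nm frame pair.

The estimate is the lookup-table inversion of the inter-frame log-ratio
``ln(I473 / I445)``.  Because the ratio cancels any gain common to both
frames, the estimate is exactly invariant under global illumination-scale
changes.  Dark and saturated pixels (specular highlights) are excluded by an
intensity validity mask; pixels whose ratio falls outside the calibrated
range are clipped to 0 or 100 % but kept valid, with a separate clip flag,
so region statistics are not biased by dropping extremes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import median_filter

from .errors import ConfigurationError, ValidationError
from .ioutils import config_hash, read_json, write_json
from .spectra import InversionLUT
from .stream import Frame

logger = logging.getLogger("oximap.estimator")

#: Invalid pixels carry NaN, never 0, so true anoxia is not aliased.
INVALID_SENTINEL = np.nan

DEFAULT_FLOOR_FRAC = 0.01
DEFAULT_CEIL_FRAC = 0.98


@dataclass(frozen=True)
class EstimatorConfig:
    """Validity thresholds and optional pre-filtering.

    ``floor_frac``/``ceil_frac`` bound the usable intensity range as
    fractions of sensor full scale; ``median_prefilter`` applies a 3x3
    median to both frames before the ratio (off by default: the device
    displays pixel-level maps).
    """

    floor_frac: float = DEFAULT_FLOOR_FRAC
    ceil_frac: float = DEFAULT_CEIL_FRAC
    median_prefilter: bool = False


@dataclass(frozen=True)
class StO2Map:
    """Per-pixel StO2 in percent with validity and clip masks.

    ``sto2_pct`` is in [0, 100] wherever ``valid_mask`` is set and NaN
    elsewhere; ``clipped_mask`` flags valid pixels whose log-ratio fell
    outside the lookup table's span.  ``provenance`` records the indices of
    the source frame pair.
    """

    sto2_pct: np.ndarray
    valid_mask: np.ndarray
    clipped_mask: np.ndarray
    provenance: tuple[int, int]

    def __post_init__(self) -> None:
        s = np.asarray(self.sto2_pct, dtype=float)
        v = np.asarray(self.valid_mask, dtype=bool)
        c = np.asarray(self.clipped_mask, dtype=bool)
        if s.shape != v.shape or s.shape != c.shape:
            raise ValidationError("estimator: map and masks must share one shape")
        vals = s[v]
        if vals.size and (np.any(vals < 0) or np.any(vals > 100) or np.any(np.isnan(vals))):
            raise ValidationError("estimator: valid StO2 values must lie in [0, 100]")
        object.__setattr__(self, "sto2_pct", s)
        object.__setattr__(self, "valid_mask", v)
        object.__setattr__(self, "clipped_mask", c)


def _check_pair(frame_445: Frame, frame_473: Frame) -> None:
    if frame_445.pixels.shape != frame_473.pixels.shape:
        raise ValidationError("estimator: frame pair shapes differ")
    if (frame_445.illumination_nm, frame_473.illumination_nm) != (445.0, 473.0):
        raise ConfigurationError("estimator: frame pair must be tagged (445, 473) nm")


def validity_mask(
    frame_445: Frame,
    frame_473: Frame,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
    ceil_frac: float = DEFAULT_CEIL_FRAC,
) -> np.ndarray:
    """Pixels whose intensity is usable in *both* frames.

    Valid iff both intensities lie strictly inside
    ``(floor_frac, ceil_frac) * full_scale`` — rejects dark pixels (no
    signal) and saturated/specular pixels.
    """
    _check_pair(frame_445, frame_473)
    mask = np.ones(frame_445.pixels.shape, dtype=bool)
    for f in (frame_445, frame_473):
        lo = floor_frac * f.saturated_value
        hi = ceil_frac * f.saturated_value
        mask &= (f.pixels > lo) & (f.pixels < hi)
    return mask


def ratio_image(frame_445: Frame, frame_473: Frame, mask: np.ndarray) -> np.ndarray:
    """Log-ratio ``ln(I473 / I445)`` on valid pixels, NaN elsewhere.

    Invariant under multiplying both frames by any common positive gain.
    """
    _check_pair(frame_445, frame_473)
    if mask.shape != frame_445.pixels.shape:
        raise ValidationError("estimator: mask shape differs from frames")
    r = np.full(frame_445.pixels.shape, INVALID_SENTINEL, dtype=float)
    np.divide(frame_473.pixels, frame_445.pixels, out=r, where=mask)
    np.log(r, out=r, where=mask)
    return r


def estimate_sto2(
    frame_445: Frame,
    frame_473: Frame,
    lut: InversionLUT,
    config: EstimatorConfig | None = None,
) -> StO2Map:
    """Per-pixel StO2 map from one frame pair via log-ratio LUT inversion."""
    cfg = config or EstimatorConfig()
    if tuple(lut.config.wavelength_pair_nm) != (
        frame_445.illumination_nm,
        frame_473.illumination_nm,
    ):
        raise ConfigurationError(
            f"estimator: LUT built for {lut.config.wavelength_pair_nm} nm does not "
            f"match frame tags ({frame_445.illumination_nm:g}, {frame_473.illumination_nm:g})"
        )
    f445, f473 = frame_445, frame_473
    if cfg.median_prefilter:
        f445 = Frame(
            median_filter(f445.pixels, size=3), 445.0, f445.index, f445.saturated_value
        )
        f473 = Frame(
            median_filter(f473.pixels, size=3), 473.0, f473.index, f473.saturated_value
        )
    mask = validity_mask(f445, f473, cfg.floor_frac, cfg.ceil_frac)
    r = ratio_image(f445, f473, mask)
    sto2 = np.full(r.shape, INVALID_SENTINEL, dtype=float)
    sto2[mask] = lut.invert(r[mask])
    clipped = np.zeros(r.shape, dtype=bool)
    clipped[mask] = lut.out_of_range(r[mask])
    n_valid = int(mask.sum())
    logger.info(
        "estimated StO2 for pair (%d, %d): %d/%d valid, %d clipped",
        frame_445.index, frame_473.index, n_valid, mask.size, int(clipped.sum()),
    )
    return StO2Map(sto2, mask, clipped, provenance=(frame_445.index, frame_473.index))


# -- serialization ---------------------------------------------------------


def save_sto2_map(sto2_map: StO2Map, basepath, config: EstimatorConfig | None = None) -> None:
    """Write ``<base>_sto2.tif`` (float32), ``<base>_mask.tif`` (uint8) and a
    JSON sidecar carrying provenance and the producing config hash."""
    base = str(basepath)
    tifffile.imwrite(base + "_sto2.tif", sto2_map.sto2_pct.astype(np.float32))
    mask8 = sto2_map.valid_mask.astype(np.uint8) + 2 * sto2_map.clipped_mask.astype(np.uint8)
    tifffile.imwrite(base + "_mask.tif", mask8)
    cfg = config or EstimatorConfig()
    write_json(
        base + "_sto2.json",
        {
            "provenance_frames": list(sto2_map.provenance),
            "config": cfg,
            "config_hash": config_hash(cfg),
        },
    )


def load_sto2_map(basepath) -> StO2Map:
    base = str(basepath)
    sto2 = tifffile.imread(base + "_sto2.tif").astype(float)
    mask8 = tifffile.imread(base + "_mask.tif")
    sidecar = read_json(base + "_sto2.json")
    return StO2Map(
        sto2,
        valid_mask=(mask8 & 1).astype(bool),
        clipped_mask=(mask8 & 2).astype(bool),
        provenance=tuple(sidecar["provenance_frames"]),
    )
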