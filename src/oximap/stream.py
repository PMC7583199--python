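"""Interleaved two-wavelength video stream: simulation, pairing, WLI split.

The imaging device alternates 445 nm and 473 nm illumination synchronously
with the video frames at 30 fps.  Even-indexed frames (445 nm, shared with
white-light imaging) and odd-indexed frames (473 nm) are paired disjointly,
so a 30-frame second yields 15 StO2 maps and 15 white-light frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import tifffile

from . import spectra
from .errors import StreamIntegrityError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import ScenePhantom

logger = logging.getLogger("oximap.stream")

#: Sensor full scale: 16-bit linear.
DEFAULT_FULL_SCALE = 65535.0

#: Nominal capture rate of the interleaved stream, frames per second.
NOMINAL_RATE_FPS = 30.0

#: Fraction of full scale the brightest phantom pixel is exposed to.
DEFAULT_EXPOSURE_FRACTION = 0.6


@dataclass(frozen=True)
class Frame:
    """One sensor frame tagged with its illumination wavelength."""

    pixels: np.ndarray
    illumination_nm: float
    index: int
    saturated_value: float = DEFAULT_FULL_SCALE

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError("stream: frame pixels must be a 2-D image")
        if np.any(px < 0) or np.any(px > self.saturated_value):
            raise ValidationError("stream: pixel intensities must lie in [0, full scale]")
        if self.illumination_nm not in (445.0, 473.0):
            raise ValidationError("stream: illumination wavelength must be 445 or 473 nm")
        if self.index < 0:
            raise ValidationError("stream: frame index must be non-negative")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class InterleavedStream:
    """Ordered frame sequence with strictly alternating 445/473 tags."""

    frames: tuple[Frame, ...]
    nominal_rate_fps: float = NOMINAL_RATE_FPS

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        for i, f in enumerate(frames):
            expected = 445.0 if i % 2 == 0 else 473.0
            if f.illumination_nm != expected:
                raise StreamIntegrityError(
                    f"stream: frame {i} tagged {f.illumination_nm:g} nm, expected "
                    f"{expected:g} nm (445/473 alternation starting at 445)"
                )
            if f.index != i:
                raise StreamIntegrityError(f"stream: frame {i} carries index {f.index}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor noise model: Poisson shot noise plus Gaussian read noise.

    With ``shot_noise`` enabled each clean intensity (in counts) is replaced
    by a Poisson draw of the same mean; ``read_noise_sd`` is the standard
    deviation of the additive read noise in counts.
    """

    shot_noise: bool = True
    read_noise_sd: float = 10.0

    @classmethod
    def disabled(cls) -> "NoiseConfig":
        return cls(shot_noise=False, read_noise_sd=0.0)


def simulate_stream(
    scene: "ScenePhantom",
    n_frames: int,
    noise_config: NoiseConfig | None = None,
    seed: int = 0,
    *,
    table: spectra.ExtinctionTable | None = None,
    pathlength_mm: float = 0.15,
    dpf: float = 1.0,
    gain: float | None = None,
    full_scale: float = DEFAULT_FULL_SCALE,
) -> InterleavedStream:
    """Simulate an interleaved 445/473 nm stream viewing a phantom scene.

    Pixel intensity is ``gain * R(scene pixel, wavelength)`` with the
    modified Beer-Lambert reflectance, degraded by the configured noise and
    clipped to the sensor range; specular pixels saturate at full scale.
    When ``gain`` is None it is set so the brightest clean pixel across both
    wavelengths sits at ~60 % of full scale.  Bit-identical for equal seeds.
    """
    if n_frames < 2:
        raise ValidationError("stream: need at least 2 frames (one 445/473 pair)")
    noise = noise_config if noise_config is not None else NoiseConfig()
    tab = table if table is not None else spectra.ExtinctionTable.default()

    state = spectra.OpticalState(
        sto2_frac=scene.sto2_truth / 100.0,
        thb_g_per_l=scene.thb_truth,
        pathlength_mm=pathlength_mm,
        baseline_reflectance=scene.baseline_truth,
    )
    clean = {
        wl: np.asarray(spectra.reflectance(state, wl, tab, dpf=dpf))
        for wl in (445.0, 473.0)
    }
    if gain is None:
        peak = max(clean[445.0].max(), clean[473.0].max())
        gain = DEFAULT_EXPOSURE_FRACTION * full_scale / peak
    counts = {wl: gain * clean[wl] for wl in clean}

    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        wl = 445.0 if i % 2 == 0 else 473.0
        px = counts[wl]
        if noise.shot_noise:
            px = rng.poisson(px).astype(float)
        else:
            px = px.copy()
        if noise.read_noise_sd > 0:
            px += rng.normal(0.0, noise.read_noise_sd, size=px.shape)
        px[scene.specular_mask] = full_scale
        np.clip(px, 0.0, full_scale, out=px)
        frames.append(Frame(px, wl, i, saturated_value=full_scale))
    logger.info("simulated %d frames (%dx%d) at gain %.3g", n_frames, *frames[0].pixels.shape, gain)
    return InterleavedStream(tuple(frames))


def pair_frames(stream: InterleavedStream) -> list[tuple[Frame, Frame]]:
    """Disjoint consecutive (445, 473) pairs: frames (0,1), (2,3), ...

    A trailing unpaired frame is dropped; 30 frames in one second thus yield
    exactly 15 pairs, matching the device's 15 fps StO2 output.
    """
    frames = stream.frames
    n_pairs = len(frames) // 2
    if len(frames) % 2:
        logger.debug("stream: dropping trailing unpaired frame %d", frames[-1].index)
    pairs = [(frames[2 * k], frames[2 * k + 1]) for k in range(n_pairs)]
    for f445, f473 in pairs:
        if f445.illumination_nm != 445.0 or f473.illumination_nm != 473.0:
            raise StreamIntegrityError("stream: pair tags violate (445, 473) order")
    logger.info("paired %d frames into %d StO2 inputs", 2 * n_pairs, n_pairs)
    return pairs


def extract_wli(stream: InterleavedStream) -> list[Frame]:
    """The white-light channel: exactly the even-index (445 nm) frames."""
    return [f for f in stream.frames if f.index % 2 == 0]


# -- serialization ---------------------------------------------------------


def save_stream(stream: InterleavedStream, directory, manifest_extra: dict | None = None) -> Path:
    """Write frames as ``frame_{index:05d}_{wavelength}.tif`` plus manifest.json."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for f in stream.frames:
        name = f"frame_{f.index:05d}_{int(f.illumination_nm)}.tif"
        tifffile.imwrite(out / name, f.pixels.astype(np.float32))
    manifest = {
        "n_frames": len(stream),
        "nominal_rate_fps": stream.nominal_rate_fps,
        "saturated_value": stream.frames[0].saturated_value if stream.frames else None,
        "shape": list(stream.frames[0].pixels.shape) if stream.frames else None,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def load_stream(directory) -> InterleavedStream:
    """Read a stream directory written by :func:`save_stream`."""
    src = Path(directory)
    manifest = json.loads((src / "manifest.json").read_text())
    full = float(manifest.get("saturated_value") or DEFAULT_FULL_SCALE)
    frames = []
    for path in sorted(src.glob("frame_*.tif")):
        stem = path.stem.split("_")
        idx, wl = int(stem[1]), float(stem[2])
        frames.append(Frame(tifffile.imread(path).astype(float), wl, idx, saturated_value=full))
    frames.sort(key=lambda f: f.index)
    return InterleavedStream(
        tuple(frames), nominal_rate_fps=float(manifest.get("nominal_rate_fps", NOMINAL_RATE_FPS))
    )
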