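"""Synthetic tissue phantoms and the four-time-point ischemia experiment.

No animal data accompany the study this package emulates, so testing is
done on synthetic scenes: smooth Gaussian-random-field StO2 maps over a
mucosa-like baseline, with mild hemoglobin and albedo heterogeneity and a
sparse specular mask.  The experiment generator reproduces the study
design: n subjects, four time points (before/after anastomosis, 1 min and
30 min after arterial ligation), subject-level means drawn around the
reported group means, and — after ligation — a demarcated hypoxic region
with a smooth sigmoidal boundary covering the three ROI sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from . import quantify, spectra, stream as stream_mod
from .errors import ValidationError
from .estimator import EstimatorConfig, StO2Map, estimate_sto2
from .ioutils import config_hash, write_json
from .stream import InterleavedStream, NoiseConfig, pair_frames, simulate_stream

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

logger = logging.getLogger("oximap.phantom")

DEFAULT_SHAPE = (256, 256)

#: Study defaults: group mean and between-subject SD (%) per time point.
DEFAULT_TIMEPOINT_MEANS = (52.6, 52.0, 15.9, 12.1)
DEFAULT_TIMEPOINT_SDS = (2.0, 2.6, 6.0, 5.3)

#: Time points whose scenes carry a demarcated hypoxic region.
LIGATION_TIMEPOINTS = ("post_ligation_1min", "post_ligation_30min")


@dataclass(frozen=True)
class SceneConfig:
    """Texture parameters of the phantom mucosa.

    StO2 spatial correlation length and the mild hemoglobin/baseline
    heterogeneity emulate smooth perfusion texture; the specular fraction
    emulates wet-surface highlights.  Hemoglobin heterogeneity is kept small
    (1 % relative SD) because a two-wavelength intensity log-ratio estimator
    maps concentration error into StO2 error (see the methods note).
    """

    corr_len_px: float = 12.0
    thb_mean_g_per_l: float = 15.0
    thb_rel_sd: float = 0.01
    baseline_mean: float = 0.5
    baseline_rel_sd: float = 0.05
    specular_frac: float = 0.005
    region_radius_rel: float = 0.42
    region_edge_px: float = 8.0


@dataclass(frozen=True)
class ScenePhantom:
    """Ground-truth optical state of one synthetic scene."""

    sto2_truth: np.ndarray
    thb_truth: np.ndarray
    baseline_truth: np.ndarray
    specular_mask: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sto2_truth, dtype=float)
        if np.any(s < 0) or np.any(s > 100):
            raise ValidationError("phantom: sto2_truth must lie in [0, 100] %")
        if np.any(np.asarray(self.thb_truth) < 0):
            raise ValidationError("phantom: thb_truth must be >= 0")
        b = np.asarray(self.baseline_truth, dtype=float)
        if np.any(b <= 0) or np.any(b > 1):
            raise ValidationError("phantom: baseline_truth must lie in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sto2_truth.shape


def _unit_grf(rng: np.random.Generator, shape: tuple[int, int], corr_len_px: float) -> np.ndarray:
    """Smooth Gaussian random field standardized to zero mean, unit SD."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=corr_len_px, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def _texture(
    rng: np.random.Generator, shape: tuple[int, int], config: SceneConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    thb = config.thb_mean_g_per_l * (
        1.0 + config.thb_rel_sd * _unit_grf(rng, shape, 2 * config.corr_len_px)
    )
    baseline = np.clip(
        config.baseline_mean
        * (1.0 + config.baseline_rel_sd * _unit_grf(rng, shape, 2 * config.corr_len_px)),
        1e-3,
        1.0,
    )
    specular = rng.random(shape) < config.specular_frac
    return np.clip(thb, 0.0, None), baseline, specular


def make_scene(
    target_mean: float,
    spatial_sd: float,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    config: SceneConfig | None = None,
) -> ScenePhantom:
    """Homogeneous-perfusion phantom: clipped smooth GRF StO2 field.

    The field has the stated mean and SD before clipping to [0, 100];
    hemoglobin and baseline are mildly heterogeneous; ~0.5 % of pixels are
    specular.  Deterministic per seed.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    sto2 = target_mean + (
        spatial_sd * _unit_grf(rng, shape, cfg.corr_len_px) if spatial_sd > 0 else 0.0
    )
    thb, baseline, specular = _texture(rng, shape, cfg)
    return ScenePhantom(np.clip(np.broadcast_to(sto2, shape).copy(), 0, 100), thb, baseline, specular)


def hypoxic_region_weight(shape: tuple[int, int], config: SceneConfig | None = None) -> np.ndarray:
    """Sigmoid membership (1 inside) of the demarcated hypoxic region.

    A central disk with a smooth sigmoidal edge, mimicking the visible
    demarcation line after arterial ligation; it covers the default ROI
    sites with a wide margin.
    """
    cfg = config or SceneConfig()
    rr, cc = np.indices(shape, dtype=float)
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    radius = cfg.region_radius_rel * min(shape)
    dist = np.hypot(rr - r0, cc - c0)
    return 1.0 / (1.0 + np.exp((dist - radius) / cfg.region_edge_px))


def make_ischemic_scene(
    interior_mean: float,
    surround_mean: float,
    spatial_sd: float,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    config: SceneConfig | None = None,
) -> ScenePhantom:
    """Post-ligation phantom: hypoxic disk at ``interior_mean`` inside a
    perfused surround, blended through a sigmoidal demarcation edge."""
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    w = hypoxic_region_weight(shape, cfg)
    mean_map = surround_mean + (interior_mean - surround_mean) * w
    sto2 = mean_map + (
        spatial_sd * _unit_grf(rng, shape, cfg.corr_len_px) if spatial_sd > 0 else 0.0
    )
    thb, baseline, specular = _texture(rng, shape, cfg)
    return ScenePhantom(np.clip(sto2, 0, 100), thb, baseline, specular)


@dataclass(frozen=True)
class IschemiaProtocol:
    """The synthetic study protocol.

    Defaults are the study's group results: time-point means
    (52.6, 52.0, 15.9, 12.1) % with between-subject SDs (2.0, 2.6, 6.0,
    5.3) %, n = 3 subjects, two frames (one StO2 map) per acquisition.
    ``within_scene_sd`` is the spatial SD of the StO2 texture.
    """

    timepoint_means: tuple[float, float, float, float] = DEFAULT_TIMEPOINT_MEANS
    timepoint_sds: tuple[float, float, float, float] = DEFAULT_TIMEPOINT_SDS
    within_scene_sd: float = 3.0
    n_subjects: int = 3
    shape: tuple[int, int] = DEFAULT_SHAPE
    n_frames: int = 2
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    scene_config: SceneConfig = field(default_factory=SceneConfig)
    surround_mean: float = 52.0

    def __post_init__(self) -> None:
        if len(self.timepoint_means) != 4 or len(self.timepoint_sds) != 4:
            raise ValidationError("phantom: protocol needs four time points")
        if any(not 0 <= m <= 100 for m in self.timepoint_means):
            raise ValidationError("phantom: time-point means must lie in [0, 100] %")
        if any(sd < 0 for sd in self.timepoint_sds):
            raise ValidationError("phantom: between-subject SDs must be >= 0")
        if self.n_subjects < 1:
            raise ValidationError("phantom: need at least one subject")


@dataclass(frozen=True)
class Acquisition:
    """One simulated endoscopy: stream, scene and its ground truth."""

    stream: InterleavedStream
    scene: ScenePhantom
    truth_mean: float
    subject: str
    timepoint: str


def simulate_experiment(
    protocol: IschemiaProtocol,
    table: spectra.ExtinctionTable | None = None,
) -> dict[tuple[str, str], Acquisition]:
    """Simulate every (subject, time point) acquisition of the protocol.

    Subject-level means are drawn Normal(target mean, between-subject SD)
    and clipped to [0, 100]; post-ligation scenes embed the demarcated
    hypoxic region at the drawn mean, earlier scenes are homogeneous at it.
    All randomness flows from the protocol seed through spawned
    sub-generators, so each acquisition is independently reproducible.
    """
    tab = table if table is not None else spectra.ExtinctionTable.default()
    root = np.random.SeedSequence(protocol.seed)
    dataset: dict[tuple[str, str], Acquisition] = {}
    children = root.spawn(protocol.n_subjects * len(quantify.TIMEPOINTS))
    k = 0
    for s in range(protocol.n_subjects):
        subject = f"pig{s + 1}"
        for tp, target, sd in zip(
            quantify.TIMEPOINTS, protocol.timepoint_means, protocol.timepoint_sds
        ):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            subject_mean = float(np.clip(rng.normal(target, sd), 0.0, 100.0))
            scene_seed, stream_seed = (int(x) for x in child.generate_state(2) % (2**31))
            if tp in LIGATION_TIMEPOINTS:
                scene = make_ischemic_scene(
                    subject_mean,
                    protocol.surround_mean,
                    protocol.within_scene_sd,
                    protocol.shape,
                    seed=scene_seed,
                    config=protocol.scene_config,
                )
            else:
                scene = make_scene(
                    subject_mean,
                    protocol.within_scene_sd,
                    protocol.shape,
                    seed=scene_seed,
                    config=protocol.scene_config,
                )
            strm = simulate_stream(
                scene,
                protocol.n_frames,
                noise_config=protocol.noise,
                seed=stream_seed,
                table=tab,
            )
            dataset[(subject, tp)] = Acquisition(strm, scene, subject_mean, subject, tp)
    logger.info(
        "simulated experiment: %d subjects x %d time points = %d streams",
        protocol.n_subjects, len(quantify.TIMEPOINTS), len(dataset),
    )
    return dataset


@dataclass(frozen=True)
class ExperimentResult:
    """End-to-end pipeline output for one simulated experiment."""

    roi_table: "pd.DataFrame"
    values: "pd.DataFrame"
    summaries: list[quantify.TimePointSummary]
    tests: "pd.DataFrame"
    truth_means: dict[tuple[str, str], float]


def run_experiment(
    protocol: IschemiaProtocol,
    lut: spectra.InversionLUT | None = None,
    estimator_config: EstimatorConfig | None = None,
    roi_side_px: int = quantify.DEFAULT_ROI_SIDE_PX,
    mode: str = "per_subject",
    table: spectra.ExtinctionTable | None = None,
) -> ExperimentResult:
    """Simulate the protocol and run estimation + ROI quantification on it."""
    tab = table if table is not None else spectra.ExtinctionTable.default()
    lut = lut if lut is not None else spectra.build_inversion_lut(tab)
    dataset = simulate_experiment(protocol, table=tab)
    maps: dict[tuple[str, str], StO2Map] = {}
    for key, acq in dataset.items():
        f445, f473 = pair_frames(acq.stream)[0]
        maps[key] = estimate_sto2(f445, f473, lut, estimator_config)
    roi_specs = quantify.default_roi_specs(protocol.shape, side_px=roi_side_px)
    table_df = quantify.roi_table(maps, roi_specs)
    values = quantify.per_subject_values(table_df, mode=mode)
    summaries = quantify.summarize_experiment(values)
    tests = quantify.pairwise_tests(values)
    truth = {key: acq.truth_mean for key, acq in dataset.items()}
    return ExperimentResult(table_df, values, summaries, tests, truth)


# -- serialization ---------------------------------------------------------


def write_dataset(
    dataset: dict[tuple[str, str], Acquisition], directory, protocol: IschemiaProtocol
) -> None:
    """Write each acquisition as a stream directory plus truth TIFFs.

    The top-level manifest records the protocol, its config hash and the
    three auto-placed ROI sites.
    """
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    roi_specs = quantify.default_roi_specs(protocol.shape)
    for (subject, tp), acq in sorted(dataset.items()):
        sub = out / subject / tp
        stream_mod.save_stream(acq.stream, sub, manifest_extra={"truth_mean": acq.truth_mean})
        tifffile.imwrite(sub / "truth_sto2.tif", acq.scene.sto2_truth.astype(np.float32))
        tifffile.imwrite(sub / "truth_thb.tif", acq.scene.thb_truth.astype(np.float32))
    write_json(
        out / "experiment_manifest.json",
        {
            "protocol": protocol,
            "config_hash": config_hash(protocol),
            "subjects": sorted({s for s, _ in dataset}),
            "timepoints": list(quantify.TIMEPOINTS),
            "roi_sites": [
                {"label": r.label, "center": list(r.center), "side_px": r.side_px}
                for r in roi_specs
            ],
        },
    )
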