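"""ROI quantification and the study's statistical protocol.

Quantification follows the evaluation protocol of the ischemia experiment:
three square regions of interest per image, the arithmetic mean of valid
StO2 pixels per ROI, one value per subject per time point (mean of its ROI
means, preserving subject pairing), mean +/- sample SD per time point, and
two-sided paired t-tests between time points at alpha = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GeometryError, InsufficientDataError, ValidationError
from .estimator import StO2Map

logger = logging.getLogger("oximap.quantify")

#: The four experimental time points, in protocol order.
TIMEPOINTS = (
    "pre_anastomosis",
    "post_anastomosis",
    "post_ligation_1min",
    "post_ligation_30min",
)

#: The three between-time-point comparisons the protocol tests.
COMPARISONS = (
    ("pre_anastomosis", "post_anastomosis"),
    ("post_anastomosis", "post_ligation_1min"),
    ("post_ligation_1min", "post_ligation_30min"),
)

ALPHA = 0.05

#: Relative (row, col) positions of the three ROI sites.
DEFAULT_ROI_REL_SITES = ((0.42, 0.42), (0.42, 0.58), (0.58, 0.50))

DEFAULT_ROI_SIDE_PX = 21

#: Minimum fraction of valid pixels for an ROI mean to be reportable.
MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class RoiSpec:
    """A square ROI: 0-based (row, col) center, odd side length, label."""

    center: tuple[int, int]
    side_px: int = DEFAULT_ROI_SIDE_PX
    label: str = "roi"

    def __post_init__(self) -> None:
        if self.side_px <= 0 or self.side_px % 2 == 0:
            raise ValidationError("quantify: ROI side must be an odd positive integer")

    def slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        half = self.side_px // 2
        r, c = self.center
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise GeometryError(
                f"quantify: ROI '{self.label}' ({self.side_px}px at {self.center}) "
                f"exceeds image bounds {shape}"
            )
        return slice(r0, r1), slice(c0, c1)


def default_roi_specs(
    shape: tuple[int, int],
    side_px: int = DEFAULT_ROI_SIDE_PX,
    rel_sites: tuple[tuple[float, float], ...] = DEFAULT_ROI_REL_SITES,
) -> list[RoiSpec]:
    """Three ROIs at fixed relative positions, labelled roi1..roi3."""
    return [
        RoiSpec(
            center=(int(round(rr * shape[0])), int(round(rc * shape[1]))),
            side_px=side_px,
            label=f"roi{i + 1}",
        )
        for i, (rr, rc) in enumerate(rel_sites)
    ]


def roi_mean(sto2_map: StO2Map, roi: RoiSpec) -> float:
    """Arithmetic mean StO2 (%) over valid pixels of the ROI.

    Requires at least half of the ROI pixels to be valid; clipped pixels
    count as valid (the display shows 0-100 % everywhere).
    """
    rs, cs = roi.slices(sto2_map.sto2_pct.shape)
    patch = sto2_map.sto2_pct[rs, cs]
    valid = sto2_map.valid_mask[rs, cs]
    frac = valid.mean()
    if frac < MIN_VALID_FRACTION:
        raise InsufficientDataError(
            f"quantify: ROI '{roi.label}' has only {frac:.0%} valid pixels "
            f"(needs >= {MIN_VALID_FRACTION:.0%})"
        )
    return float(patch[valid].mean())


def summarize_timepoint(values) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of per-subject StO2 values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("quantify: need at least two subjects to summarize")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test: t statistic, degrees of freedom, p-value.

    ``degenerate`` marks zero-variance differences; with all differences
    exactly zero the result is t = 0, p = 1 rather than an error.
    """

    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t_test(a, b) -> PairedTestResult:
    """Two-sided paired t-test of subject-aligned samples ``a`` vs ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("quantify: paired samples must be equal-length 1-D, n >= 2")
    d = a - b
    if np.all(d == d[0]) and d.std(ddof=1) == 0.0:
        if d[0] == 0.0:
            return PairedTestResult(0.0, a.size - 1, 1.0, degenerate=True)
        return PairedTestResult(math.copysign(math.inf, d[0]), a.size - 1, 0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(float(res.statistic), a.size - 1, float(res.pvalue))


@dataclass(frozen=True)
class TimePointSummary:
    """Per-time-point aggregate: per-subject values plus mean +/- SD (%)."""

    timepoint: str
    per_subject_values: tuple[float, ...]
    mean: float
    sd: float


# -- protocol-level tables -------------------------------------------------


def roi_table(maps: dict[tuple[str, str], StO2Map], roi_specs: list[RoiSpec]) -> pd.DataFrame:
    """Long-format ROI table: one row per (subject, timepoint, ROI).

    ``maps`` is keyed by (subject, timepoint).
    """
    rows = [
        {
            "subject": subject,
            "timepoint": timepoint,
            "roi_label": roi.label,
            "sto2_mean": roi_mean(m, roi),
        }
        for (subject, timepoint), m in sorted(maps.items())
        for roi in roi_specs
    ]
    return pd.DataFrame(rows, columns=["subject", "timepoint", "roi_label", "sto2_mean"])


def per_subject_values(table: pd.DataFrame, mode: str = "per_subject") -> pd.DataFrame:
    """Subject x timepoint matrix of StO2 values for the paired tests.

    ``per_subject`` (default) averages each subject's ROI means to one value
    per subject, preserving the pairing unit; ``pooled`` keeps every ROI as
    its own paired observation (subject:roi pairs).
    """
    if mode == "per_subject":
        wide = table.groupby(["subject", "timepoint"])["sto2_mean"].mean().unstack("timepoint")
    elif mode == "pooled":
        wide = table.set_index(["subject", "roi_label", "timepoint"])["sto2_mean"].unstack(
            "timepoint"
        )
    else:
        raise ValidationError(f"quantify: unknown pooling mode '{mode}'")
    present = [tp for tp in TIMEPOINTS if tp in wide.columns]
    return wide[present]


def summarize_experiment(values: pd.DataFrame) -> list[TimePointSummary]:
    """Time-point summaries (mean +/- sample SD) from a subject x timepoint matrix."""
    out = []
    for tp in values.columns:
        v = values[tp].to_numpy(dtype=float)
        mean, sd = summarize_timepoint(v)
        out.append(TimePointSummary(tp, tuple(v), mean, sd))
    return out


def pairwise_tests(values: pd.DataFrame) -> pd.DataFrame:
    """The protocol's three paired comparisons on a subject x timepoint matrix."""
    rows = []
    for tp_a, tp_b in COMPARISONS:
        if tp_a not in values.columns or tp_b not in values.columns:
            continue
        res = paired_t_test(values[tp_a].to_numpy(), values[tp_b].to_numpy())
        rows.append(
            {
                "comparison": f"{tp_a} vs {tp_b}",
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": bool(res.p < ALPHA),
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows, columns=["comparison", "t", "df", "p", "significant", "degenerate"])


def report_text(summaries: list[TimePointSummary], tests: pd.DataFrame) -> str:
    """Human-readable summary of the quantification."""
    lines = ["StO2 quantification report", "=" * 26, "", "Time-point summaries (mean +/- SD, %):"]
    for s in summaries:
        subj = ", ".join(f"{v:.1f}" for v in s.per_subject_values)
        lines.append(f"  {s.timepoint:<22s} {s.mean:5.1f} +/- {s.sd:4.1f}   (subjects: {subj})")
    lines += ["", f"Paired two-sided t-tests (alpha = {ALPHA:g}):"]
    for _, row in tests.iterrows():
        mark = "*" if row["significant"] else " "
        lines.append(
            f" {mark} {row['comparison']:<46s} t = {row['t']:7.3f}, df = {row['df']:d}, "
            f"p = {row['p']:.4f}"
        )
    return "\n".join(lines) + "\n"


def plot_timepoint_bars(summaries: list[TimePointSummary], path) -> None:
    """Bar chart of time-point means with SD error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [s.timepoint.replace("_", "\n") for s in summaries]
    means = [s.mean for s in summaries]
    sds = [s.sd for s in summaries]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, means, yerr=sds, capsize=4, color="#4878a8", edgecolor="black")
    ax.set_ylabel("StO$_2$ (%)")
    ax.set_ylim(0, 100)
    ax.set_title("Mean StO$_2$ by time point (error bars: SD)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
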