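"""Hemoglobin absorption physics and the two-wavelength forward model.

The imaging mode estimates tissue oxygen saturation (StO2) from the
difference in light absorption between oxy- and deoxy-hemoglobin at the two
illumination wavelengths, 445 nm and 473 nm.  This module provides

* the packaged oxy/deoxy-Hb molar extinction table,
* a modified Beer-Lambert reflectance model
  ``R(lambda) = R0 * exp(-mu_a(lambda) * DPF * d)``,
* construction of the monotone lookup table that inverts the inter-frame
  log-ratio ``ln(R473 / R445)`` back to StO2 in percent.

Concentration convention: total hemoglobin is expressed in g/L and converted
to molarity with the tetramer molar mass 64,500 g/mol; extinction
coefficients are decadic, per tetramer, in cm^-1 M^-1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .errors import ConstructionError, RangeError, ValidationError

#: Molar mass of the hemoglobin tetramer, g/mol (4-heme convention).
HB_MOLAR_MASS_G_PER_MOL = 64_500.0

#: ln(10): converts decadic extinction to a natural-log absorption coefficient.
_LN10 = float(np.log(10.0))

#: Illumination wavelength pair of the imaging mode, nm.
DEFAULT_WAVELENGTH_PAIR = (445.0, 473.0)

_RESOURCE = "hb_extinction_synthetic.csv"


@dataclass(frozen=True)
class ExtinctionTable:
    """Wavelength-indexed molar extinction of oxy- and deoxy-hemoglobin.

    Attributes
    ----------
    wavelength_nm : strictly increasing grid, covering at least 400-600 nm.
    eps_oxy, eps_deoxy : decadic molar extinction, cm^-1 M^-1, all > 0.
    """

    wavelength_nm: np.ndarray
    eps_oxy: np.ndarray
    eps_deoxy: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        eo = np.asarray(self.eps_oxy, dtype=float)
        ed = np.asarray(self.eps_deoxy, dtype=float)
        if not (w.ndim == 1 and w.size >= 2 and np.all(np.diff(w) > 0)):
            raise ValidationError("spectra: wavelength grid must be 1-D and strictly increasing")
        if eo.shape != w.shape or ed.shape != w.shape:
            raise ValidationError("spectra: extinction columns must match the wavelength grid")
        if not (np.all(eo > 0) and np.all(ed > 0)):
            raise ValidationError("spectra: extinction coefficients must be positive")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "eps_oxy", eo)
        object.__setattr__(self, "eps_deoxy", ed)

    # -- queries -----------------------------------------------------------

    def _check_range(self, wavelength_nm: float) -> None:
        w = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if np.any(w < lo) or np.any(w > hi):
            raise RangeError(
                f"spectra: wavelength {wavelength_nm} nm outside table range [{lo}, {hi}] nm"
            )

    def extinction(self, wavelength_nm: float) -> tuple[float, float]:
        """Interpolated (eps_oxy, eps_deoxy) at ``wavelength_nm`` (cm^-1 M^-1)."""
        self._check_range(wavelength_nm)
        eo = np.interp(wavelength_nm, self.wavelength_nm, self.eps_oxy)
        ed = np.interp(wavelength_nm, self.wavelength_nm, self.eps_deoxy)
        return float(eo), float(ed)

    def isosbestic_wavelengths(self) -> np.ndarray:
        """Wavelengths where the interpolated oxy and deoxy spectra cross.

        At these points absorption is independent of StO2.  Roots are found
        by bisection on the piecewise-linear difference, one per sign change.
        """
        w = self.wavelength_nm
        d = self.eps_oxy - self.eps_deoxy

        def diff(x: float) -> float:
            return float(np.interp(x, w, self.eps_oxy) - np.interp(x, w, self.eps_deoxy))

        roots = [float(w[i]) for i in range(w.size) if d[i] == 0.0]
        sign = np.sign(d)
        for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
            roots.append(brentq(diff, w[i], w[i + 1], xtol=1e-12))
        return np.array(sorted(roots))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path_or_buffer) -> "ExtinctionTable":
        """Read a 3-column table (wavelength_nm, eps_oxy, eps_deoxy).

        Lines starting with ``#`` are comment header; an optional column
        header line is tolerated.
        """
        data = np.genfromtxt(path_or_buffer, delimiter=",", comments="#", names=True)
        if data.dtype.names and set(data.dtype.names) >= {"wavelength_nm", "eps_oxy", "eps_deoxy"}:
            return cls(data["wavelength_nm"], data["eps_oxy"], data["eps_deoxy"])
        arr = np.atleast_2d(np.asarray(data.tolist(), dtype=float))
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The packaged 400-600 nm, 2 nm-step extinction table."""
        text = resources.files("oximap.data").joinpath(_RESOURCE).read_text()
        return cls.from_csv(io.StringIO(text))


@dataclass(frozen=True)
class OpticalState:
    """Per-pixel (or scalar) optical state of the tissue.

    Fields may be scalars or broadcastable arrays; ``sto2_frac`` is the
    saturation as a fraction (StO2 % / 100), ``thb_g_per_l`` the total
    hemoglobin concentration in g/L, ``pathlength_mm`` the effective optical
    pathlength, and ``baseline_reflectance`` the reflectance at zero
    absorption.
    """

    sto2_frac: float | np.ndarray
    thb_g_per_l: float | np.ndarray
    pathlength_mm: float | np.ndarray
    baseline_reflectance: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.sto2_frac, dtype=float)
        c = np.asarray(self.thb_g_per_l, dtype=float)
        d = np.asarray(self.pathlength_mm, dtype=float)
        b = np.asarray(self.baseline_reflectance, dtype=float)
        if np.any(s < 0) or np.any(s > 1):
            raise ValidationError("spectra: sto2_frac must lie in [0, 1]")
        if np.any(c < 0):
            raise ValidationError("spectra: total hemoglobin concentration must be >= 0")
        if np.any(d <= 0):
            raise ValidationError("spectra: pathlength must be positive")
        if np.any(b <= 0) or np.any(b > 1):
            raise ValidationError("spectra: baseline reflectance must lie in (0, 1]")


def absorption_coefficient(
    table: ExtinctionTable, wavelength_nm: float, state: OpticalState
) -> float | np.ndarray:
    """Tissue absorption coefficient mu_a in mm^-1.

    ``mu_a = ln(10) * (s * eps_oxy + (1 - s) * eps_deoxy) * c_molar``, with
    the concentration converted from g/L via the tetramer molar mass and the
    cm^-1 result divided by 10 to yield mm^-1.  Affine in ``sto2_frac``.
    """
    eps_oxy, eps_deoxy = table.extinction(wavelength_nm)
    s = np.asarray(state.sto2_frac, dtype=float)
    c_molar = np.asarray(state.thb_g_per_l, dtype=float) / HB_MOLAR_MASS_G_PER_MOL
    eps_mix = s * eps_oxy + (1.0 - s) * eps_deoxy
    mu_a_per_cm = _LN10 * eps_mix * c_molar
    out = mu_a_per_cm / 10.0
    return float(out) if out.ndim == 0 else out


def reflectance(
    state: OpticalState,
    wavelength_nm: float,
    table: ExtinctionTable,
    dpf: float = 1.0,
) -> float | np.ndarray:
    """Modified Beer-Lambert diffuse reflectance at one wavelength.

    ``R = baseline * exp(-mu_a * DPF * pathlength)`` with a fixed
    differential pathlength factor (default 1) and a wavelength-independent
    baseline.  Returns values in (0, baseline].
    """
    mu_a = absorption_coefficient(table, wavelength_nm, state)
    b = np.asarray(state.baseline_reflectance, dtype=float)
    d = np.asarray(state.pathlength_mm, dtype=float)
    out = b * np.exp(-np.asarray(mu_a) * dpf * d)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class LutConfig:
    """Reference state and grid used to build the inversion lookup table.

    The reference concentration/pathlength are deliberately those of the
    default tissue phantom, so the table is exact there; sensitivity to a
    concentration mismatch is a measured property, not assumed zero.
    """

    wavelength_pair_nm: tuple[float, float] = DEFAULT_WAVELENGTH_PAIR
    thb_ref_g_per_l: float = 15.0
    pathlength_ref_mm: float = 0.15
    dpf: float = 1.0
    baseline_reflectance: float = 0.5
    grid_step_pct: float = 0.5


@dataclass(frozen=True)
class InversionLUT:
    """Monotone map between the log-ratio ``ln(R473/R445)`` and StO2 %.

    ``ratio_grid`` is stored strictly increasing with ``sto2_grid`` aligned
    (the physical direction -- StO2 rising as the log-ratio falls for the
    default wavelengths -- is fixed by the extinction table, not assumed).
    Queries outside the tabulated range clip to 0 or 100.
    """

    ratio_grid: np.ndarray
    sto2_grid: np.ndarray
    config: LutConfig = field(default_factory=LutConfig)

    def __post_init__(self) -> None:
        r = np.asarray(self.ratio_grid, dtype=float)
        s = np.asarray(self.sto2_grid, dtype=float)
        if r.shape != s.shape or r.ndim != 1 or r.size < 2:
            raise ConstructionError("spectra: LUT grids must be matching 1-D arrays")
        if not np.all(np.diff(r) > 0):
            raise ConstructionError("spectra: LUT ratio grid must be strictly increasing")
        if not (s.min() == 0.0 and s.max() == 100.0):
            raise ConstructionError("spectra: LUT StO2 grid must span 0-100 %")
        object.__setattr__(self, "ratio_grid", r)
        object.__setattr__(self, "sto2_grid", s)

    @property
    def grid_step_pct(self) -> float:
        return self.config.grid_step_pct

    def invert(self, log_ratio: float | np.ndarray) -> float | np.ndarray:
        """StO2 % for a measured log-ratio, clipped to [0, 100] out of range."""
        out = np.interp(np.asarray(log_ratio, dtype=float), self.ratio_grid, self.sto2_grid)
        return float(out) if np.ndim(out) == 0 else out

    def out_of_range(self, log_ratio: np.ndarray) -> np.ndarray:
        """Boolean mask of queries outside the tabulated ratio span."""
        r = np.asarray(log_ratio, dtype=float)
        return (r < self.ratio_grid[0]) | (r > self.ratio_grid[-1])

    def forward(self, sto2_pct: float | np.ndarray) -> float | np.ndarray:
        """Log-ratio the reference state would produce at ``sto2_pct``."""
        out = np.interp(
            np.asarray(sto2_pct, dtype=float), self.sto2_grid[::-1], self.ratio_grid[::-1]
        ) if self.sto2_grid[0] > self.sto2_grid[-1] else np.interp(
            np.asarray(sto2_pct, dtype=float), self.sto2_grid, self.ratio_grid
        )
        return float(out) if np.ndim(out) == 0 else out

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        cfg = self.config
        header = (
            "# StO2 inversion lookup table: ln(R{:g}/R{:g}) -> StO2 %\n"
            "# wavelength_pair_nm={:g},{:g}\n"
            "# thb_ref_g_per_l={:g}\n# pathlength_ref_mm={:g}\n# dpf={:g}\n"
            "# baseline_reflectance={:g}\n# grid_step_pct={:g}\n"
            "log_ratio,sto2_pct\n"
        ).format(
            cfg.wavelength_pair_nm[1], cfg.wavelength_pair_nm[0],
            *cfg.wavelength_pair_nm, cfg.thb_ref_g_per_l, cfg.pathlength_ref_mm,
            cfg.dpf, cfg.baseline_reflectance, cfg.grid_step_pct,
        )
        with open(path, "w") as f:
            f.write(header)
            for r, s in zip(self.ratio_grid, self.sto2_grid):
                f.write(f"{r:.12g},{s:.12g}\n")

    @classmethod
    def from_csv(cls, path) -> "InversionLUT":
        meta: dict[str, str] = {}
        rows: list[tuple[float, float]] = []
        with open(path) as f:
            for line in f:
                line = line.strip()
                if line.startswith("#"):
                    if "=" in line:
                        key, _, val = line.lstrip("# ").partition("=")
                        meta[key.strip()] = val.strip()
                elif line and not line[0].isalpha():
                    a, b = line.split(",")
                    rows.append((float(a), float(b)))
        pair = tuple(float(x) for x in meta["wavelength_pair_nm"].split(","))
        cfg = LutConfig(
            wavelength_pair_nm=(pair[0], pair[1]),
            thb_ref_g_per_l=float(meta["thb_ref_g_per_l"]),
            pathlength_ref_mm=float(meta["pathlength_ref_mm"]),
            dpf=float(meta["dpf"]),
            baseline_reflectance=float(meta["baseline_reflectance"]),
            grid_step_pct=float(meta["grid_step_pct"]),
        )
        arr = np.array(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1], cfg)


def build_inversion_lut(
    table: ExtinctionTable, config: LutConfig | None = None
) -> InversionLUT:
    """Tabulate ``ln(R_long / R_short)`` against StO2 at the reference state.

    For each StO2 grid value the forward model is evaluated at both
    wavelengths of the configured pair; a non-monotone ratio over the grid
    (a degenerate pair with no oxy/deoxy contrast difference) raises
    :class:`ConstructionError`.
    """
    cfg = config or LutConfig()
    w_short, w_long = cfg.wavelength_pair_nm
    step = cfg.grid_step_pct
    if step <= 0 or step > 100:
        raise ConstructionError("spectra: LUT grid step must lie in (0, 100]")
    n = int(round(100.0 / step))
    sto2 = np.linspace(0.0, 100.0, n + 1)
    state = OpticalState(
        sto2_frac=sto2 / 100.0,
        thb_g_per_l=cfg.thb_ref_g_per_l,
        pathlength_mm=cfg.pathlength_ref_mm,
        baseline_reflectance=cfg.baseline_reflectance,
    )
    r_short = reflectance(state, w_short, table, dpf=cfg.dpf)
    r_long = reflectance(state, w_long, table, dpf=cfg.dpf)
    log_ratio = np.log(np.asarray(r_long) / np.asarray(r_short))
    diffs = np.diff(log_ratio)
    if np.all(diffs > 0):
        order = slice(None)
    elif np.all(diffs < 0):
        order = slice(None, None, -1)
    else:
        raise ConstructionError(
            f"spectra: log-ratio not strictly monotone in StO2 for pair "
            f"({w_short:g}, {w_long:g}) nm -- degenerate wavelength pair"
        )
    return InversionLUT(log_ratio[order], sto2[order], cfg)
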