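"""Spectrum data model, wavelength-grid handling and skin-colour screening.

The package works on UV spectra sampled on a common wavelength grid
(canonically 290–400 nm at 1 nm steps).  Three kinds of spectra occur:

* diffuse **reflectance** of skin (fraction of incident light),
* **transmission** of a sunscreen film (fraction),
* **absorbance** in optical-density units (``A = -log10(T)``).

Diffuse reflectance spectroscopy (DRS) infers the double-pass transmission
of an applied sunscreen film from the ratio of protected to bare-skin
reflectance, ``T(λ) = R(λ)/R0(λ)``, giving the in vivo absorbance
``A_DRS(λ) = -log10(T(λ))``.

The module also provides the individual typological angle (ITA°), the
CIELAB-derived pigmentation index used to screen volunteer panels:
``ITA° = arctan((L* - 50)/b*) · 180/π``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "WavelengthWindow",
    "LabColor",
    "CANONICAL_GRID",
    "SpectrumError",
    "GridMismatchError",
    "read_spectrum",
    "resample",
    "drs_absorbance",
    "average_spectra",
    "ita_degrees",
    "screen_panel_ita",
    "PanelScreeningReport",
]

#: Canonical 1 nm wavelength grid used throughout the pipeline (nm).
CANONICAL_GRID = np.arange(290.0, 401.0, 1.0)

_WL_MIN, _WL_MAX = 250.0, 450.0
#: Tolerance allowed above 1.0 for noisy reflectance/transmission values.
_FRACTION_EPS = 0.05
#: Small negative absorbance tolerated (measurement noise when R > R0).
_ABSORBANCE_FLOOR = -0.05

_KINDS = ("reflectance", "transmission", "absorbance", "ratio")


class SpectrumError(ValueError):
    """Invalid spectrum content or incompatible operation."""


class GridMismatchError(SpectrumError):
    """Two spectra do not share an identical wavelength grid."""


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed series of one spectral kind.

    Parameters
    ----------
    wavelengths:
        Strictly increasing wavelengths in nm, all within [250, 450].
    values:
        Reflectance/transmission as fractions (``[0, 1.05]`` with noise
        tolerance) or absorbance in OD units (``>= -0.05``).
    kind:
        One of ``"reflectance"``, ``"transmission"``, ``"absorbance"``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size == 0:
            raise SpectrumError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if wl[0] < _WL_MIN or wl[-1] > _WL_MAX:
            raise SpectrumError(
                f"wavelengths must lie within [{_WL_MIN:g}, {_WL_MAX:g}] nm"
            )
        if not np.all(np.isfinite(vals)):
            raise SpectrumError("non-finite spectrum values")
        if self.kind in ("reflectance", "transmission"):
            if np.any(vals < 0) or np.any(vals > 1.0 + _FRACTION_EPS):
                raise SpectrumError(
                    f"{self.kind} values must lie in [0, {1 + _FRACTION_EPS}]"
                )
        elif self.kind == "absorbance":
            if np.any(vals < _ABSORBANCE_FLOOR):
                raise SpectrumError(
                    f"absorbance values must be >= {_ABSORBANCE_FLOOR}"
                )
        else:  # unitless ratio (e.g. srpd): positive, unbounded above
            if np.any(vals <= 0):
                raise SpectrumError("ratio values must be > 0")

    def __len__(self) -> int:
        return self.wavelengths.size

    def same_grid(self, other: "Spectrum") -> bool:
        """True if both spectra share an identical wavelength array."""
        return (
            self.wavelengths.size == other.wavelengths.size
            and bool(np.array_equal(self.wavelengths, other.wavelengths))
        )

    def slice(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum with ``lo <= λ <= hi`` (inclusive bounds)."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise SpectrumError(f"no grid points inside [{lo:g}, {hi:g}] nm")
        return Spectrum(self.wavelengths[mask], self.values[mask], self.kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths, values, kind or self.kind)


@dataclass(frozen=True)
class WavelengthWindow:
    """Closed wavelength interval [lo, hi] in nm (e.g. a hybridization range)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.lo) & (wavelengths <= self.hi)


@dataclass(frozen=True)
class LabColor:
    """CIELAB coordinates used for the ITA° pigmentation index."""

    L_star: float
    b_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError("L* must lie in [0, 100]")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path, kind: str) -> Spectrum:
    """Read a two-column delimited spectrum file.

    Accepts comma or tab delimiters (auto-detected), an optional header
    line, ``#`` comment lines and UTF-8 text with '.' decimals.  Rows are
    sorted by wavelength; duplicate wavelengths are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    wl: list[float] = []
    vals: list[float] = []
    seen_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        delim = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise SpectrumError(f"{path}:{lineno}: expected two columns")
        try:
            w = float(parts[0])
            v = float(parts[1])
        except ValueError:
            if not seen_data:
                continue  # header line
            raise SpectrumError(f"{path}:{lineno}: non-numeric row {line!r}") from None
        seen_data = True
        wl.append(w)
        vals.append(v)
    if not wl:
        raise SpectrumError(f"{path}: no spectral data found")
    order = np.argsort(wl)
    wl_arr = np.asarray(wl, dtype=float)[order]
    vals_arr = np.asarray(vals, dtype=float)[order]
    if np.any(np.diff(wl_arr) == 0):
        dupes = wl_arr[:-1][np.diff(wl_arr) == 0]
        raise SpectrumError(f"{path}: duplicate wavelength(s) {sorted(set(dupes))}")
    return Spectrum(wl_arr, vals_arr, kind)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV (wavelength_nm, value)."""
    path = Path(path)
    lines = ["wavelength_nm,value"]
    lines += [f"{w:g},{v:.10g}" for w, v in zip(spectrum.wavelengths, spectrum.values)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------

def resample(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    The grid must lie within the support of ``s``; no extrapolation.
    Values at grid points already present in the source are exact.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise SpectrumError("empty resampling grid")
    if grid.min() < s.wavelengths[0] or grid.max() > s.wavelengths[-1]:
        raise SpectrumError(
            "resampling grid "
            f"[{grid.min():g}, {grid.max():g}] outside spectrum support "
            f"[{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}]"
        )
    vals = np.interp(grid, s.wavelengths, s.values)
    return Spectrum(grid, vals, s.kind)


def drs_absorbance(r_protected: Spectrum, r_bare: Spectrum) -> Spectrum:
    """In vivo absorbance from protected and bare-skin reflectance.

    ``T(λ) = R(λ)/R0(λ)`` and ``A_DRS(λ) = -log10 T(λ)``.  Points where
    R exceeds R0 (noise) yield small negative absorbance and are kept;
    clipping happens only at protection-factor integration time.
    """
    if r_protected.kind != "reflectance" or r_bare.kind != "reflectance":
        raise SpectrumError("drs_absorbance requires two reflectance spectra")
    if not r_protected.same_grid(r_bare):
        raise GridMismatchError("reflectance spectra are on different grids")
    if np.any(r_bare.values <= 0):
        raise SpectrumError("bare-skin reflectance contains zero values")
    t = r_protected.values / r_bare.values
    if np.any(t <= 0):
        raise SpectrumError("non-positive transmission ratio")
    a = -np.log10(t)
    a = np.maximum(a, _ABSORBANCE_FLOOR)  # tolerate noise-induced negatives
    return Spectrum(r_protected.wavelengths, a, "absorbance")


def average_spectra(spectra: Iterable[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of same-kind, same-grid spectra.

    Used e.g. for the 10 bare-skin reflectance replicates taken per site.
    """
    spectra = list(spectra)
    if not spectra:
        raise SpectrumError("cannot average an empty list of spectra")
    first = spectra[0]
    for s in spectra[1:]:
        if s.kind != first.kind:
            raise SpectrumError("cannot average spectra of mixed kinds")
        if not s.same_grid(first):
            raise GridMismatchError("cannot average spectra on different grids")
    stacked = np.vstack([s.values for s in spectra])
    return Spectrum(first.wavelengths, stacked.mean(axis=0), first.kind)


# ---------------------------------------------------------------------------
# ITA° screening
# ---------------------------------------------------------------------------

def ita_degrees(c: LabColor) -> float:
    """Individual typological angle ITA° = arctan((L* − 50)/b*)·180/π."""
    if c.b_star == 0:
        raise ValueError("ITA undefined for b* = 0")
    return math.degrees(math.atan((c.L_star - 50.0) / c.b_star))


#: ITA below which a volunteer is excluded (too pigmented for DRS signal).
ITA_EXCLUSION_DEG = 28.0
#: Maximum tolerated ITA spread within one measurement field.
ITA_SITE_SPREAD_DEG = 5.0
#: Target range for the panel-average ITA.
ITA_PANEL_RANGE = (41.0, 55.0)


@dataclass
class PanelScreeningReport:
    """Outcome of ITA°-based volunteer/site screening."""

    excluded_volunteers: list[int] = field(default_factory=list)
    excluded_sites: list[int] = field(default_factory=list)
    panel_mean_ita: float = float("nan")
    panel_mean_in_range: bool = False
    n_retained: int = 0


def screen_panel_ita(
    itas_per_site: Sequence[float],
    within_site_spread: Sequence[float] | None = None,
    *,
    exclusion_deg: float = ITA_EXCLUSION_DEG,
    max_spread_deg: float = ITA_SITE_SPREAD_DEG,
    panel_range: tuple[float, float] = ITA_PANEL_RANGE,
) -> PanelScreeningReport:
    """Screen a volunteer panel on ITA° criteria.

    Volunteers with ITA below ``exclusion_deg`` are excluded; sites whose
    within-field ITA spread exceeds ``max_spread_deg`` (strictly — a spread
    equal to the limit passes) are excluded; the report states whether the
    mean ITA of retained volunteers falls within ``panel_range``.
    """
    itas = np.asarray(itas_per_site, dtype=float)
    if itas.size == 0:
        raise ValueError("screening requires at least one volunteer")
    spreads = (
        np.zeros_like(itas)
        if within_site_spread is None
        else np.asarray(within_site_spread, dtype=float)
    )
    if spreads.shape != itas.shape:
        raise ValueError("spread array must match volunteer array")
    report = PanelScreeningReport()
    keep = np.ones(itas.size, dtype=bool)
    for i, (ita, spread) in enumerate(zip(itas, spreads)):
        if ita < exclusion_deg:
            report.excluded_volunteers.append(i)
            keep[i] = False
        if spread > max_spread_deg:
            report.excluded_sites.append(i)
            keep[i] = False
    retained = itas[keep]
    report.n_retained = int(keep.sum())
    if retained.size:
        report.panel_mean_ita = float(retained.mean())
        report.panel_mean_in_range = bool(
            panel_range[0] <= report.panel_mean_ita <= panel_range[1]
        )
    return report
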