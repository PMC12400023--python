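"""Protection factors: SPF / UVA-PF integrals, calibration and panel stats.

From a (hybrid) absorbance spectrum ``A(λ)`` the protection factors are
ratios of action-spectrum-weighted source integrals on a 1 nm grid:

    SPF    = Σ E(λ) S(λ) Δλ / Σ E(λ) S(λ) 10^(−A(λ)) Δλ   over 290–400 nm
    UVA-PF = Σ P(λ) S(λ) Δλ / Σ P(λ) S(λ) 10^(−A(λ)) Δλ   over 320–400 nm

with ``E`` the erythema and ``P`` the PPD action spectrum and ``S`` the
source irradiance.  Negative absorbance (noise) is clipped to zero at
integration time only.

A device calibration maps the raw per-volunteer factor to the reference
scale.  The default reading is a power law, ``pf_cal = pf_raw^c_led ·
e^b``, with the exponent fitted against the reference method
(0.8695 for the legacy configuration, 0.9174 for the re-evaluation
configuration) and ``b = 0.164`` the overall ln-bias correction.  The
ISO-style multiplication factor ``C_Cal(pf) = pf^(c_led−1) · e^b`` is
exposed for reporting, and a pure multiplicative mode is available.

Panel aggregation is on the ln scale (geometric mean) with a t-based
dispersion statistic ``c`` (% half-width of the 95 % CI of the mean),
flagged when it exceeds 17 %.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from . import actionspectra
from .spectral import Spectrum, SpectrumError, WavelengthWindow, resample

__all__ = [
    "ActionWeighting",
    "CalibrationModel",
    "ProtectionResult",
    "compute_spf",
    "compute_uvapf",
    "apply_calibration",
    "calibration_factor",
    "aggregate_panel",
    "check_standard_acceptance",
    "STANDARD_ACCEPTANCE_RANGES",
    "C_LED_STUDY1_LEGACY",
    "C_LED_STUDY2",
    "BIAS_B_DEFAULT",
]

#: Calibration exponent of the legacy configuration (linear-in-T correction).
C_LED_STUDY1_LEGACY = 0.8695
#: Calibration exponent of the re-evaluation configuration.
C_LED_STUDY2 = 0.9174
#: Common overall ln-bias correction for SPF and UVA-PF.
BIAS_B_DEFAULT = 0.164

#: Panel dispersion statistic threshold (%).
C_STAT_LIMIT_PCT = 17.0


@dataclass(frozen=True)
class ActionWeighting:
    """Action spectra, source irradiance and integration bands."""

    erythema_spectrum: Spectrum
    ppd_spectrum: Spectrum
    source_spectrum: Spectrum
    uva_band: WavelengthWindow = WavelengthWindow(320.0, 400.0)
    full_band: WavelengthWindow = WavelengthWindow(290.0, 400.0)

    @classmethod
    def default(cls, grid: np.ndarray | None = None) -> "ActionWeighting":
        """Packaged weighting on the canonical (or given) grid."""
        return cls(
            erythema_spectrum=actionspectra.erythema_action_spectrum(grid),
            ppd_spectrum=actionspectra.ppd_action_spectrum(grid),
            source_spectrum=actionspectra.ssr_source_spectrum(grid),
        )


def _weighted_pf(
    a: Spectrum, weight: Spectrum, source: Spectrum, band: WavelengthWindow
) -> float:
    wl = a.wavelengths
    if wl[0] > band.lo or wl[-1] < band.hi:
        raise SpectrumError(
            f"absorbance spectrum does not cover [{band.lo:g}, {band.hi:g}] nm"
        )
    mask = band.mask(wl)
    grid = wl[mask]
    w = resample(weight, grid).values
    s = resample(source, grid).values
    a_clipped = np.maximum(a.values[mask], 0.0)
    num = float(np.sum(w * s))
    den = float(np.sum(w * s * 10.0 ** (-a_clipped)))
    return num / den


def compute_spf(a: Spectrum, w: ActionWeighting | None = None) -> float:
    """Erythema-weighted protection factor over the full UV band."""
    w = w or ActionWeighting.default(a.wavelengths)
    return _weighted_pf(a, w.erythema_spectrum, w.source_spectrum, w.full_band)


def compute_uvapf(a: Spectrum, w: ActionWeighting | None = None) -> float:
    """PPD-weighted protection factor over the UVA band."""
    w = w or ActionWeighting.default(a.wavelengths)
    return _weighted_pf(a, w.ppd_spectrum, w.source_spectrum, w.uva_band)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationModel:
    """Device calibration: power-law exponent and ln-bias correction.

    ``mode`` selects the reading of the fit: ``"power_law"`` (default)
    calibrates as ``pf^c_led · e^b``; ``"multiplicative"`` as
    ``pf · c_led · e^b``.
    """

    c_led: float = C_LED_STUDY2
    bias_b: float = BIAS_B_DEFAULT
    mode: str = "power_law"

    def __post_init__(self) -> None:
        if not 0.0 < self.c_led < 2.0:
            raise ValueError("c_led must lie in (0, 2)")
        if not math.isfinite(self.bias_b):
            raise ValueError("bias_b must be finite")
        if self.mode not in ("power_law", "multiplicative"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")

    @classmethod
    def study1_legacy(cls, bias_b: float = 0.0) -> "CalibrationModel":
        """Legacy configuration (no bias correction by default)."""
        return cls(c_led=C_LED_STUDY1_LEGACY, bias_b=bias_b)

    @classmethod
    def study2(cls) -> "CalibrationModel":
        """Re-evaluation configuration with the common bias correction."""
        return cls(c_led=C_LED_STUDY2, bias_b=BIAS_B_DEFAULT)


def apply_calibration(pf_raw: float, cal: CalibrationModel) -> float:
    """Calibrated protection factor for one volunteer."""
    if pf_raw < 1.0:
        raise ValueError("raw protection factor must be >= 1")
    if cal.mode == "multiplicative":
        return pf_raw * cal.c_led * math.exp(cal.bias_b)
    return pf_raw**cal.c_led * math.exp(cal.bias_b)


def calibration_factor(pf_raw: float, cal: CalibrationModel) -> float:
    """ISO-style multiplication factor C_Cal = pf_cal / pf_raw."""
    return apply_calibration(pf_raw, cal) / pf_raw


# ---------------------------------------------------------------------------
# Panel aggregation
# ---------------------------------------------------------------------------

@dataclass
class VolunteerResult:
    volunteer_id: str
    spf_hdrsi: float
    uvapf_hdrsi: float
    uvapf_drs: float = float("nan")


@dataclass
class PanelStatistic:
    """Geometric-mean panel value with a t-based dispersion statistic."""

    value: float
    c_stat_pct: float
    n: int
    flagged: bool


@dataclass
class ProtectionResult:
    per_volunteer: list[VolunteerResult]
    panel_spf: PanelStatistic
    panel_uvapf: PanelStatistic

    def to_dict(self) -> dict:
        return {
            "per_volunteer": [
                {
                    "volunteer_id": v.volunteer_id,
                    "spf_hdrsi": v.spf_hdrsi,
                    "uvapf_hdrsi": v.uvapf_hdrsi,
                    "uvapf_drs": v.uvapf_drs,
                }
                for v in self.per_volunteer
            ],
            "panel_spf": vars(self.panel_spf),
            "panel_uvapf": vars(self.panel_uvapf),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def panel_statistic(
    values: Sequence[float], confidence: float = 0.95
) -> PanelStatistic:
    """Geometric mean and ln-scale t-CI dispersion of per-volunteer PFs.

    The panel value is ``exp(mean ln PF)``.  The statistic ``c`` is the
    half-width of the two-sided t confidence interval of the mean ln PF,
    expressed as a percentage of the panel mean on the PF scale
    (``100 · (e^hw − 1)``), flagged when above 17 %.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("panel statistics require at least 2 volunteers")
    if np.any(vals <= 0):
        raise ValueError("protection factors must be positive")
    ln = np.log(vals)
    n = ln.size
    mean_ln = ln.mean()
    sd_ln = ln.std(ddof=1)
    t = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    hw = t * sd_ln / math.sqrt(n)
    c_pct = 100.0 * (math.exp(hw) - 1.0)
    return PanelStatistic(
        value=float(math.exp(mean_ln)),
        c_stat_pct=float(c_pct),
        n=n,
        flagged=bool(c_pct > C_STAT_LIMIT_PCT),
    )


def aggregate_panel(
    results: Sequence[VolunteerResult], confidence: float = 0.95
) -> ProtectionResult:
    """Aggregate per-volunteer results to panel level (geometric means)."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("panel aggregation requires at least 2 volunteers")
    return ProtectionResult(
        per_volunteer=results,
        panel_spf=panel_statistic([r.spf_hdrsi for r in results], confidence),
        panel_uvapf=panel_statistic([r.uvapf_hdrsi for r in results], confidence),
    )


# ---------------------------------------------------------------------------
# Standard-sunscreen acceptance ranges
# ---------------------------------------------------------------------------

#: Published panel-average SPF acceptance ranges for reference sunscreens.
#: Only the ranges with public worked examples ship here; extend via the
#: ``table`` argument for further standards (e.g. P6, S2).
STANDARD_ACCEPTANCE_RANGES: dict[str, tuple[float, float]] = {
    "P5": (23.7, 37.4),
    "P8": (43.9, 82.3),
}


@dataclass(frozen=True)
class AcceptanceCheck:
    standard_id: str
    value: float
    lo: float
    hi: float
    passed: bool
    margin: float  # distance to the nearer bound; negative when outside


def check_standard_acceptance(
    panel_pf: float,
    standard_id: str,
    table: dict[str, tuple[float, float]] | None = None,
) -> AcceptanceCheck:
    """Check a panel protection factor against a standard's range.

    Bounds are inclusive; ``margin`` reports the distance to the nearer
    bound (negative if the value lies outside the range).
    """
    table = table if table is not None else STANDARD_ACCEPTANCE_RANGES
    if standard_id not in table:
        raise KeyError(f"unknown standard sunscreen {standard_id!r}")
    lo, hi = table[standard_id]
    passed = lo <= panel_pf <= hi
    margin = min(panel_pf - lo, hi - panel_pf)
    return AcceptanceCheck(standard_id, panel_pf, lo, hi, passed, margin)
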