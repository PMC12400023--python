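"""Spectral hybridization of in vivo DRS and in vitro film absorbance.

At safe in vivo doses the UVB part of the skin spectrum cannot be measured,
so the pre-exposure in vitro absorbance spectrum of the product film
(``Avt0``) is scaled to the in vivo DRS absorbance (``A_DRS``) over a
hybridization window — default 320–345 nm, the range of maximal LED
irradiance — and replaces the in vivo spectrum below the window:

    hybrid(λ) = c_Ai · Avt0(λ)   for λ < window.lo
    hybrid(λ) = A_DRS(λ)         for λ >= window.lo

The scaling factor ``c_Ai`` absorbs the in vivo/in vitro pathlength
mismatch.  The default estimator is the ratio of window means; a
mean-of-pointwise-ratios variant is available for sensitivity analysis.
The splice is intentionally allowed to step at ``window.lo``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import GridMismatchError, Spectrum, SpectrumError, WavelengthWindow

__all__ = [
    "HybridizationResult",
    "DEFAULT_WINDOW",
    "LEGACY_WINDOW",
    "hybridization_scale",
    "hybridize",
    "window_signal_check",
    "WindowSignalReport",
]

#: Hybridization window of the re-evaluation configuration (nm).
DEFAULT_WINDOW = WavelengthWindow(320.0, 345.0)
#: Original narrower window used in the first ring study (nm).
LEGACY_WINDOW = WavelengthWindow(320.0, 330.0)

_ESTIMATORS = ("ratio_of_means", "mean_of_ratios")


@dataclass(frozen=True)
class HybridizationResult:
    """Scaled in vitro spectrum and the spliced hybrid absorbance."""

    scale_factor: float
    scaled_vitro: Spectrum
    hybrid_uncorrected: Spectrum
    window: WavelengthWindow
    mean_window_absorbance: float


def _check_inputs(a_drs: Spectrum, a_vt0: Spectrum) -> None:
    if a_drs.kind != "absorbance" or a_vt0.kind != "absorbance":
        raise SpectrumError("hybridization requires absorbance spectra")
    if not a_drs.same_grid(a_vt0):
        raise GridMismatchError("in vivo and in vitro spectra on different grids")


def hybridization_scale(
    a_drs: Spectrum,
    a_vt0: Spectrum,
    window: WavelengthWindow = DEFAULT_WINDOW,
    estimator: str = "ratio_of_means",
) -> float:
    """Scaling factor c_Ai matching Avt0 to A_DRS over the window.

    ``ratio_of_means`` (default): mean(A_DRS)/mean(Avt0) over the window,
    robust to low-signal points near the short-wavelength edge.
    ``mean_of_ratios``: mean of pointwise A_DRS/Avt0.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    _check_inputs(a_drs, a_vt0)
    mask = window.mask(a_drs.wavelengths)
    if mask.sum() < 3:
        raise SpectrumError(
            f"hybridization window [{window.lo:g}, {window.hi:g}] "
            f"contains {int(mask.sum())} grid points (need >= 3)"
        )
    vivo = a_drs.values[mask]
    vitro = a_vt0.values[mask]
    if vitro.mean() <= 0:
        raise SpectrumError("in vitro spectrum has non-positive window mean")
    if estimator == "ratio_of_means":
        c = vivo.mean() / vitro.mean()
    else:
        if np.any(vitro <= 0):
            raise SpectrumError("mean_of_ratios requires positive in vitro values")
        c = float(np.mean(vivo / vitro))
    if c <= 0:
        raise SpectrumError(f"non-positive scaling factor c_Ai = {c:g}")
    return float(c)


def hybridize(
    a_drs: Spectrum,
    a_vt0: Spectrum,
    window: WavelengthWindow = DEFAULT_WINDOW,
    estimator: str = "ratio_of_means",
) -> HybridizationResult:
    """Build the hybrid absorbance spectrum on the common grid.

    The in vitro spectrum must cover down to 290 nm (the UVB part it
    supplies) and the in vivo spectrum must cover the window and above.
    """
    _check_inputs(a_drs, a_vt0)
    wl = a_drs.wavelengths
    if wl[0] > window.lo or wl[-1] < window.hi:
        raise SpectrumError(
            "spectra do not cover the hybridization window "
            f"[{window.lo:g}, {window.hi:g}] nm"
        )
    c = hybridization_scale(a_drs, a_vt0, window, estimator)
    scaled_values = c * a_vt0.values
    below = wl < window.lo
    hybrid_values = np.where(below, scaled_values, a_drs.values)
    mask = window.mask(wl)
    # Scaled values may dip slightly negative where Avt0 had noise floor;
    # the Spectrum invariant tolerance covers that.
    scaled = Spectrum(wl, np.maximum(scaled_values, -0.05), "absorbance")
    hybrid = Spectrum(wl, np.maximum(hybrid_values, -0.05), "absorbance")
    return HybridizationResult(
        scale_factor=c,
        scaled_vitro=scaled,
        hybrid_uncorrected=hybrid,
        window=window,
        mean_window_absorbance=float(a_drs.values[mask].mean()),
    )


@dataclass(frozen=True)
class WindowSignalReport:
    """Low-signal diagnostics for the hybridization window."""

    flagged_wavelengths: np.ndarray
    usable_fraction: float
    noise_floor: float


def window_signal_check(
    a_drs: Spectrum,
    r_protected: Spectrum,
    window: WavelengthWindow = DEFAULT_WINDOW,
    noise_floor: float = 1e-3,
) -> WindowSignalReport:
    """Flag window grid points where detected reflectance is below a floor.

    Low reflected signal near the short-wavelength window edge makes the
    scaling factor unstable; the report gives the fraction of usable
    window points so a wider window or site exclusion can be considered.
    """
    mask = window.mask(r_protected.wavelengths)
    wl = r_protected.wavelengths[mask]
    refl = r_protected.values[mask]
    flagged = wl[refl < noise_floor]
    usable = 1.0 if wl.size == 0 else 1.0 - flagged.size / wl.size
    return WindowSignalReport(
        flagged_wavelengths=flagged,
        usable_fraction=float(usable),
        noise_floor=noise_floor,
    )
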