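"""Action spectra and source irradiance used in protection-factor integrals.

Three weighting functions enter the SPF / UVA-PF integrals:

* ``erythema_action_spectrum`` — the CIE erythema reference action
  spectrum in its closed form (weight 1 at and below 298 nm).
* ``ppd_action_spectrum`` — persistent pigment darkening (PPD) weighting
  for UVA-PF.  The normative table is not redistributable, so the
  packaged curve is a synthetic smooth stand-in with the accepted shape
  (unity at 320 nm, slow log-linear decline through the UVA); replace it
  via :class:`~hdrskit.protection.ActionWeighting` for normative work.
* ``ssr_source_spectrum`` — a synthetic solar-simulator (SSR-like) UV
  irradiance: steeply rising through the UVB, flat plateau in the UVA.
  Any tabulated source can be substituted; all integrals expose the grid
  step explicitly.

All functions evaluate on an arbitrary wavelength grid and return
:class:`~hdrskit.spectral.Spectrum`-compatible arrays.
"""

from __future__ import annotations

import numpy as np

from .spectral import CANONICAL_GRID, Spectrum

__all__ = [
    "erythema_action_spectrum",
    "ppd_action_spectrum",
    "ssr_source_spectrum",
]


def erythema_weights(wavelengths: np.ndarray) -> np.ndarray:
    """CIE erythema action spectrum, closed form.

    weight = 1                      for λ <= 298 nm
    weight = 10^(0.094 (298 − λ))   for 298 < λ <= 328 nm
    weight = 10^(0.015 (140 − λ))   for 328 < λ <= 400 nm
    """
    wl = np.asarray(wavelengths, dtype=float)
    w = np.ones_like(wl)
    mid = (wl > 298.0) & (wl <= 328.0)
    far = wl > 328.0
    w[mid] = 10.0 ** (0.094 * (298.0 - wl[mid]))
    w[far] = 10.0 ** (0.015 * (140.0 - wl[far]))
    return w


def erythema_action_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """CIE erythema action spectrum as a Spectrum on ``grid``."""
    wl = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(wl, erythema_weights(wl), "ratio")


def ppd_weights(wavelengths: np.ndarray) -> np.ndarray:
    """Synthetic PPD action-spectrum stand-in (unity at 320 nm).

    Log-linear decline of 0.5 decades across 320–400 nm, matching the
    gentle long-wavelength roll-off of published PPD weightings.  Weights
    below 320 nm are held at 1 (UVA-PF integrals never use them).
    """
    wl = np.asarray(wavelengths, dtype=float)
    w = 10.0 ** (-0.00625 * np.clip(wl - 320.0, 0.0, None))
    return w


def ppd_action_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Synthetic PPD action spectrum as a Spectrum on ``grid``."""
    wl = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(wl, ppd_weights(wl), "ratio")


def ssr_weights(wavelengths: np.ndarray) -> np.ndarray:
    """Synthetic SSR-like relative spectral irradiance (unit plateau).

    Below 400 nm real simulators fall by roughly four decades between the
    UVA plateau and 290 nm; modelled here as a smooth log-quadratic rise
    from 290 to 340 nm followed by a flat plateau.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = np.clip((340.0 - wl) / 50.0, 0.0, None)  # 1 at 290 nm, 0 above 340
    log10_s = -4.0 * x**2
    return 10.0**log10_s


def ssr_source_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Synthetic solar-simulator source spectrum as a Spectrum on ``grid``."""
    wl = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(wl, ssr_weights(wl), "ratio")
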