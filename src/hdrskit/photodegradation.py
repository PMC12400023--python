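"""Photodegradation assessment and correction of the hybrid spectrum.

Sunscreen films on PMMA plates are measured before (``Avt0``) and after
(``Avt1``) a UV exposure whose dose is proportional to the product's
UVA-PF.  The spectral ratio of photodegradation

    srpd(λ) = 10^(−Avt0(λ)) / 10^(−Avt1(λ)) = 10^(Avt1(λ) − Avt0(λ))

is the pre/post transmission ratio: it is <= 1 wherever absorbance
decreased (genuine degradation) and the product counts as photostable
when the band summaries over UVB and UVA both exceed 0.8.

Two correction modes are provided:

* ``linear_in_T`` — the transmission-domain correction applied uniformly:
  ``A_HDRS(λ) = A_HDRS0(λ) + (Avt1(λ) − Avt0(λ))``, a translation in
  absorbance (used in the first ring study).
* ``case_dependent_absorbance`` — a multiplicative absorbance factor
  ``g(λ)`` chosen by stability class (the standardized style); the
  default strategy is ``g = clip(srpd, threshold, 1)``, reflecting the
  observation that degradation beyond srpd = 0.8 does not reduce
  corrected results further.  Custom ``g``-functions can be plugged in.

Both modes are the identity when no degradation occurred, and neither can
raise the protection factor under genuine degradation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .actionspectra import ssr_weights
from .hybridization import HybridizationResult
from .spectral import GridMismatchError, Spectrum, SpectrumError

__all__ = [
    "PhotodegradationAssessment",
    "CorrectionPolicy",
    "UVB_BAND",
    "UVA_BAND",
    "compute_srpd",
    "apply_linear_T_correction",
    "apply_case_dependent_correction",
    "apply_correction",
    "irradiation_dose",
]

#: UVB band for the srpd summary (upper edge exclusive).
UVB_BAND = (290.0, 320.0)
#: UVA band for the srpd summary (inclusive).
UVA_BAND = (320.0, 400.0)

#: Stability threshold on the band srpd summaries.
DEFAULT_THRESHOLD = 0.8

STABILITY_CLASSES = ("stable", "moderately_unstable", "strongly_unstable")


@dataclass(frozen=True)
class PhotodegradationAssessment:
    """Per-wavelength srpd plus band summaries and a stability class."""

    srpd: Spectrum
    srpd_uva: float
    srpd_uvb: float
    stability_class: str
    anomalous: bool = False  # srpd > 1 somewhere (post-exposure gain)


@dataclass(frozen=True)
class CorrectionPolicy:
    """Which correction to apply and its stability threshold."""

    mode: str = "case_dependent_absorbance"
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("linear_in_T", "case_dependent_absorbance", "none"):
            raise ValueError(f"unknown correction mode {self.mode!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")


def _band_mean(
    wl: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float],
    *,
    upper_inclusive: bool,
    weights: np.ndarray | None,
) -> float:
    lo, hi = band
    mask = (wl >= lo) & ((wl <= hi) if upper_inclusive else (wl < hi))
    if not mask.any():
        return float("nan")
    w = (ssr_weights(wl) if weights is None else weights)[mask]
    if w.sum() <= 0:
        w = np.ones(mask.sum())
    return float(np.average(values[mask], weights=w))


def compute_srpd(
    a_vt0: Spectrum,
    a_vt1: Spectrum,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    source_weights: np.ndarray | None = None,
) -> PhotodegradationAssessment:
    """Spectral ratio of photodegradation and its stability classification.

    Band summaries are source-weighted means of srpd over UVB [290, 320)
    and UVA [320, 400]; the default weighting is the packaged simulator
    spectrum.  The product is *stable* when both summaries exceed
    ``threshold``; *moderately unstable* when the smaller summary is
    within 0.2 of it; *strongly unstable* otherwise.
    """
    if a_vt0.kind != "absorbance" or a_vt1.kind != "absorbance":
        raise SpectrumError("compute_srpd requires absorbance spectra")
    if not a_vt0.same_grid(a_vt1):
        raise GridMismatchError("pre/post in vitro spectra on different grids")
    wl = a_vt0.wavelengths
    ratio = 10.0 ** (a_vt1.values - a_vt0.values)
    uvb = _band_mean(wl, ratio, UVB_BAND, upper_inclusive=False, weights=source_weights)
    uva = _band_mean(wl, ratio, UVA_BAND, upper_inclusive=True, weights=source_weights)
    worst = np.nanmin([uvb, uva])
    if uvb > threshold and uva > threshold:
        stability = "stable"
    elif worst > threshold - 0.2:
        stability = "moderately_unstable"
    else:
        stability = "strongly_unstable"
    anomalous = bool(np.any(ratio > 1.0))
    if np.any(ratio > 1.05):
        warnings.warn(
            "srpd exceeds 1.05 at some wavelengths (post-exposure absorbance gain)",
            stacklevel=2,
        )
    srpd = Spectrum(wl, np.clip(ratio, 1e-12, None), "ratio")
    return PhotodegradationAssessment(
        srpd=srpd,
        srpd_uva=uva,
        srpd_uvb=uvb,
        stability_class=stability,
        anomalous=anomalous,
    )


def apply_linear_T_correction(
    hybrid: HybridizationResult,
    assessment: PhotodegradationAssessment,
) -> Spectrum:
    """Transmission-domain correction: subtract the absorbance loss.

    ``A_HDRS = A_HDRS0 + (Avt1 − Avt0) = A_HDRS0 + log10(srpd)``; the
    correction lowers absorbance wherever degradation occurred and is
    floored at zero absorbance.
    """
    a0 = hybrid.hybrid_uncorrected
    if not a0.same_grid(assessment.srpd):
        raise GridMismatchError("hybrid and srpd spectra on different grids")
    corrected = a0.values + np.log10(assessment.srpd.values)
    return Spectrum(a0.wavelengths, np.maximum(corrected, 0.0), "absorbance")


GFunction = Callable[[np.ndarray, PhotodegradationAssessment, CorrectionPolicy], np.ndarray]


def default_g_function(
    srpd: np.ndarray,
    assessment: PhotodegradationAssessment,
    policy: CorrectionPolicy,
) -> np.ndarray:
    """Default multiplicative absorbance factor: clip(srpd, threshold, 1)."""
    return np.clip(srpd, policy.threshold, 1.0)


def apply_case_dependent_correction(
    hybrid: HybridizationResult,
    assessment: PhotodegradationAssessment,
    policy: CorrectionPolicy | None = None,
    g_function: GFunction | None = None,
) -> Spectrum:
    """Absorbance-domain correction ``A_HDRS = g(λ) · A_HDRS0``.

    ``g`` defaults to :func:`default_g_function`; supply a custom strategy
    to reproduce alternative stability-class equation sets.
    """
    policy = policy or CorrectionPolicy()
    if policy.mode == "linear_in_T":
        raise ValueError("policy mode is linear_in_T; use apply_linear_T_correction")
    a0 = hybrid.hybrid_uncorrected
    if not a0.same_grid(assessment.srpd):
        raise GridMismatchError("hybrid and srpd spectra on different grids")
    g = (g_function or default_g_function)(assessment.srpd.values, assessment, policy)
    corrected = np.maximum(a0.values, 0.0) * g
    return Spectrum(a0.wavelengths, np.maximum(corrected, 0.0), "absorbance")


def apply_correction(
    hybrid: HybridizationResult,
    assessment: PhotodegradationAssessment,
    policy: CorrectionPolicy,
) -> Spectrum:
    """Dispatch on the policy mode (``none`` returns the uncorrected hybrid)."""
    if policy.mode == "none":
        return hybrid.hybrid_uncorrected
    if policy.mode == "linear_in_T":
        return apply_linear_T_correction(hybrid, assessment)
    return apply_case_dependent_correction(hybrid, assessment, policy)


#: Exposure dose per unit UVA-PF for the in vitro irradiation (J/cm²).
DEFAULT_DOSE_PER_UNIT = 1.2


def irradiation_dose(
    uvapf_drs: float, dose_per_unit: float = DEFAULT_DOSE_PER_UNIT
) -> float:
    """In vitro irradiation dose in J/cm², proportional to UVA-PF_DRS.

    No reference SPF is available to scale the in vitro spectra, so the
    UVA-PF computed from the in vivo DRS spectrum sets the dose.
    """
    if uvapf_drs < 1.0:
        raise ValueError("UVA-PF_DRS must be >= 1")
    if dose_per_unit == 0:
        warnings.warn("dose_per_unit is 0: zero irradiation dose", stacklevel=2)
    return dose_per_unit * uvapf_drs
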