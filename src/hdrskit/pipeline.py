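"""End-to-end processing: manifest of raw spectra → panel protection factors.

For each (lab, product, duplicate, volunteer) measurement set the chain is

    R0, R  →  A_DRS = −log10(R/R0)
    A_DRS, Avt0  →  hybrid spectrum (scaled splice at the window edge)
    Avt0, Avt1   →  srpd → photodegradation-corrected hybrid
    corrected hybrid  →  SPF_HDRSi, UVA-PF_HDRSi  →  calibration
    per-volunteer values  →  ln-scale panel aggregation

The run configuration bundles the hybridization window/estimator, the
correction policy and the calibration model; the two published study
configurations are available as presets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hybridization import DEFAULT_WINDOW, LEGACY_WINDOW, hybridize
from .photodegradation import CorrectionPolicy, apply_correction, compute_srpd
from .protection import (
    ActionWeighting,
    CalibrationModel,
    VolunteerResult,
    aggregate_panel,
    apply_calibration,
    compute_spf,
    compute_uvapf,
)
from .spectral import WavelengthWindow, drs_absorbance, read_spectrum, resample

__all__ = ["RunConfig", "process_measurement", "process_manifest"]


@dataclass
class RunConfig:
    """Resolved configuration of one processing run."""

    window_lo: float = DEFAULT_WINDOW.lo
    window_hi: float = DEFAULT_WINDOW.hi
    estimator: str = "ratio_of_means"
    photodeg_mode: str = "case_dependent_absorbance"
    photodeg_threshold: float = 0.8
    dose_per_unit: float = 1.2
    c_led: float = 0.9174
    bias_b: float = 0.164
    calibration_mode: str = "power_law"
    confidence: float = 0.95

    @property
    def window(self) -> WavelengthWindow:
        return WavelengthWindow(self.window_lo, self.window_hi)

    @property
    def policy(self) -> CorrectionPolicy:
        return CorrectionPolicy(self.photodeg_mode, self.photodeg_threshold)

    @property
    def calibration(self) -> CalibrationModel:
        return CalibrationModel(self.c_led, self.bias_b, self.calibration_mode)

    @classmethod
    def study1_legacy(cls) -> "RunConfig":
        """First-study configuration: 320–330 nm window, linear-in-T
        correction, C_LED = 0.8695, no bias correction."""
        return cls(
            window_lo=LEGACY_WINDOW.lo,
            window_hi=LEGACY_WINDOW.hi,
            photodeg_mode="linear_in_T",
            c_led=0.8695,
            bias_b=0.0,
        )

    @classmethod
    def study2(cls) -> "RunConfig":
        """Re-evaluation configuration: 320–345 nm window, case-dependent
        correction, C_LED = 0.9174, b = 0.164."""
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )


def process_measurement(
    r0,
    r,
    avt0,
    avt1,
    config: RunConfig,
    weighting: ActionWeighting | None = None,
) -> dict:
    """Process one measurement set to calibrated per-volunteer factors.

    Returns raw and calibrated SPF/UVA-PF, the UVA-PF computed from the
    uncorrected in vivo DRS spectrum (used for the exposure dose), the
    hybridization scale factor and the stability class.
    """
    a_drs = drs_absorbance(r, r0)
    grid = a_drs.wavelengths
    w = weighting or ActionWeighting.default(grid)
    avt0 = avt0 if np.array_equal(avt0.wavelengths, grid) else resample(avt0, grid)
    avt1 = avt1 if np.array_equal(avt1.wavelengths, grid) else resample(avt1, grid)
    hybrid = hybridize(a_drs, avt0, config.window, config.estimator)
    assessment = compute_srpd(avt0, avt1, threshold=config.photodeg_threshold)
    corrected = apply_correction(hybrid, assessment, config.policy)
    spf_raw = compute_spf(corrected, w)
    uvapf_raw = compute_uvapf(corrected, w)
    uvapf_drs = compute_uvapf(a_drs, w)
    cal = config.calibration
    return {
        "spf_raw": spf_raw,
        "uvapf_raw": uvapf_raw,
        "spf_hdrsi": apply_calibration(max(spf_raw, 1.0), cal),
        "uvapf_hdrsi": apply_calibration(max(uvapf_raw, 1.0), cal),
        "uvapf_drs": uvapf_drs,
        "scale_factor": hybrid.scale_factor,
        "stability_class": assessment.stability_class,
    }


def process_manifest(
    manifest_path: str | Path,
    config: RunConfig,
    weighting: ActionWeighting | None = None,
) -> pd.DataFrame:
    """Process every measurement in a manifest CSV and aggregate panels.

    The manifest must have columns ``lab, product, duplicate, volunteer,
    r0_file, r_file, avt0_file, avt1_file`` (paths relative to the
    manifest's directory).  Returns one row per (lab, product, duplicate)
    with panel-level protection factors and per-volunteer counts.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError(f"{manifest_path}: empty manifest")
    required = {
        "lab", "product", "duplicate", "volunteer",
        "r0_file", "r_file", "avt0_file", "avt1_file",
    }
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {sorted(missing)}")

    rows = []
    for (lab, product, duplicate), sub in manifest.groupby(
        ["lab", "product", "duplicate"]
    ):
        volunteers = []
        for _, rec in sub.iterrows():
            spectra = {}
            for key, kind in (
                ("r0_file", "reflectance"),
                ("r_file", "reflectance"),
                ("avt0_file", "absorbance"),
                ("avt1_file", "absorbance"),
            ):
                fpath = base / rec[key]
                if not fpath.exists():
                    raise FileNotFoundError(f"missing spectrum file {fpath}")
                spectra[key] = read_spectrum(fpath, kind)
            res = process_measurement(
                spectra["r0_file"],
                spectra["r_file"],
                spectra["avt0_file"],
                spectra["avt1_file"],
                config,
                weighting,
            )
            volunteers.append(
                VolunteerResult(
                    volunteer_id=str(rec["volunteer"]),
                    spf_hdrsi=res["spf_hdrsi"],
                    uvapf_hdrsi=res["uvapf_hdrsi"],
                    uvapf_drs=res["uvapf_drs"],
                )
            )
        if len(volunteers) >= 2:
            panel = aggregate_panel(volunteers, config.confidence)
            spf_panel = panel.panel_spf.value
            uvapf_panel = panel.panel_uvapf.value
            c_spf = panel.panel_spf.c_stat_pct
            c_uvapf = panel.panel_uvapf.c_stat_pct
        else:
            spf_panel = volunteers[0].spf_hdrsi
            uvapf_panel = volunteers[0].uvapf_hdrsi
            c_spf = c_uvapf = float("nan")
        row = {
            "lab": lab,
            "product": product,
            "duplicate": duplicate,
            "n_volunteers": len(volunteers),
            "spf_hdrs": spf_panel,
            "uvapf_hdrs": uvapf_panel,
            "c_spf_pct": c_spf,
            "c_uvapf_pct": c_uvapf,
        }
        for extra in ("product_group", "panel", "tech_vivo", "tech_vitro"):
            if extra in sub.columns:
                row[extra] = sub.iloc[0][extra]
        rows.append(row)
    return pd.DataFrame(rows)
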