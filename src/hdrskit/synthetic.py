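"""Synthetic paired in vivo / in vitro spectra and ring-study datasets.

Everything the pipeline consumes can be generated here with known ground
truth: product films with target SPF/UVA-PF and a photostability level,
skin baselines parameterized by the ITA° pigmentation index, and complete
balanced ring studies with configurable ln-scale variance components
(persistent lab bias, lab×product, lab×factor, repeatability).

The forward model mirrors the measurement physics the pipeline inverts:

* in vivo: ``R(λ) = R0(λ) · 10^(−A_film(λ)) · (1 + noise)``, so the DRS
  absorbance recovers the film absorbance exactly at zero noise;
* in vitro: ``Avt0(λ) = A_film(λ)/path_scale + noise``; the pathlength
  mismatch ``path_scale`` is exactly what the hybridization scale factor
  absorbs; ``Avt1 = Avt0 · (1 − photostability(λ))`` after exposure.

Randomness uses one root seed spawning per-entity substreams so adding
entities does not perturb existing draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protection import ActionWeighting, compute_spf, compute_uvapf
from .ring import STANDARD_LAYOUT, RingStudyData
from .spectral import CANONICAL_GRID, Spectrum

__all__ = [
    "ProductModel",
    "SkinModel",
    "StudySimConfig",
    "make_product",
    "make_skin",
    "simulate_measurement",
    "simulate_ring_study",
    "write_study_tree",
]


@dataclass(frozen=True)
class ProductModel:
    """Ground-truth sunscreen film: absorbance, photostability, labels."""

    film_absorbance: Spectrum
    photostability: np.ndarray  # fractional absorbance loss per λ, in [0, 1]
    spf_true: float
    uvapf_true: float
    label: str = "product"

    def __post_init__(self) -> None:
        ps = np.asarray(self.photostability, dtype=float)
        object.__setattr__(self, "photostability", ps)
        if ps.shape != self.film_absorbance.wavelengths.shape:
            raise ValueError("photostability must match the film grid")
        if np.any(ps < 0) or np.any(ps > 1):
            raise ValueError("photostability must lie in [0, 1]")


@dataclass(frozen=True)
class SkinModel:
    """Bare-skin UV reflectance baseline parameterized by ITA°."""

    baseline_reflectance: Spectrum
    ita: float
    noise_sd: float = 0.0


class FeasibilityError(ValueError):
    """No film absorbance can reach the requested target pair."""


def _two_bump_absorbance(
    grid: np.ndarray, h_uvb: float, h_uva: float
) -> np.ndarray:
    """Smooth UVB (307 nm) + UVA (355 nm) absorber mix."""
    uvb = np.exp(-0.5 * ((grid - 307.0) / 14.0) ** 2)
    uva = np.exp(-0.5 * ((grid - 355.0) / 30.0) ** 2)
    return h_uvb * uvb + h_uva * uva


def make_product(
    spf_target: float,
    uvapf_target: float | None = None,
    photostability: float | np.ndarray = 0.0,
    label: str = "product",
    *,
    profile: str = "two_bump",
    weighting: ActionWeighting | None = None,
    grid: np.ndarray | None = None,
    rtol: float = 0.01,
) -> ProductModel:
    """Construct a film whose pipeline SPF/UVA-PF hit the targets.

    ``profile="two_bump"`` solves a UVB+UVA absorber mix by alternating
    1-D bisections until both protection factors match within ``rtol``;
    ``profile="flat"`` uses the uniform absorbance ``log10(spf_target)``
    (then UVA-PF equals SPF and ``uvapf_target`` is ignored).
    """
    if spf_target < 1.0 or (uvapf_target is not None and uvapf_target < 1.0):
        raise FeasibilityError("protection-factor targets must be >= 1")
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    w = weighting or ActionWeighting.default(grid)
    ps = np.broadcast_to(
        np.asarray(photostability, dtype=float), grid.shape
    ).copy()

    if profile == "flat":
        a = np.full_like(grid, math.log10(spf_target))
        spec = Spectrum(grid, a, "absorbance")
        return ProductModel(spec, ps, compute_spf(spec, w), compute_uvapf(spec, w), label)
    if profile != "two_bump":
        raise ValueError(f"unknown profile {profile!r}")
    if uvapf_target is None:
        uvapf_target = max(1.0, spf_target / 3.0)

    from scipy.optimize import brentq

    h_uvb, h_uva = 0.5, 0.5
    hi = 12.0  # ~SPF 10^12 flat: generous bracket

    def spf_of(hb: float, ha: float) -> float:
        return compute_spf(Spectrum(grid, _two_bump_absorbance(grid, hb, ha), "absorbance"), w)

    def uvapf_of(hb: float, ha: float) -> float:
        return compute_uvapf(Spectrum(grid, _two_bump_absorbance(grid, hb, ha), "absorbance"), w)

    try:
        for _ in range(60):
            # match UVA-PF with the UVA bump, then SPF with the UVB bump
            f = lambda ha: uvapf_of(h_uvb, ha) - uvapf_target  # noqa: E731
            h_uva = 0.0 if f(0.0) >= 0 else brentq(f, 0.0, hi, xtol=1e-10)
            g = lambda hb: spf_of(hb, h_uva) - spf_target  # noqa: E731
            h_uvb = 0.0 if g(0.0) >= 0 else brentq(g, 0.0, hi, xtol=1e-10)
            spf = spf_of(h_uvb, h_uva)
            uvapf = uvapf_of(h_uvb, h_uva)
            if (
                abs(spf - spf_target) <= rtol * spf_target
                and abs(uvapf - uvapf_target) <= rtol * uvapf_target
            ):
                break
        else:
            raise FeasibilityError(
                f"targets (SPF {spf_target}, UVA-PF {uvapf_target}) did not "
                f"converge (reached {spf:.2f}, {uvapf:.2f})"
            )
    except ValueError as exc:  # brentq bracket failure
        raise FeasibilityError(
            f"infeasible target pair (SPF {spf_target}, UVA-PF {uvapf_target}): {exc}"
        ) from exc
    if abs(spf - spf_target) > rtol * spf_target or abs(uvapf - uvapf_target) > rtol * uvapf_target:
        raise FeasibilityError(
            f"infeasible target pair (SPF {spf_target}, UVA-PF {uvapf_target}); "
            f"closest achievable ({spf:.2f}, {uvapf:.2f})"
        )
    spec = Spectrum(grid, _two_bump_absorbance(grid, h_uvb, h_uva), "absorbance")
    return ProductModel(spec, ps, spf, uvapf, label)


def make_skin(
    ita: float,
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
) -> SkinModel:
    """Simple melanin-slope skin baseline: lighter skin reflects more UV.

    ``R0(λ) = r_base(ita) · (1 + 0.004 (λ − 290))`` with the base level
    rising linearly in ITA; only the monotone ITA→reflectance relation is
    modelled (it drives the low-signal behaviour of dark-skin windows).
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    r_base = float(np.clip(0.04 + 0.004 * ita, 0.005, 0.5))
    r0 = np.clip(r_base * (1.0 + 0.004 * (grid - 290.0)), 1e-4, 0.95)
    return SkinModel(Spectrum(grid, r0, "reflectance"), ita, noise_sd)


def simulate_measurement(
    product: ProductModel,
    skin: SkinModel,
    degrade: bool = False,
    seed: int | np.random.SeedSequence | None = None,
    path_scale: float = 1.0,
    plate_noise_sd: float = 0.0,
) -> tuple[Spectrum, Spectrum, Spectrum, Spectrum]:
    """Forward-simulate one measurement set ``(R0, R, Avt0, Avt1)``.

    At zero noise and ``path_scale = 1`` the full pipeline recovers the
    ground-truth protection factors exactly.
    """
    rng = np.random.default_rng(seed)
    grid = product.film_absorbance.wavelengths
    r0 = skin.baseline_reflectance
    if not np.array_equal(r0.wavelengths, grid):
        raise ValueError("skin and product grids differ")
    mult_noise = (
        1.0 + rng.normal(0.0, skin.noise_sd, size=grid.shape)
        if skin.noise_sd > 0
        else 1.0
    )
    r_vals = r0.values * 10.0 ** (-product.film_absorbance.values) * mult_noise
    r = Spectrum(grid, np.clip(r_vals, 0.0, 1.0), "reflectance")
    avt0_vals = product.film_absorbance.values / path_scale
    if plate_noise_sd > 0:
        avt0_vals = avt0_vals + rng.normal(0.0, plate_noise_sd, size=grid.shape)
    avt0_vals = np.maximum(avt0_vals, 0.0)
    avt0 = Spectrum(grid, avt0_vals, "absorbance")
    avt1_vals = avt0_vals * (1.0 - product.photostability) if degrade else avt0_vals
    avt1 = Spectrum(grid, avt1_vals, "absorbance")
    return r0, r, avt0, avt1


# ---------------------------------------------------------------------------
# Ring-study simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySimConfig:
    """Generating configuration for a balanced synthetic ring study.

    Variance components are ln-scale standard deviations.  Defaults
    mirror the re-evaluation study scale: 4 labs, 4 products with 2
    duplicates, panels of 10 volunteers, and dispersion of the order the
    validated configuration achieved.
    """

    n_labs: int = 4
    n_products: int = 4
    n_duplicates: int = 2
    panel_size: int = 10
    lab_pers: float = 0.10
    lab_product: float = 0.05
    lab_F1: float = 0.03
    lab_F2: float = 0.03
    lab_F3: float = 0.03
    repeatability: float = 0.08
    reference_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        sds = (
            self.lab_pers,
            self.lab_product,
            self.lab_F1,
            self.lab_F2,
            self.lab_F3,
            self.repeatability,
            self.reference_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("variance-component sds must be >= 0")
        if self.n_duplicates != 2 or self.n_products != 4:
            raise ValueError(
                "the balanced factorial layout requires 4 products × 2 duplicates"
            )
        if self.n_labs < 1:
            raise ValueError("need at least one lab")


def simulate_ring_study(
    cfg: StudySimConfig,
    products: Sequence[ProductModel],
    group_of: Sequence[object] | None = None,
) -> RingStudyData:
    """Draw a balanced ln-scale ring study around ground-truth products.

    ``products`` are assigned to product groups of 4 (or per ``group_of``);
    each group receives the standard 8-row factorial layout in every lab.
    ``ln_pf_alt`` adds lab, lab×product, lab×factor and residual effects
    to the true ln SPF; ``ln_pf_ref`` adds independent reference noise.
    """
    products = list(products)
    if len(products) % 4:
        raise ValueError("products must come in groups of 4")
    if group_of is None:
        group_of = [i // 4 + 1 for i in range(len(products))]
    root = np.random.SeedSequence(cfg.seed)
    lab_seeds = root.spawn(cfg.n_labs)
    ref_rng = np.random.default_rng(root.spawn(1)[0])

    records = []
    for li in range(cfg.n_labs):
        lab_root = lab_seeds[li]
        lab_rng = np.random.default_rng(lab_root)
        a_l = lab_rng.normal(0.0, cfg.lab_pers)
        # one effect per factor level, per factor, per lab
        f_effects = {
            k: lab_rng.normal(0.0, sd, size=2)
            for k, sd in zip(
                ("panel", "tech_vivo", "tech_vitro"),
                (cfg.lab_F1, cfg.lab_F2, cfg.lab_F3),
            )
        }
        b_lp = lab_rng.normal(0.0, cfg.lab_product, size=len(products))
        for gi, group in enumerate(sorted(set(group_of))):
            idx = [i for i, g in enumerate(group_of) if g == group]
            for row, (p_off, levels) in enumerate(
                zip([i // 2 for i in range(8)], STANDARD_LAYOUT)
            ):
                pi = idx[p_off]
                product = products[pi]
                duplicate = row % 2 + 1
                panel, tv, tw = levels
                eps = lab_rng.normal(0.0, cfg.repeatability)
                ln_alt = (
                    math.log(product.spf_true)
                    + a_l
                    + b_lp[pi]
                    + f_effects["panel"][panel - 1]
                    + f_effects["tech_vivo"][tv - 1]
                    + f_effects["tech_vitro"][tw - 1]
                    + eps
                )
                ln_ref = math.log(product.spf_true) + ref_rng.normal(
                    0.0, cfg.reference_sd
                )
                records.append(
                    {
                        "lab": f"lab{li + 1}",
                        "product_group": group,
                        "product": product.label or f"prod{pi + 1}",
                        "duplicate": duplicate,
                        "panel": panel,
                        "tech_vivo": tv,
                        "tech_vitro": tw,
                        "ln_pf_alt": ln_alt,
                        "ln_pf_ref": ln_ref,
                        "ln_pf_true": math.log(product.spf_true),
                    }
                )
    return RingStudyData(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# On-disk study tree
# ---------------------------------------------------------------------------

def write_study_tree(
    out_dir: str | Path,
    cfg: StudySimConfig,
    spf_targets: Sequence[float] = (30.0, 40.0, 35.0, 50.0),
    uvapf_targets: Sequence[float] | None = None,
    photostability: float = 0.1,
    ita_range: tuple[float, float] = (41.0, 55.0),
) -> dict:
    """Write a complete synthetic study tree (spectra + manifest + truth).

    For each lab/product/duplicate, per-volunteer spectra (R0, R, Avt0,
    Avt1) are written as two-column CSV files, listed in ``manifest.csv``
    together with the design factors; the generating parameters go to
    ``ground_truth.json`` and the layout to ``design.csv``.
    """
    from .spectral import write_spectrum

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    if uvapf_targets is None:
        uvapf_targets = [max(1.0, s / 3.0) for s in spf_targets]
    products = [
        make_product(s, u, photostability, label=f"prod{i + 1}")
        for i, (s, u) in enumerate(zip(spf_targets, uvapf_targets))
    ]
    root = np.random.SeedSequence(cfg.seed)
    manifest_rows = []
    design_rows = []
    lab_seeds = root.spawn(cfg.n_labs)
    for li in range(cfg.n_labs):
        lab = f"lab{li + 1}"
        vol_rng = np.random.default_rng(lab_seeds[li])
        panel_itas = {
            1: vol_rng.uniform(*ita_range, size=cfg.panel_size),
            2: vol_rng.uniform(*ita_range, size=cfg.panel_size),
        }
        for row, levels in enumerate(STANDARD_LAYOUT):
            p = products[row // 2]
            duplicate = row % 2 + 1
            panel, tv, tw = levels
            if li == 0:
                design_rows.append(
                    {
                        "product": p.label,
                        "duplicate": duplicate,
                        "panel": panel,
                        "tech_vivo": tv,
                        "tech_vitro": tw,
                    }
                )
            for vi in range(cfg.panel_size):
                skin = make_skin(panel_itas[panel][vi], noise_sd=0.0)
                r0, r, avt0, avt1 = simulate_measurement(
                    p,
                    skin,
                    degrade=photostability > 0,
                    seed=np.random.SeedSequence(
                        entropy=cfg.seed, spawn_key=(li, row, vi)
                    ),
                )
                stem = f"{lab}_{p.label}_d{duplicate}_v{vi + 1}"
                files = {}
                for tag, spec in (
                    ("R0", r0),
                    ("R", r),
                    ("Avt0", avt0),
                    ("Avt1", avt1),
                ):
                    fname = f"{stem}_{tag}.csv"
                    write_spectrum(spec, spectra_dir / fname)
                    files[tag] = f"spectra/{fname}"
                manifest_rows.append(
                    {
                        "lab": lab,
                        "product": p.label,
                        "duplicate": duplicate,
                        "volunteer": vi + 1,
                        "panel": panel,
                        "tech_vivo": tv,
                        "tech_vitro": tw,
                        "r0_file": files["R0"],
                        "r_file": files["R"],
                        "avt0_file": files["Avt0"],
                        "avt1_file": files["Avt1"],
                    }
                )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(design_rows).to_csv(out / "design.csv", index=False)
    truth = {
        "seed": cfg.seed,
        "panel_size": cfg.panel_size,
        "products": [
            {
                "label": p.label,
                "spf_true": p.spf_true,
                "uvapf_true": p.uvapf_true,
                "photostability": float(np.mean(p.photostability)),
            }
            for p in products
        ],
    }
    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=2), encoding="utf-8"
    )
    return {
        "manifest": str(out / "manifest.csv"),
        "design": str(out / "design.csv"),
        "ground_truth": str(out / "ground_truth.json"),
        "n_measurements": len(manifest_rows),
    }
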