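"""Interlaboratory ring-study validation statistics.

A multi-laboratory validation compares the alternative method against the
reference method on a balanced factorial layout: within each product
group, 4 products × 2 blinded duplicates are assigned to combinations of
three two-level factors (volunteer panel F1, in vivo technician F2,
in vitro technician F3) such that every factor level appears in half the
rows and every product sees both levels of every factor.

All statistics are computed on the natural-log scale of the protection
factors.  Five acceptance criteria are scored as percentages of their
limits (<= 100 % met, <= 110 % almost met):

1. reproducibility: ``s_R(alt) / s_R(ref)``
2. persistent lab bias: ``s_L,pers / AL`` (AL = 0.3 ln units)
3. augmented reproducibility (adds product-bias variance within the
   group): ``sqrt(s_R² + var(bias_p)) / s_R(ref)``
4. product-group mean bias: ``|bias| / DL`` (DL = 0.3, 0.4 for group 2)
5. cross-group bias consistency: ``sd(group biases) / CL``

The variance decomposition is a balanced method-of-moments scheme on the
factorial layout: within-lab orthogonal contrasts isolate the lab×factor
components and the repeatability residual; lab-by-product cell means
yield the lab×product and persistent-lab components via two-way mean
squares.  Negative variance estimates are truncated at zero.  The overall
bias across products is a robust, standard-error-weighted Hampel
M-estimate ("MU-Hampel").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingStudyDesign",
    "RingStudyData",
    "PrecisionEstimates",
    "RingLimits",
    "CriteriaReport",
    "GroupCriteria",
    "validate_design",
    "estimate_precision",
    "criterion1",
    "criterion2",
    "criterion3",
    "criterion4",
    "criterion5",
    "product_bias",
    "status_code",
    "mu_hampel_bias",
    "apply_bias_correction",
    "evaluate_criteria",
    "render_report",
    "DEFAULT_AL",
    "DEFAULT_DL",
    "DEFAULT_CL",
]

FACTOR_COLUMNS = ("panel", "tech_vivo", "tech_vitro")

#: Acceptability limit for the persistent lab bias (ln units).
DEFAULT_AL = 0.3
#: Decision limit for the product-group bias (ln units).
DEFAULT_DL = 0.3
#: Decision limit override for low-SPF emulsions (product group 2).
DL_OVERRIDES = {"2": 0.4, 2: 0.4}
#: Consistency limit for the cross-group bias dispersion (ln units).
DEFAULT_CL = 0.093


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignRow:
    product: str
    duplicate: int
    panel: int
    tech_vivo: int
    tech_vitro: int

    def factors(self) -> tuple[int, int, int]:
        return (self.panel, self.tech_vivo, self.tech_vitro)


#: The balanced 8-row layout applied to every product group: products
#: p1..p4 with duplicates a/b and factor levels (panel, vivo, vitro).
STANDARD_LAYOUT: tuple[tuple[int, int, int], ...] = (
    (1, 1, 1),
    (2, 2, 2),
    (1, 2, 1),
    (2, 1, 2),
    (1, 2, 2),
    (2, 1, 1),
    (1, 1, 2),
    (2, 2, 1),
)


@dataclass
class RingStudyDesign:
    """Factorial layout for one product group (8 sample rows)."""

    rows: list[DesignRow]

    @classmethod
    def standard(cls, products: Sequence[str] | None = None) -> "RingStudyDesign":
        products = list(products) if products else [f"p{i}" for i in range(1, 5)]
        if len(products) != 4:
            raise ValueError("the standard layout covers exactly 4 products")
        rows = []
        for i, levels in enumerate(STANDARD_LAYOUT):
            rows.append(DesignRow(products[i // 2], i % 2 + 1, *levels))
        return cls(rows)


@dataclass
class DesignValidationReport:
    valid: bool
    violations: list[str] = field(default_factory=list)


def validate_design(design: RingStudyDesign) -> DesignValidationReport:
    """Check the factorial balance of a product-group layout.

    Requires: each factor level appears in half the rows; every product
    has two duplicates whose settings differ and which cover both levels
    of every factor; factor contrasts are mutually orthogonal.
    """
    violations: list[str] = []
    rows = design.rows
    if not rows:
        return DesignValidationReport(False, ["empty design"])
    n = len(rows)
    if n % 2:
        violations.append(f"odd number of rows ({n})")
    for k, name in enumerate(FACTOR_COLUMNS):
        levels = [r.factors()[k] for r in rows]
        if set(levels) - {1, 2}:
            violations.append(f"{name}: levels outside {{1, 2}}")
            continue
        if levels.count(1) != levels.count(2):
            violations.append(
                f"{name}: unbalanced levels ({levels.count(1)} vs {levels.count(2)})"
            )
    by_product: dict[str, list[DesignRow]] = {}
    for r in rows:
        by_product.setdefault(r.product, []).append(r)
    for product, prows in by_product.items():
        if len(prows) != 2:
            violations.append(f"product {product}: {len(prows)} rows (expected 2)")
            continue
        for k, name in enumerate(FACTOR_COLUMNS):
            if {prows[0].factors()[k], prows[1].factors()[k]} != {1, 2}:
                violations.append(
                    f"product {product}: duplicates share {name} level"
                )
    # pairwise orthogonality of factor contrasts
    signs = np.array(
        [[1 if lv == 1 else -1 for lv in r.factors()] for r in rows], dtype=float
    )
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(float(signs[:, i] @ signs[:, j])) > 1e-9:
                violations.append(
                    f"factors {FACTOR_COLUMNS[i]} and {FACTOR_COLUMNS[j]} "
                    "are not orthogonal"
                )
    return DesignValidationReport(not violations, violations)


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "lab",
    "product_group",
    "product",
    "duplicate",
    "panel",
    "tech_vivo",
    "tech_vitro",
    "ln_pf_alt",
    "ln_pf_ref",
)


@dataclass
class RingStudyData:
    """Ln-scale ring-study results with their design factors."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if not np.all(np.isfinite(self.frame["ln_pf_alt"])):
            raise ValueError("non-finite ln_pf_alt values")
        key = self.frame[["lab", "product", "duplicate"]]
        if key.duplicated().any():
            raise ValueError("duplicate (lab, product, duplicate) records")

    @classmethod
    def from_results_csv(cls, path: str | Path) -> "RingStudyData":
        """Load a CSV with pf_alt/pf_ref columns (PF scale) or ln columns."""
        df = pd.read_csv(path)
        if "ln_pf_alt" not in df.columns:
            if np.any(df["pf_alt"] <= 0) or np.any(df["pf_ref"] <= 0):
                raise ValueError("protection factors must be positive")
            df["ln_pf_alt"] = np.log(df["pf_alt"])
            df["ln_pf_ref"] = np.log(df["pf_ref"])
        return cls(df)

    def groups(self) -> list:
        return sorted(self.frame["product_group"].unique())

    def group_frame(self, group) -> pd.DataFrame:
        sub = self.frame[self.frame["product_group"] == group]
        if sub.empty:
            raise KeyError(f"no data for product group {group!r}")
        return sub

    def with_bias_correction(self, b: float) -> "RingStudyData":
        df = self.frame.copy()
        df["ln_pf_alt"] = apply_bias_correction(df["ln_pf_alt"].to_numpy(), b)
        return RingStudyData(df)


def apply_bias_correction(ln_values: np.ndarray | float, b: float):
    """Shift ln-scale results by +b (undoing an estimated bias of −b)."""
    return np.asarray(ln_values, dtype=float) + b if np.ndim(ln_values) else ln_values + b


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass
class PrecisionEstimates:
    """Ln-scale variance components for one product group."""

    s_R: float
    s_L: float
    s_L_pers: float
    s_L_product: float
    s_L_F1: float
    s_L_F2: float
    s_L_F3: float
    s_r: float
    n_results: int
    n_labs: int
    degraded: bool = False


def _within_lab_matrices(sub: pd.DataFrame):
    """Order one lab's rows canonically; return (y, products, signs)."""
    sub = sub.sort_values(["product", "duplicate"])
    y = sub["ln_pf_alt"].to_numpy()
    products = sub["product"].to_numpy()
    signs = np.column_stack(
        [np.where(sub[c].to_numpy() == 1, 1.0, -1.0) for c in FACTOR_COLUMNS]
    )
    return y, products, signs


def estimate_precision(data: RingStudyData, group) -> PrecisionEstimates:
    """Method-of-moments variance decomposition for one product group.

    Components: persistent lab effect (``s_L,pers``), lab×product
    (``s_L,product``), lab×factor (``s_L,F1..F3``), repeatability
    (``s_r``); ``s_R`` is the square root of their summed variances and
    ``s_L`` the observed standard deviation of lab means.  Negative
    moment estimates are truncated at zero.
    """
    import warnings

    df = data.group_frame(group)
    labs = sorted(df["lab"].unique())
    products = sorted(df["product"].unique())
    L, P = len(labs), len(products)
    if L < 2:
        raise ValueError("variance decomposition requires at least 2 labs")
    if P < 2:
        raise ValueError("variance decomposition requires at least 2 products")
    counts = df.groupby(["lab", "product"]).size()
    balanced = (
        len(counts) == L * P
        and (counts == 2).all()
        and len(df) == 2 * L * P
    )
    degraded = not balanced
    if degraded:
        warnings.warn(
            f"group {group!r}: unbalanced layout; using degraded estimator",
            stacklevel=2,
        )
        return _degraded_estimate(df, labs, products)

    # --- within-lab contrasts -------------------------------------------
    t_contrasts = np.zeros((L, 3))
    resid_ss = 0.0
    resid_df = 0
    for i, lab in enumerate(labs):
        y, prods, signs = _within_lab_matrices(df[df["lab"] == lab])
        for k in range(3):
            s = signs[:, k]
            t_contrasts[i, k] = y[s > 0].mean() - y[s < 0].mean()
        # residual after removing product means and factor contrasts
        X = np.column_stack(
            [np.where(prods == p, 1.0, 0.0) for p in products] + [signs]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rank = np.linalg.matrix_rank(X)
        resid_ss += float(r @ r)
        resid_df += y.size - rank

    if resid_df > 0:
        var_r = resid_ss / resid_df
    else:
        # factor contrasts exhaust the duplicate df (P = 3): fall back to
        # duplicate differences, confounded with factor effects
        d = df.groupby(["lab", "product"])["ln_pf_alt"].agg(lambda v: np.ptp(v))
        var_r = float(np.mean(d.to_numpy() ** 2) / 2.0)
        degraded = True

    var_F = np.zeros(3)
    for k in range(3):
        vt = float(np.var(t_contrasts[:, k], ddof=1))
        var_F[k] = max(0.0, (vt - 2.0 * var_r / P) / 2.0)

    # --- lab × product cell means ---------------------------------------
    cell = df.groupby(["lab", "product"])["ln_pf_alt"].mean().unstack()
    cell = cell.loc[labs, products].to_numpy()
    lab_means = cell.mean(axis=1)
    prod_means = cell.mean(axis=0)
    grand = cell.mean()
    interaction = cell - lab_means[:, None] - prod_means[None, :] + grand
    ms_int = float((interaction**2).sum() / ((L - 1) * (P - 1)))
    ms_lab = float(P * ((lab_means - grand) ** 2).sum() / (L - 1))

    var_prod = max(0.0, ms_int - var_r / 2.0)
    var_pers = max(0.0, (ms_lab - ms_int) / P - float(var_F.sum()) / 2.0)
    var_R = var_pers + var_prod + float(var_F.sum()) + var_r

    return PrecisionEstimates(
        s_R=math.sqrt(var_R),
        s_L=float(np.std(lab_means, ddof=1)),
        s_L_pers=math.sqrt(var_pers),
        s_L_product=math.sqrt(var_prod),
        s_L_F1=math.sqrt(var_F[0]),
        s_L_F2=math.sqrt(var_F[1]),
        s_L_F3=math.sqrt(var_F[2]),
        s_r=math.sqrt(var_r),
        n_results=len(df),
        n_labs=L,
        degraded=degraded,
    )


def _degraded_estimate(
    df: pd.DataFrame, labs: list, products: list
) -> PrecisionEstimates:
    """Coarse two-component decomposition for unbalanced data."""
    d = df.groupby(["lab", "product"])["ln_pf_alt"].agg(lambda v: np.ptp(v))
    pairs = d[df.groupby(["lab", "product"]).size() == 2]
    var_r = float(np.mean(pairs.to_numpy() ** 2) / 2.0) if len(pairs) else 0.0
    cell = df.groupby(["lab", "product"])["ln_pf_alt"].mean().unstack()
    lab_means = cell.mean(axis=1).to_numpy()
    var_pers = max(0.0, float(np.var(lab_means, ddof=1)) - var_r / 2.0)
    return PrecisionEstimates(
        s_R=math.sqrt(var_pers + var_r),
        s_L=float(np.std(lab_means, ddof=1)),
        s_L_pers=math.sqrt(var_pers),
        s_L_product=0.0,
        s_L_F1=0.0,
        s_L_F2=0.0,
        s_L_F3=0.0,
        s_r=math.sqrt(var_r),
        n_results=len(df),
        n_labs=len(labs),
        degraded=True,
    )


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

def criterion1(s_R_alt: float, s_R_ref: float) -> float:
    """Reproducibility ratio as a percentage of the reference method's."""
    if s_R_ref <= 0:
        raise ValueError("reference reproducibility must be positive")
    return 100.0 * s_R_alt / s_R_ref


def criterion2(s_L_pers: float, AL: float = DEFAULT_AL) -> float:
    """Persistent lab bias as a percentage of the acceptability limit."""
    if AL <= 0:
        raise ValueError("acceptability limit must be positive")
    return 100.0 * s_L_pers / AL


def criterion3(
    s_R_alt: float, product_biases: Sequence[float], s_R_ref: float
) -> float:
    """Augmented reproducibility (adds within-group bias variance)."""
    biases = np.asarray(product_biases, dtype=float)
    if biases.size < 2:
        raise ValueError("criterion 3 requires at least 2 products")
    if s_R_ref <= 0:
        raise ValueError("reference reproducibility must be positive")
    augmented = math.sqrt(s_R_alt**2 + float(np.var(biases, ddof=1)))
    return 100.0 * augmented / s_R_ref


def product_bias(mean_alt: float, mean_ref: float) -> float:
    """Ln-scale bias of the alternative method for one product."""
    if mean_alt <= 0 or mean_ref <= 0:
        raise ValueError("product means must be positive")
    return math.log(mean_alt) - math.log(mean_ref)


def criterion4(group_bias: float, DL: float = DEFAULT_DL) -> float:
    """Absolute product-group bias as a percentage of the decision limit."""
    if DL <= 0:
        raise ValueError("decision limit must be positive")
    return 100.0 * abs(group_bias) / DL


def criterion5(group_biases: Sequence[float], CL: float = DEFAULT_CL) -> float:
    """Dispersion of signed group biases as a percentage of the CL."""
    biases = np.asarray(group_biases, dtype=float)
    if biases.size < 2:
        raise ValueError("criterion 5 requires at least 2 product groups")
    if CL <= 0:
        raise ValueError("consistency limit must be positive")
    return 100.0 * float(np.std(biases, ddof=1)) / CL


def status_code(pct: float) -> str:
    """met (<= 100 %), almost_met (<= 110 %) or not_met."""
    if pct < 0:
        raise ValueError("criterion percentage cannot be negative")
    if pct <= 100.0:
        return "met"
    if pct <= 110.0:
        return "almost_met"
    return "not_met"


# ---------------------------------------------------------------------------
# Robust overall bias (MU-Hampel)
# ---------------------------------------------------------------------------

def _hampel_psi(r: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Three-part redescending Hampel ψ."""
    ar = np.abs(r)
    psi = np.where(ar <= a, r, 0.0)
    mid = (ar > a) & (ar <= b)
    psi = np.where(mid, a * np.sign(r), psi)
    desc = (ar > b) & (ar <= c)
    psi = np.where(desc, a * (c - ar) / (c - b) * np.sign(r), psi)
    return psi


def hampel_rho(r: np.ndarray, a: float = 1.5, b: float = 3.0, c: float = 4.5):
    """Hampel ρ (integral of ψ), used by the grid-search cross-check."""
    ar = np.abs(np.asarray(r, dtype=float))
    rho = np.where(ar <= a, 0.5 * ar**2, 0.0)
    mid = (ar > a) & (ar <= b)
    rho = np.where(mid, a * ar - 0.5 * a**2, rho)
    desc = (ar > b) & (ar <= c)
    rho = np.where(
        desc,
        a * b - 0.5 * a**2 + a * (c - b) / 2.0 * (1.0 - ((c - ar) / (c - b)) ** 2),
        rho,
    )
    tail = ar > c
    rho = np.where(tail, a * b - 0.5 * a**2 + a * (c - b) / 2.0, rho)
    return rho


def mu_hampel_bias(
    biases: Sequence[float],
    std_errors: Sequence[float],
    a: float = 1.5,
    b: float = 3.0,
    c: float = 4.5,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> float:
    """Standard-error-weighted Hampel M-estimate of the overall bias.

    Solves ``Σ ψ((x_i − μ)/se_i)/se_i = 0`` by iteratively reweighted
    means with weights ``ψ(r)/r / se²``; started at the inverse-variance
    weighted median-adjacent mean.  Observations further than ``c``
    standardized units receive zero weight (bounded influence).
    """
    x = np.asarray(biases, dtype=float)
    se = np.asarray(std_errors, dtype=float)
    if x.size == 0:
        raise ValueError("mu_hampel_bias requires at least one bias")
    if x.shape != se.shape or np.any(se <= 0):
        raise ValueError("standard errors must be positive and match biases")
    if x.size == 1:
        return float(x[0])
    mu = float(np.median(x))
    for _ in range(max_iter):
        r = (x - mu) / se
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(r == 0.0, 1.0, _hampel_psi(r, a, b, c) / r) / se**2
        if w.sum() <= 0:
            # every point fully rejected from this start: fall back to the
            # closest observation and continue
            mu_new = float(x[np.argmin(np.abs(x - mu))])
        else:
            mu_new = float(np.sum(w * x) / np.sum(w))
        if abs(mu_new - mu) < tol:
            return mu_new
        mu = mu_new
    raise RuntimeError(f"MU-Hampel did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# Criteria evaluation and reporting
# ---------------------------------------------------------------------------

@dataclass
class RingLimits:
    """Reference-method limits — inputs, not computed quantities."""

    s_R_ref: dict = field(default_factory=dict)  # per product group, ln units
    AL: float = DEFAULT_AL
    DL: dict = field(default_factory=dict)  # per-group overrides
    DL_default: float = DEFAULT_DL
    CL: float = DEFAULT_CL

    def dl_for(self, group) -> float:
        for key in (group, str(group)):
            if key in self.DL:
                return self.DL[key]
        for key in (group, str(group)):
            if key in DL_OVERRIDES and not self.DL:
                return DL_OVERRIDES[key]
        return self.DL_default

    def sr_ref_for(self, group) -> float:
        for key in (group, str(group)):
            if key in self.s_R_ref:
                return self.s_R_ref[key]
        raise KeyError(f"no reference reproducibility for group {group!r}")


@dataclass
class GroupCriteria:
    product_group: object
    c1_pct: float
    c2_pct: float
    c3_pct: float
    c4_pct: float
    statuses: dict
    group_bias: float
    product_biases: dict
    precision: PrecisionEstimates


@dataclass
class CriteriaReport:
    groups: list[GroupCriteria]
    c5_pct: float | None
    c5_status: str | None
    overall_bias_mu_hampel: float | None
    limits: RingLimits
    bias_corrected: bool = False


def _group_product_biases(df: pd.DataFrame) -> dict:
    biases = {}
    for product, sub in df.groupby("product"):
        mean_alt = float(np.exp(sub["ln_pf_alt"]).mean())
        mean_ref = float(np.exp(sub["ln_pf_ref"]).mean())
        biases[product] = product_bias(mean_alt, mean_ref)
    return biases


def evaluate_criteria(
    data: RingStudyData,
    limits: RingLimits,
    bias_b: float = 0.0,
) -> CriteriaReport:
    """Score criteria 1–5 for every product group in the data.

    When ``bias_b`` is non-zero the ln-scale results are shifted by +b
    before the bias criteria (4/5) and the robust overall bias; the
    dispersion criteria (1/2/3) are invariant to the shift.
    """
    corrected = data.with_bias_correction(bias_b) if bias_b else data
    groups = []
    group_biases = []
    all_biases: list[float] = []
    all_ses: list[float] = []
    for g in data.groups():
        df = corrected.group_frame(g)
        prec = estimate_precision(corrected, g)
        biases = _group_product_biases(df)
        gbias = float(np.mean(list(biases.values())))
        sr_ref = limits.sr_ref_for(g)
        c1 = criterion1(prec.s_R, sr_ref)
        c2 = criterion2(prec.s_L_pers, limits.AL)
        c3 = criterion3(prec.s_R, list(biases.values()), sr_ref)
        c4 = criterion4(gbias, limits.dl_for(g))
        statuses = {
            "c1": status_code(c1),
            "c2": status_code(c2),
            "c3": status_code(c3),
            "c4": status_code(c4),
        }
        groups.append(
            GroupCriteria(g, c1, c2, c3, c4, statuses, gbias, biases, prec)
        )
        group_biases.append(gbias)
        for product, pb in biases.items():
            sub = df[df["product"] == product]
            n = len(sub)
            se = float(sub["ln_pf_alt"].std(ddof=1) / math.sqrt(n)) if n > 1 else 1.0
            all_biases.append(pb)
            all_ses.append(max(se, 1e-6))
    c5 = c5_status = None
    if len(group_biases) >= 2:
        c5 = criterion5(group_biases, limits.CL)
        c5_status = status_code(c5)
    overall = (
        mu_hampel_bias(all_biases, all_ses) if all_biases else None
    )
    return CriteriaReport(
        groups=groups,
        c5_pct=c5,
        c5_status=c5_status,
        overall_bias_mu_hampel=overall,
        limits=limits,
        bias_corrected=bool(bias_b),
    )


def report_tables(report: CriteriaReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Criteria and precision tables as DataFrames."""
    crit_rows = []
    prec_rows = []
    for g in report.groups:
        crit_rows.append(
            {
                "product_group": g.product_group,
                "criterion1_pct": round(g.c1_pct, 1),
                "criterion2_pct": round(g.c2_pct, 1),
                "criterion3_pct": round(g.c3_pct, 1),
                "criterion4_pct": round(g.c4_pct, 1),
                "criterion5_pct": (
                    round(report.c5_pct, 1) if report.c5_pct is not None else np.nan
                ),
                "status_c1": g.statuses["c1"],
                "status_c2": g.statuses["c2"],
                "status_c3": g.statuses["c3"],
                "status_c4": g.statuses["c4"],
                "group_bias_ln": round(g.group_bias, 3),
            }
        )
        p = g.precision
        prec_rows.append(
            {
                "product_group": g.product_group,
                "n_results": p.n_results,
                "n_labs": p.n_labs,
                "s_R": round(p.s_R, 3),
                "s_L": round(p.s_L, 3),
                "s_L_pers": round(p.s_L_pers, 3),
                "s_L_product": round(p.s_L_product, 3),
                "s_L_F1": round(p.s_L_F1, 3),
                "s_L_F2": round(p.s_L_F2, 3),
                "s_L_F3": round(p.s_L_F3, 3),
                "s_r": round(p.s_r, 3),
            }
        )
    return pd.DataFrame(crit_rows), pd.DataFrame(prec_rows)


def report_to_dict(report: CriteriaReport) -> dict:
    crit, prec = report_tables(report)
    return {
        "criteria": crit.to_dict(orient="records"),
        "precision": prec.to_dict(orient="records"),
        "c5_pct": report.c5_pct,
        "c5_status": report.c5_status,
        "overall_bias_mu_hampel": report.overall_bias_mu_hampel,
        "bias_corrected": report.bias_corrected,
    }


def render_report(
    report: CriteriaReport,
    out_dir: str | Path,
    data: RingStudyData | None = None,
    plot: bool = False,
) -> dict:
    """Write criteria/precision tables (CSV + JSON) and an optional plot.

    The plot shows individual ln-scale results per product on a base-2
    log axis with the reference mean and a reproducibility band.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    crit, prec = report_tables(report)
    paths = {
        "criteria_csv": out_dir / "criteria.csv",
        "precision_csv": out_dir / "precision.csv",
        "report_json": out_dir / "report.json",
    }
    crit.to_csv(paths["criteria_csv"], index=False)
    prec.to_csv(paths["precision_csv"], index=False)
    paths["report_json"].write_text(
        json.dumps(report_to_dict(report), indent=2, default=str), encoding="utf-8"
    )
    if plot and data is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 4))
        df = data.frame.sort_values(["product_group", "product", "lab"])
        labels = df["product"].astype(str) + "/" + df["lab"].astype(str)
        x = np.arange(len(df))
        ax.plot(x, np.exp(df["ln_pf_ref"]), "_", color="tab:blue", label="reference")
        ax.plot(x, np.exp(df["ln_pf_alt"]), "o", ms=3, color="tab:orange", label="alternative")
        ax.set_yscale("log", base=2)
        ax.set_xticks(x[:: max(1, len(x) // 30)])
        ax.set_xticklabels(labels[:: max(1, len(x) // 30)], rotation=90, fontsize=6)
        ax.set_ylabel("protection factor (log2 axis)")
        ax.legend()
        fig.tight_layout()
        plot_path = out_dir / "results_plot.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path
    return {k: str(v) for k, v in paths.items()}


def report_from_dict(d: dict, limits: RingLimits | None = None) -> dict:
    """Re-parse a serialized report (round-trip helper for callers)."""
    return json.loads(json.dumps(d))
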