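"""Quantitative assay mathematics: relative and absolute qPCR, count ratios.

Relative expression follows the 2^-ΔΔCq method: replicate quantification
cycles are averaged on the Cq scale, normalized to the arithmetic-mean Cq of
the endogenous reference genes (equivalently the geometric mean of their
expression), and referred to a calibrator sample.  Absolute quantification
fits a standard curve of Cq on log10 input quantity from serial dilutions;
the slope gives the amplification efficiency ``10**(-1/slope) - 1``.
Simple percentage endpoints (metastasis penetrance, clonogenic ability,
karyotype aberration summaries) round half-up to one decimal, the precision
such results are conventionally reported at.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionResult",
    "StandardCurve",
    "KaryotypeSummary",
    "ddcq_fold_change",
    "fold_reduction",
    "fit_standard_curve",
    "absolute_quantity",
    "penetrance",
    "clonogenic_ability",
    "karyotype_summary",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (printed-value convention)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class ExpressionResult:
    """Relative expression of one sample/gene pair vs the calibrator."""

    sample: str
    gene: str
    delta_cq: float
    delta_delta_cq: float
    fold_change: float
    cq_sd: float
    fold_change_low: float
    fold_change_high: float

    @property
    def percent_of_calibrator(self) -> float:
        return 100.0 * self.fold_change

    @property
    def fold_reduction(self) -> float:
        return fold_reduction(self.fold_change) if self.fold_change <= 1 else np.nan


def _validate_cq_table(cq: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "gene", "cq", "role"}
    missing = required - set(cq.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    if (cq["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    return cq


def ddcq_fold_change(
    cq: pd.DataFrame,
    reference_genes: tuple[str, ...] | None = None,
    calibrator: str | None = None,
) -> list[ExpressionResult]:
    """Relative expression by the 2^-ΔΔCq method.

    ΔCq = mean target Cq − mean reference-gene Cq (arithmetic mean over
    replicates, then over reference genes); ΔΔCq subtracts the calibrator's
    ΔCq; fold change is 2^-ΔΔCq.  The replicate SD of the target Cq is
    propagated to an interval ``2**-(ΔΔCq ± SD)``.  The result is invariant
    to adding a constant to every Cq on the plate.
    """
    cq = _validate_cq_table(cq)
    if reference_genes is None:
        reference_genes = tuple(sorted(cq.loc[cq["role"] == "reference", "gene"].unique()))
    if not reference_genes:
        raise ValueError("no reference genes found or given")
    samples = list(dict.fromkeys(cq["sample"]))
    if calibrator is None:
        calibrator = samples[0]
    if calibrator not in samples:
        raise ValueError(f"calibrator {calibrator!r} not present in the table")

    target_genes = [g for g in dict.fromkeys(cq["gene"]) if g not in reference_genes]

    def ref_aggregate(sample: str) -> float:
        means = []
        for gene in reference_genes:
            vals = cq.loc[(cq["sample"] == sample) & (cq["gene"] == gene), "cq"]
            if vals.empty:
                raise ValueError(f"sample {sample!r} lacks reference gene {gene!r}")
            means.append(vals.mean())
        return float(np.mean(means))

    results = []
    for gene in target_genes:
        cal_vals = cq.loc[(cq["sample"] == calibrator) & (cq["gene"] == gene), "cq"]
        if cal_vals.empty:
            raise ValueError(f"calibrator lacks target gene {gene!r}")
        dcq_cal = float(cal_vals.mean()) - ref_aggregate(calibrator)
        for sample in samples:
            vals = cq.loc[(cq["sample"] == sample) & (cq["gene"] == gene), "cq"]
            if vals.empty:
                continue
            dcq = float(vals.mean()) - ref_aggregate(sample)
            ddcq = dcq - dcq_cal
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            results.append(ExpressionResult(
                sample=sample, gene=gene, delta_cq=dcq, delta_delta_cq=ddcq,
                fold_change=float(2.0 ** -ddcq), cq_sd=sd,
                fold_change_low=float(2.0 ** -(ddcq + sd)),
                fold_change_high=float(2.0 ** -(ddcq - sd)),
            ))
    return results


def fold_reduction(relative_expression: float, decimals: int = 1) -> float:
    """Express residual expression (a fraction of the calibrator) as an x-fold drop."""
    if not 0 < relative_expression <= 1:
        raise ValueError(
            f"relative expression {relative_expression} is not a reduction (need 0 < x <= 1)"
        )
    return round_half_up(1.0 / relative_expression, decimals)


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Cq on log10 quantity from a serial dilution series."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    quantity_range: tuple[float, float]

    def cq_of(self, quantity: float) -> float:
        return self.intercept + self.slope * np.log10(quantity)


def fit_standard_curve(quantities, cq_values) -> StandardCurve:
    """Least-squares standard curve; needs >= 3 distinct positive quantities.

    A 100%-efficient assay loses log2(dilution) cycles per dilution step,
    i.e. slope −1/log10(2) ≈ −3.3219 cycles per decade.
    """
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cq_values, dtype=float)
    if np.any(q <= 0):
        raise ValueError("standard quantities must be positive")
    if len(np.unique(q)) < 3:
        raise ValueError("need at least 3 distinct standard quantities")
    fit = stats.linregress(np.log10(q), c)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        efficiency=float(efficiency),
        quantity_range=(float(q.min()), float(q.max())),
    )


@dataclass(frozen=True)
class AbsoluteQuantity:
    quantity: float
    extrapolated: bool


def absolute_quantity(curve: StandardCurve, cq: float) -> AbsoluteQuantity:
    """Invert the standard curve: ``quantity = 10**((cq - intercept) / slope)``.

    Quantities outside the curve's dynamic range are flagged as extrapolated
    rather than rejected — below-range signals are how weak micrometastases
    present, and the positivity rule is applied downstream.
    """
    q = 10.0 ** ((cq - curve.intercept) / curve.slope)
    lo, hi = curve.quantity_range
    return AbsoluteQuantity(quantity=float(q), extrapolated=not lo <= q <= hi)


def micrometastasis_positive(curve: StandardCurve, replicate_cqs, min_in_range: int = 2) -> bool:
    """A tissue is positive when >= ``min_in_range`` of its technical replicates
    interpolate within the standard curve's dynamic range."""
    in_range = sum(not absolute_quantity(curve, c).extrapolated for c in replicate_cqs)
    return in_range >= min_in_range


def penetrance(positives: int, total: int, decimals: int = 1) -> float:
    """Percent of inoculations (or animals) that developed tumors/metastases."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    return round_half_up(100.0 * positives / total, decimals)


def clonogenic_ability(colonies: int, plated: int, decimals: int = 1) -> float:
    """Percent of plated cells forming colonies (>30-cell colonies only,
    excluded upstream of this count)."""
    if plated <= 0:
        raise ValueError("plated cell count must be positive")
    if colonies < 0:
        raise ValueError("colony count must be non-negative")
    return round_half_up(100.0 * colonies / plated, decimals)


@dataclass(frozen=True)
class KaryotypeSummary:
    """Per-category aberration percentages over scored metaphases."""

    categories: dict[str, float]

    @property
    def total_aberrant_percent(self) -> float:
        return round_half_up(sum(self.categories.values()), 2)


def karyotype_summary(per_category_percentages: dict[str, float]) -> KaryotypeSummary:
    """Total aberrant-cell percentage from mutually exclusive category percentages."""
    for name, pct in per_category_percentages.items():
        if not 0 <= pct <= 100:
            raise ValueError(f"category {name!r} percentage {pct} outside [0, 100]")
    if sum(per_category_percentages.values()) > 100 + 1e-9:
        raise ValueError("per-cell exclusive categories cannot sum above 100%")
    return KaryotypeSummary(categories=dict(per_category_percentages))
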