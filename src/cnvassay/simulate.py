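"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure the downstream analysis
assumes: negative-binomial bin counts with GC bias over a known karyotype,
qPCR quantification cycles under known relative expression, take/no-take
limiting-dilution tables under the single-hit Poisson model, and exponential
confluence curves.  All randomness flows through one ``numpy`` generator built
from the explicit ``seed`` argument; nothing touches global state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BinCounts, CopyNumberProfile

__all__ = [
    "gc_bias_factor",
    "simulate_bin_counts",
    "simulate_qpcr_plate",
    "simulate_dilution_assay",
    "simulate_growth_curve",
]

#: contamination floor: state-0 bins keep this fraction of the diploid mean,
#: mimicking residual normal-cell reads in a tumor sample
DEFAULT_CONTAMINATION = 0.01

#: default multiplicative GC bias: quadratic curve peaking at GC 0.45.
#: With the default GC track centered below the peak this depresses coverage
#: in both AT- and GC-rich tails, most strongly AT-rich bins.
DEFAULT_GC_BIAS = {"peak": 0.45, "curvature": 6.0}


def gc_bias_factor(gc: np.ndarray, peak: float = 0.45, curvature: float = 0.0) -> np.ndarray:
    """Multiplicative depth factor as a unimodal quadratic in GC fraction.

    ``curvature=0`` switches the bias off (factor 1 everywhere); the factor is
    floored at 0.1 so extreme-GC bins never lose coverage entirely.
    """
    gc = np.asarray(gc, dtype=float)
    return np.maximum(0.1, 1.0 - curvature * (gc - peak) ** 2)


def simulate_bin_counts(
    profile: CopyNumberProfile,
    mean_depth_per_diploid_bin: float = 500.0,
    dispersion: float = 50.0,
    gc_bias: dict | None = None,
    seed: int = 0,
    contamination: float = DEFAULT_CONTAMINATION,
    sample: str | None = None,
) -> BinCounts:
    """Draw per-bin read counts from a negative binomial around the karyotype.

    The mean of bin *i* with copy-number state ``k_i`` and GC fraction
    ``g_i`` is ``depth * max(k_i, 2*contamination) / 2 * f(g_i)`` where ``f``
    is the GC bias curve; the variance is ``m + m**2 / dispersion`` (NB "size"
    parameterization).  State-0 bins therefore keep a small contamination
    floor so likelihoods stay finite downstream.
    """
    if mean_depth_per_diploid_bin <= 0:
        raise ValueError("mean depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion (NB size) must be positive")
    gc_bias = DEFAULT_GC_BIAS if gc_bias is None else gc_bias
    rng = np.random.default_rng(seed)

    states = np.maximum(profile.states.astype(float), 2.0 * contamination)
    gc = profile.genome.bins["gc"].to_numpy(float)
    mean = mean_depth_per_diploid_bin * (states / 2.0) * gc_bias_factor(gc, **gc_bias)
    p = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p)
    return BinCounts(
        counts=counts,
        genome=profile.genome,
        sample=sample or profile.sample,
    )


def simulate_qpcr_plate(
    true_rel_expr: dict[str, float],
    reference_genes: tuple[str, ...] = ("HPRT1", "COPE"),
    target_gene: str = "TARGET",
    calibrator: str | None = None,
    n_replicates: int = 4,
    cq_noise_sd: float = 0.0,
    calibrator_cq: float = 25.0,
    reference_cq: float = 22.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Cq plate under known relative expression.

    ``true_rel_expr`` maps each sample to its expression as a fraction of the
    calibrator (the first key by default).  The target Cq of a sample is
    shifted by ``-log2(fraction)`` cycles relative to the calibrator; the
    reference genes have a constant Cq across samples, up to noise.  With
    ``cq_noise_sd=0`` the ΔΔCq pipeline recovers the input fractions exactly.

    Returns a tidy table with columns sample, gene, replicate, cq, role.
    """
    for name, frac in true_rel_expr.items():
        if frac <= 0:
            raise ValueError(f"relative expression for {name!r} must be > 0, got {frac}")
    if calibrator is None:
        calibrator = next(iter(true_rel_expr))
    if calibrator not in true_rel_expr:
        raise ValueError(f"calibrator {calibrator!r} missing from true_rel_expr")

    rng = np.random.default_rng(seed)
    cal_frac = true_rel_expr[calibrator]
    rows = []
    for sample, frac in true_rel_expr.items():
        target_cq = calibrator_cq - np.log2(frac / cal_frac)
        for rep in range(n_replicates):
            rows.append((sample, target_gene, rep,
                         target_cq + rng.normal(0, cq_noise_sd), "target"))
            for ref in reference_genes:
                rows.append((sample, ref, rep,
                             reference_cq + rng.normal(0, cq_noise_sd), "reference"))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "cq", "role"])


def simulate_dilution_assay(
    frequency: float,
    doses: tuple[int, ...] = (1_000_000, 100_000, 10_000, 1_000, 100),
    n_per_dose: int = 3,
    group: str = "group",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate tumor take/no-take outcomes under the single-hit model.

    Each inoculation of ``d`` cells carries at least one tumor-initiating cell
    with probability ``1 - exp(-frequency * d)``.  The default dose ladder
    follows the study design (10-fold steps from one million down to one
    hundred cells).  Returns columns group, dose, n, tumors.
    """
    if not 0 < frequency < 1:
        raise ValueError(f"frequency must lie in (0, 1), got {frequency}")
    rng = np.random.default_rng(seed)
    doses_arr = np.asarray(doses, dtype=float)
    p = 1.0 - np.exp(-frequency * doses_arr)
    tumors = rng.binomial(n_per_dose, p)
    return pd.DataFrame({
        "group": group,
        "dose": np.asarray(doses, dtype=int),
        "n": n_per_dose,
        "tumors": tumors,
    })


def simulate_growth_curve(
    A: float = 5.0,
    B: float = np.log(2) / 18.6,
    duration: float = 144.0,
    interval: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential confluence curve ``min(100, A * exp(B t) + noise)``.

    Times are hours, confluence is percent and plateaus at 100 (a full well).
    Returns columns t, confluence; confluence is floored just above zero so
    log-scale fits remain defined.
    """
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 1e-9, interval)
    conf = A * np.exp(B * t) + rng.normal(0, noise_sd, size=len(t))
    conf = np.clip(conf, 1e-3, 100.0)
    return pd.DataFrame({"t": t, "confluence": conf})
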