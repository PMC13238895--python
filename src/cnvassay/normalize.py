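"""Library-size and GC normalization of binned read counts.

Raw bin counts carry two nuisance scales: total sequencing depth and a
unimodal GC-content bias.  Normalization here is deterministic and
three-step:

1. scale all counts so the genome-wide mean equals ``target``;
2. divide each bin by the median ratio of its GC stratum to the global
   median (deciles of the GC track, thin strata merged with a neighbor);
3. rescale once more so the genome-wide mean is exactly ``target`` again.

The closing rescale makes the whole map idempotent: normalizing an already
normalized track is a no-op to floating-point precision.  The output is
invariant to multiplying every input count by a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .genome import BinCounts, GenomeBins

__all__ = [
    "NormalizedBins",
    "normalize_counts",
    "estimate_diploid_mean",
    "estimate_dispersion",
    "mom_dispersion",
]

MIN_STRATUM_BINS = 20


@dataclass(frozen=True)
class NormalizedBins:
    """Normalized per-bin counts plus log2 ratios to the diploid baseline."""

    values: np.ndarray
    log2_ratio: np.ndarray
    genome: GenomeBins
    sample: str
    target: float
    diploid_mean: float
    lib_scale: float
    gc_factors: np.ndarray
    strata: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_bins(self) -> int:
        return len(self.values)


def _gc_strata(gc: np.ndarray, n_strata: int = 10, min_bins: int = MIN_STRATUM_BINS) -> np.ndarray:
    """Assign bins to GC decile strata, merging strata thinner than ``min_bins``.

    Returns an integer stratum label per bin; labels are contiguous from 0.
    """
    finite = np.isfinite(gc)
    edges = np.unique(np.quantile(gc[finite], np.linspace(0, 1, n_strata + 1)))
    if len(edges) < 2:  # constant GC track: one stratum
        labels = np.zeros(len(gc), dtype=int)
    else:
        labels = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    labels[~finite] = -1  # no GC information

    # merge thin strata into the nearest occupied neighbor, left to right
    present = [g for g in range(len(edges) - 1) if np.any(labels == g)]
    merged: dict[int, int] = {}
    i = 0
    while i < len(present):
        g = present[i]
        size = int(np.sum(labels == g))
        if size < min_bins and len(present) > 1:
            tgt = present[i + 1] if i + 1 < len(present) else present[i - 1]
            labels[labels == g] = tgt
            present.pop(i)
            if tgt < g:
                i = max(i - 1, 0)
        else:
            i += 1
    # relabel contiguously
    for new, g in enumerate(sorted(set(labels[labels >= 0]))):
        merged[g] = new
    out = labels.copy()
    for g, new in merged.items():
        out[labels == g] = new
    return out


def _normalize_array(values: np.ndarray, gc: np.ndarray, target: float):
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("cannot normalize: all bin counts are zero")
    lib_scale = target * len(values) / total
    scaled = values * lib_scale

    labels = _gc_strata(gc)
    global_med = float(np.median(scaled))
    factors = np.ones(len(values))
    rows = []
    for g in sorted(set(labels[labels >= 0])):
        mask = labels == g
        f = float(np.median(scaled[mask]) / global_med) if global_med > 0 else 1.0
        factors[mask] = f if f > 0 else 1.0
        rows.append((g, int(mask.sum()), float(gc[mask].min()), float(gc[mask].max()), f))
    # bins with no GC information get the global factor (1 by construction)
    corrected = scaled / factors

    final_scale = target * len(values) / corrected.sum()
    out = corrected * final_scale
    strata = pd.DataFrame(rows, columns=["stratum", "n_bins", "gc_min", "gc_max", "factor"])
    return out, lib_scale * final_scale, factors, strata


def normalize_counts(
    counts: BinCounts,
    genome: GenomeBins | None = None,
    target: float = 500.0,
    matched_normal: BinCounts | None = None,
) -> NormalizedBins:
    """Normalize bin counts for library size and GC content.

    ``target`` is the genome-wide mean of the output (and, on a mostly
    diploid genome, approximately the diploid level).  The diploid baseline
    for log2 ratios is re-estimated from the normalized track by its peak
    structure, which stays on the diploid peak even when aneuploidy drags
    the median or mode off it.

    When a ``matched_normal`` count track is given, tumor counts are first
    divided by the normal's (mean-scaled) per-bin coverage, which cancels
    shared per-bin biases before the GC step; the diploid baseline then
    follows from the normal rather than the sample's own peak structure.
    """
    genome = genome or counts.genome
    genome.require_same_backbone(counts.genome)
    gc = genome.bins["gc"].to_numpy(float)
    raw = counts.counts.astype(float)
    if matched_normal is not None:
        genome.require_same_backbone(matched_normal.genome)
        ref = matched_normal.counts.astype(float)
        if ref.sum() <= 0:
            raise ValueError("matched normal has no reads")
        raw = raw / np.maximum(ref / ref.mean(), 1e-3)
    values, lib_scale, factors, strata = _normalize_array(raw, gc, target)
    mu = estimate_diploid_mean(values)
    log2 = np.log2(np.maximum(values, 1e-6) / mu)
    return NormalizedBins(
        values=values, log2_ratio=log2, genome=genome, sample=counts.sample,
        target=target, diploid_mean=mu, lib_scale=lib_scale,
        gc_factors=factors, strata=strata,
    )


def estimate_diploid_mean(values: np.ndarray, max_state: int = 5) -> float:
    """Diploid level from the peak structure of the normalized-count density.

    A kernel density on the log2 scale (where every copy-number state has
    roughly the same peak width) proposes candidate diploid levels: each
    density peak is tried as each state 1..``max_state``.  Candidates are
    scored by how closely all bins then sit on half-integer copy ratios
    ``k/2``, with a mild pull toward the median scale to break the global
    halving/doubling ambiguity, and the winner is polished by a weighted
    least-squares pass over the implied integer states.  This stays on the
    diploid peak even when aneuploidy makes a gained or lost state the most
    common one; degenerate inputs fall back to the median.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values) & (values > 0)]
    median = float(np.median(finite)) if len(finite) else float(np.median(values))
    if len(finite) < 10 or np.ptp(finite) < 1e-12:
        return median

    try:
        logv = np.log2(finite)
        kde = stats.gaussian_kde(logv)
        grid = np.linspace(logv.min(), logv.max(), 512)
        density = kde(grid)
    except np.linalg.LinAlgError:
        return median
    peak_idx, props = signal.find_peaks(density, height=0.05 * density.max())
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(density))])
        props = {"peak_heights": density[peak_idx]}
    peaks = 2.0 ** grid[peak_idx]
    weights = props["peak_heights"]

    candidates = {median}
    for peak in peaks:
        for k in range(1, max_state + 1):
            mu = 2.0 * peak / k
            if median / 3.0 <= mu <= median * 3.0:
                candidates.add(float(mu))

    def score(mu: float) -> float:
        # a correct baseline places *every* density peak on a half-integer
        # copy ratio; scoring the few sharp peak positions (height-weighted)
        # avoids the residual-truncation artifacts of scoring all bins
        ratio = 2.0 * peaks / mu
        nearest = np.clip(np.round(ratio), 0, max_state)
        lattice = float(np.average((ratio - nearest) ** 2, weights=weights))
        return lattice + 0.05 * np.log2(mu / median) ** 2

    best = min(sorted(candidates), key=score)

    # polish: weighted LS of value ~ (mu/2) * state over confidently assigned bins
    states = np.round(2.0 * finite / best)
    keep = (states >= 1) & (states <= max_state)
    if keep.sum() >= 10:
        k = states[keep]
        best = float(2.0 * np.sum(finite[keep] * k) / np.sum(k * k))
    return best


def mom_dispersion(mu: float, s2: float, clamp: tuple[float, float] = (1.0, 1e6)) -> float:
    """NB size from moments: ``mu**2 / (s2 - mu)``, clamped; upper clamp if s2 <= mu."""
    lo, hi = clamp
    if s2 <= mu:
        return hi
    return float(np.clip(mu * mu / (s2 - mu), lo, hi))


def _running_median(values: np.ndarray, chrom_idx: np.ndarray, window: int = 5) -> np.ndarray:
    h = window // 2
    out = np.empty(len(values))
    for code in np.unique(chrom_idx):
        pos = np.flatnonzero(chrom_idx == code)
        vals = values[pos]
        for j in range(len(pos)):
            lo, hi = max(0, j - h), min(len(pos), j + h + 1)
            out[pos[j]] = np.median(vals[lo:hi])
    return out


def estimate_dispersion(norm: NormalizedBins, clamp: tuple[float, float] = (1.0, 1e6)) -> float:
    """Method-of-moments NB size on the modal-copy-number subset.

    Bins are assigned to copy states by rounding a running-median-smoothed
    copy ratio (window 5 within chromosome); the modal state's bins form the
    subset and ``r = mu**2 / (s2 - mu)`` is computed from their *raw*
    normalized values.  Smoothed assignment matters: selecting on the raw
    values would clip their own tails and bias the variance (hence ``r``)
    badly.  Poisson-like data (variance <= mean) returns the upper clamp.
    """
    if norm.n_bins < 100:
        raise ValueError("dispersion estimation needs at least 100 bins")
    smoothed = _running_median(norm.values, norm.genome.chrom_index())
    assigned = np.round(2.0 * smoothed / norm.diploid_mean).astype(int)
    modal = np.bincount(assigned[assigned >= 0]).argmax()
    subset = norm.values[assigned == modal]
    if len(subset) < 2:
        subset = norm.values
    mu = float(subset.mean())
    s2 = float(subset.var(ddof=1))
    return mom_dispersion(mu, s2, clamp)
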