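"""Genomic bin backbone, karyotype specifications and copy-number profiles.

All read-depth work in this package is expressed on a fixed-width bin grid
(default 500 kb, the resolution limit of the CNV analysis).  A
:class:`GenomeBins` object is the coordinate backbone shared by simulated
counts, normalized counts, caller results and consensus profiles; two objects
are compatible only when their bin tables are identical.

Karyotypes are written as ordered lists of ``(region, copy_number)`` entries
where a region is a chromosome (``"chr8"``) or a chromosome arm (``"chr8p"``).
Unlisted regions are diploid and later entries override earlier ones on
overlap, so a whole-chromosome gain can be carved by a subsequent arm-level
loss.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBins",
    "KaryotypeSpec",
    "CopyNumberProfile",
    "BinCounts",
    "make_genome",
    "make_karyotype_profile",
    "toy_genome",
    "grch38_genome",
    "GRCH38_AUTOSOME_LENGTHS",
    "GRCH38_ARM_BOUNDARIES",
    "TUMOR_KARYOTYPE",
    "CELL_LINE_KARYOTYPE",
]

DEFAULT_BIN_WIDTH = 500_000
DEFAULT_STATES = (0, 1, 2, 3, 4, 5)

#: GRCh38 autosome lengths (bp), packaged so realistic-scale runs need no download.
GRCH38_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468,
}

#: p/q arm boundaries (bp) at the GRCh38 cytoband centromere position.
GRCH38_ARM_BOUNDARIES: dict[str, int] = {
    "chr1": 123_400_000, "chr2": 93_900_000, "chr3": 90_900_000,
    "chr4": 50_000_000, "chr5": 48_800_000, "chr6": 59_800_000,
    "chr7": 60_100_000, "chr8": 45_200_000, "chr9": 43_000_000,
    "chr10": 39_800_000, "chr11": 53_400_000, "chr12": 35_500_000,
    "chr13": 17_700_000, "chr14": 17_200_000, "chr15": 19_000_000,
    "chr16": 36_800_000, "chr17": 25_100_000, "chr18": 18_500_000,
    "chr19": 26_200_000, "chr20": 28_100_000, "chr21": 12_000_000,
    "chr22": 15_000_000,
}

_REGION_RE = re.compile(r"^(?:chr\.?|ch\.?)?\s*([0-9XYxy]+)\s*([pq]?)$", re.IGNORECASE)


def _normalize_chrom(label: str) -> str:
    m = re.match(r"^(?:chr\.?|ch\.?)?\s*(.+)$", label.strip(), re.IGNORECASE)
    return m.group(1).lower() if m else label.strip().lower()


def parse_region(label: str) -> tuple[str, str | None]:
    """Split a region label like ``"Chr.7p"`` into (chromosome key, arm or None)."""
    m = _REGION_RE.match(label.strip())
    if m is None:
        raise ValueError(f"unrecognized region label: {label!r}")
    arm = m.group(2).lower() or None
    return m.group(1).lower(), arm


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width genomic intervals (0-based half-open) with a GC fraction.

    Parameters
    ----------
    bins
        DataFrame with columns ``chrom``, ``start``, ``end``, ``gc``; bins are
        sorted and non-overlapping within each chromosome, and every bin but
        the last per chromosome has length ``bin_width``.
    bin_width
        Nominal bin width in bp.
    arm_boundaries
        Per-chromosome p/q boundary in bp, used to resolve arm-level regions.
    """

    bins: pd.DataFrame
    bin_width: int = DEFAULT_BIN_WIDTH
    arm_boundaries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gc"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"bin table missing columns: {sorted(missing)}")
        gc = self.bins["gc"].to_numpy(float)
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("gc fractions must lie in [0, 1]")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if np.any(e <= s) or np.any(s[1:] < e[:-1]):
                raise ValueError(f"bins on {chrom} are unsorted or overlapping")
            if np.any((e - s)[:-1] != self.bin_width):
                raise ValueError(f"interior bins on {chrom} must have length {self.bin_width}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def bin_lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    @property
    def total_length(self) -> int:
        return int(self.bin_lengths().sum())

    def chrom_index(self) -> np.ndarray:
        """Integer chromosome index per bin, in table order."""
        cats = pd.Categorical(self.bins["chrom"], categories=self.chroms)
        return np.asarray(cats.codes)

    def _chrom_key_map(self) -> dict[str, str]:
        return {_normalize_chrom(c): c for c in self.chroms}

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of bins covered by a chromosome or chromosome-arm label.

        A bin is assigned to an arm by its midpoint relative to the
        chromosome's ``arm_boundaries`` entry.
        """
        key, arm = parse_region(region)
        chrom = self._chrom_key_map().get(key)
        if chrom is None:
            raise ValueError(f"region {region!r}: chromosome {key!r} not in genome")
        mask = (self.bins["chrom"] == chrom).to_numpy()
        if arm is None:
            return mask
        boundary = self.arm_boundaries.get(chrom)
        if boundary is None:
            raise ValueError(f"region {region!r}: no arm boundary defined for {chrom}")
        mid = ((self.bins["start"] + self.bins["end"]) // 2).to_numpy()
        return mask & ((mid < boundary) if arm == "p" else (mid >= boundary))

    def same_backbone(self, other: "GenomeBins") -> bool:
        a = self.bins[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.bins[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    def require_same_backbone(self, other: "GenomeBins") -> None:
        if not self.same_backbone(other):
            raise ValueError("genomic bin backbones differ")


@dataclass(frozen=True)
class KaryotypeSpec:
    """Ordered ``(region, copy_number)`` list; unlisted regions default to 2."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for region, cn in self.entries:
            parse_region(region)  # validates the label shape
            if cn < 0:
                raise ValueError(f"copy number for {region!r} must be >= 0, got {cn}")

    @classmethod
    def from_pairs(cls, pairs) -> "KaryotypeSpec":
        return cls(tuple((str(r), int(c)) for r, c in pairs))


@dataclass(frozen=True)
class CopyNumberProfile:
    """Integer copy-number state per bin on a :class:`GenomeBins` backbone."""

    states: np.ndarray
    genome: GenomeBins
    sample: str = "sample"
    state_set: tuple[int, ...] = DEFAULT_STATES

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "states", states)
        if len(states) != self.genome.n_bins:
            raise ValueError("profile length does not match the genome bin count")
        if not np.isin(states, self.state_set).all():
            bad = sorted(set(states) - set(self.state_set))
            raise ValueError(f"states {bad} outside the configured state set {self.state_set}")


@dataclass(frozen=True)
class BinCounts:
    """Per-bin non-negative read counts for one sample."""

    counts: np.ndarray
    genome: GenomeBins
    sample: str = "sample"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) != self.genome.n_bins:
            raise ValueError("count vector length does not match the genome bin count")
        if np.any(counts < 0):
            raise ValueError("bin counts must be non-negative")


def make_genome(
    chrom_lengths: dict[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
    gc_model: dict | None = None,
    seed: int = 0,
    arm_boundaries: dict[str, int] | None = None,
) -> GenomeBins:
    """Build a binned genome with a smooth, seeded GC track.

    The GC fraction follows a long-wavelength sine wave (emulating isochore
    structure) plus small seeded jitter, clipped to ``gc_model["bounds"]``
    (default ``[0.3, 0.7]``).  Deterministic for a fixed seed.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    gc_model = dict(gc_model or {})
    base = gc_model.get("base", 0.42)
    amplitude = gc_model.get("amplitude", 0.08)
    period_bp = gc_model.get("period_bp", 30_000_000)
    noise_sd = gc_model.get("noise_sd", 0.02)
    lo, hi = gc_model.get("bounds", (0.3, 0.7))

    rng = np.random.default_rng(seed)
    records = []
    for ci, (chrom, length) in enumerate(chrom_lengths.items()):
        starts = np.arange(0, length, bin_width)
        ends = np.minimum(starts + bin_width, length)
        mids = (starts + ends) / 2
        phase = rng.uniform(0, 2 * np.pi)
        gc = base + amplitude * np.sin(2 * np.pi * mids / period_bp + phase)
        gc = gc + rng.normal(0.0, noise_sd, size=len(starts))
        gc = np.clip(gc, lo, hi)
        records.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "gc": gc}))
    bins = pd.concat(records, ignore_index=True)

    if arm_boundaries is None:
        arm_boundaries = {c: length // 2 for c, length in chrom_lengths.items()}
    return GenomeBins(bins=bins, bin_width=bin_width, arm_boundaries=dict(arm_boundaries))


def toy_genome(seed: int = 0, bin_width: int = DEFAULT_BIN_WIDTH) -> GenomeBins:
    """Six desk-scale chromosomes (20–60 Mb) with arm boundaries at the midpoint."""
    lengths = {
        "chr1": 60_000_000, "chr2": 50_000_000, "chr3": 45_000_000,
        "chr4": 35_000_000, "chr5": 25_000_000, "chr6": 20_000_000,
    }
    return make_genome(lengths, bin_width=bin_width, seed=seed)


def grch38_genome(seed: int = 0, bin_width: int = DEFAULT_BIN_WIDTH) -> GenomeBins:
    """Full-scale autosomal GRCh38 backbone with cytoband arm boundaries."""
    return make_genome(
        GRCH38_AUTOSOME_LENGTHS,
        bin_width=bin_width,
        seed=seed,
        arm_boundaries=GRCH38_ARM_BOUNDARIES,
    )


def make_karyotype_profile(
    genome: GenomeBins,
    spec: KaryotypeSpec,
    sample: str = "sample",
    state_set: tuple[int, ...] = DEFAULT_STATES,
) -> CopyNumberProfile:
    """Render a karyotype spec onto a bin backbone; unlisted bins are diploid."""
    states = np.full(genome.n_bins, 2, dtype=int)
    for region, cn in spec.entries:
        if cn not in state_set:
            raise ValueError(f"copy number {cn} for {region!r} outside state set {state_set}")
        mask = genome.region_mask(region)
        states[mask] = cn
    return CopyNumberProfile(states=states, genome=genome, sample=sample, state_set=state_set)


# Karyotype fixtures for the rectal-adenocarcinoma study system: the original
# tumor and the cell line derived from it.  Rows are kept in published order so
# that the whole-chromosome chr8 gain is overridden by the later 8p loss.  The
# "3–4" mixed rows are encoded as state 3 (no sub-clonal fraction is given);
# pass state 4 explicitly to explore the alternative.
TUMOR_KARYOTYPE = KaryotypeSpec.from_pairs([
    ("chr7p", 5), ("chr13q", 5),
    ("chr1", 3), ("chr20", 3),
    ("chr3", 3), ("chr6", 3), ("chr7q", 3), ("chr8", 3), ("chr9", 3),
    ("chr10", 3), ("chr11q", 3),
    ("chr4q", 1), ("chr8p", 1), ("chr15q", 1), ("chr18", 1),
])

CELL_LINE_KARYOTYPE = KaryotypeSpec.from_pairs([
    ("chr19q", 3),
    ("chr5", 3), ("chr11p", 3), ("chr15q", 3), ("chr20p", 3),
    ("chr1p", 1), ("chr2q", 1), ("chr4", 1), ("chr6", 1), ("chr9q", 1),
    ("chr13", 1), ("chr11q", 1), ("chr21", 1), ("chr22", 1),
])
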