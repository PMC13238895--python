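"""Consensus CNV calls, segments, pathogenicity classes and profile diffs.

A bin enters the consensus only when at least ``min_support`` callers agree
on the *direction* of the aberration (gain vs loss relative to the diploid
baseline); the reported state is then the most frequent state among the
agreeing callers.  Direction, not exact copy number, is what the downstream
pathogenicity classifier consumes, so directional agreement is the natural
consensus currency.  Maximal runs of equal consensus state become segments,
which are classified as benign / uncertain / pathogenic by thresholding a
structural-variant pathogenicity score in [0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .callers import CallerResult
from .genome import CopyNumberProfile, GenomeBins

__all__ = [
    "ConsensusProfile",
    "CNVSegment",
    "AnnotatedVariant",
    "ProfileDiff",
    "consensus_calls",
    "segment_profile",
    "classify_isv",
    "classify_segments",
    "stub_isv_score",
    "filter_variants",
    "compare_profiles",
    "aberrant_fraction",
]

ISV_CATEGORIES = ("benign", "uncertain", "pathogenic")
IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_PATHOGENIC_LABELS = {"likely_pathogenic", "pathogenic"}


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-bin consensus state with the number of supporting callers."""

    states: np.ndarray
    support: np.ndarray
    genome: GenomeBins
    callers: tuple[str, ...]
    baseline: int = 2
    min_support: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=int))
        object.__setattr__(self, "support", np.asarray(self.support, dtype=int))
        aberrant = self.states != self.baseline
        if np.any(self.support[aberrant] < self.min_support):
            raise ValueError("aberrant consensus bin with support below min_support")

    def as_profile(self, sample: str = "consensus") -> CopyNumberProfile:
        return CopyNumberProfile(states=self.states, genome=self.genome, sample=sample)


def _direction_consensus(
    states: np.ndarray, baseline: int, min_support: int
) -> tuple[int, int]:
    """Consensus (state, support) for the caller states of one bin."""
    gains = states[states > baseline]
    losses = states[states < baseline]
    n_gain, n_loss = len(gains), len(losses)
    if max(n_gain, n_loss) < min_support or n_gain == n_loss >= min_support:
        return baseline, max(n_gain, n_loss)
    agreeing = gains if n_gain > n_loss or n_loss < min_support else losses
    counts = Counter(agreeing.tolist())
    top = max(counts.values())
    # mode; ties broken toward the state closer to baseline, then the lower state
    state = min(
        (s for s, c in counts.items() if c == top),
        key=lambda s: (abs(s - baseline), s),
    )
    return int(state), len(agreeing)


def consensus_calls(
    results: list[CallerResult],
    min_support: int = 2,
    baseline: int = 2,
) -> ConsensusProfile:
    """Combine caller results; a bin is aberrant only with multi-caller support.

    ``support`` records, per bin, the number of callers voting in the winning
    direction (or, for baseline bins, the largest single-direction vote that
    fell short).  Opposite-direction votes never reinforce each other: one
    gain plus one loss is no consensus.
    """
    if len(results) < 2:
        raise ValueError("consensus needs at least two callers")
    genome = results[0].genome
    for r in results[1:]:
        genome.require_same_backbone(r.genome)
    mat = np.stack([r.states for r in results])
    states = np.empty(genome.n_bins, dtype=int)
    support = np.empty(genome.n_bins, dtype=int)
    for i in range(genome.n_bins):
        states[i], support[i] = _direction_consensus(mat[:, i], baseline, min_support)
    return ConsensusProfile(
        states=states, support=support, genome=genome,
        callers=tuple(r.caller for r in results),
        baseline=baseline, min_support=min_support,
    )


@dataclass(frozen=True)
class CNVSegment:
    """Maximal run of equal copy-number state on one chromosome."""

    chrom: str
    start: int
    end: int
    state: int
    n_bins: int
    classification: str = "unclassified"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start or self.n_bins < 1:
            raise ValueError("degenerate segment coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_profile(
    profile: ConsensusProfile | CopyNumberProfile,
    genome: GenomeBins | None = None,
    include_baseline: bool = False,
    baseline: int | None = None,
) -> list[CNVSegment]:
    """Collapse a per-bin profile into maximal equal-state segments.

    By default baseline (diploid) runs are omitted, yielding the CNV list;
    ``include_baseline=True`` returns the full segmentation.
    """
    genome = genome or profile.genome
    genome.require_same_backbone(profile.genome)
    if baseline is None:
        baseline = getattr(profile, "baseline", 2)
    states = profile.states
    bins = genome.bins
    chrom_idx = genome.chrom_index()
    segments: list[CNVSegment] = []
    boundaries = np.flatnonzero(
        np.diff(chrom_idx) != 0) + 1
    breaks = np.flatnonzero(np.diff(states) != 0) + 1
    cut = np.unique(np.concatenate([[0], boundaries, breaks, [len(states)]]))
    for lo, hi in zip(cut[:-1], cut[1:]):
        state = int(states[lo])
        if not include_baseline and state == baseline:
            continue
        segments.append(CNVSegment(
            chrom=str(bins["chrom"].iloc[lo]),
            start=int(bins["start"].iloc[lo]),
            end=int(bins["end"].iloc[hi - 1]),
            state=state,
            n_bins=int(hi - lo),
        ))
    return segments


def segments_to_frame(segments: list[CNVSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end, "state": s.state,
        "n_bins": s.n_bins, "classification": s.classification, "score": s.score,
    } for s in segments])


def classify_isv(score: float) -> str:
    """Threshold a structural-variant pathogenicity score into three classes.

    Intervals are half-open, closed on the left — benign [0, 0.05),
    uncertain [0.05, 0.95), pathogenic [0.95, 1] — so the map is
    deterministic and monotone in the score.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"ISV score must lie in [0, 1], got {score}")
    if score < 0.05:
        return "benign"
    if score < 0.95:
        return "uncertain"
    return "pathogenic"


def stub_isv_score(segment: CNVSegment, scale_bp: float = 50e6) -> float:
    """Deterministic demo scorer: ``min(1, |state - 2| * length / scale_bp)``.

    Non-biological pipeline plumbing only — it lets the classify stage run on
    synthetic data.  Real scores come from an external structural-variant
    pathogenicity model and are supplied per segment.
    """
    return float(min(1.0, abs(segment.state - 2) * segment.length / scale_bp))


def classify_segments(
    segments: list[CNVSegment],
    scores: list[float] | None = None,
) -> list[CNVSegment]:
    """Attach scores and threshold classes; without scores, the demo scorer."""
    if scores is None:
        scores = [stub_isv_score(s) for s in segments]
    if len(scores) != len(segments):
        raise ValueError("one score per segment required")
    return [
        replace(s, score=float(sc), classification=classify_isv(float(sc)))
        for s, sc in zip(segments, scores)
    ]


@dataclass(frozen=True)
class AnnotatedVariant:
    """Annotated somatic small variant with per-tool pathogenicity labels."""

    gene: str
    hgvsc: str = ""
    hgvsp: str = ""
    impact: str = "MODIFIER"
    tool_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise ValueError(
                f"unknown impact label {self.impact!r}; expected one of {IMPACT_LEVELS}"
            )

    @property
    def retained(self) -> bool:
        """Retention rule: high/moderate impact, or any (likely) pathogenic call."""
        if self.impact in ("HIGH", "MODERATE"):
            return True
        return any(
            str(label).strip().lower().replace(" ", "_") in _PATHOGENIC_LABELS
            for label in self.tool_calls.values()
        )


def filter_variants(variants: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep variants with high/moderate impact or a (likely) pathogenic tool call."""
    return [v for v in variants if v.retained]


@dataclass(frozen=True)
class ProfileDiff:
    """Per-bin comparison of two consensus profiles on one backbone.

    ``normalized`` bins were aberrant in profile *a* but diploid in *b* —
    the direction used when asking how a knockout's landscape relaxed
    relative to its parental line.
    """

    category: np.ndarray  # per-bin: equal_baseline/a_only/b_only/shared_equal/shared_diff
    bins: dict[str, int]
    lengths_bp: dict[str, int]
    aberrant_bins: dict[str, int]
    aberrant_bp: dict[str, int]

    @property
    def normalized_bins(self) -> int:
        return self.bins["a_only"]

    def to_dict(self) -> dict:
        return {
            "bins": dict(self.bins),
            "lengths_bp": dict(self.lengths_bp),
            "normalized_bins": self.normalized_bins,
            "aberrant_bins": dict(self.aberrant_bins),
            "aberrant_bp": dict(self.aberrant_bp),
        }


def compare_profiles(a: ConsensusProfile, b: ConsensusProfile) -> ProfileDiff:
    """Summarize where two profiles differ: gains/losses unique or shared."""
    a.genome.require_same_backbone(b.genome)
    if a.baseline != b.baseline:
        raise ValueError("profiles use different baselines")
    base = a.baseline
    lengths = a.genome.bin_lengths()
    ab_a = a.states != base
    ab_b = b.states != base
    category = np.full(a.genome.n_bins, "equal_baseline", dtype=object)
    category[ab_a & ~ab_b] = "a_only"
    category[~ab_a & ab_b] = "b_only"
    category[ab_a & ab_b & (a.states == b.states)] = "shared_equal"
    category[ab_a & ab_b & (a.states != b.states)] = "shared_diff"
    bins = {}
    bp = {}
    for name in ("equal_baseline", "a_only", "b_only", "shared_equal", "shared_diff"):
        mask = category == name
        bins[name] = int(mask.sum())
        bp[name] = int(lengths[mask].sum())
    return ProfileDiff(
        category=category,
        bins=bins,
        lengths_bp=bp,
        aberrant_bins={"a": int(ab_a.sum()), "b": int(ab_b.sum())},
        aberrant_bp={"a": int(lengths[ab_a].sum()), "b": int(lengths[ab_b].sum())},
    )


def aberrant_fraction(
    profile: ConsensusProfile | CopyNumberProfile,
    genome: GenomeBins | None = None,
    baseline: int = 2,
) -> float:
    """Fraction of genome length (bp) in a non-diploid state."""
    genome = genome or profile.genome
    genome.require_same_backbone(profile.genome)
    lengths = genome.bin_lengths()
    return float(lengths[profile.states != baseline].sum() / lengths.sum())
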