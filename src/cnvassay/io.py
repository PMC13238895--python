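"""Plain-text readers/writers for the pipeline's tabular formats.

Bins travel as BED-like TSV (chrom, start, end, name, gc[, count]),
copy-number profiles and segments as SEG-style TSV, segments additionally as
BED, and assay tables as headered CSV.  Every writer can prepend ``#``
comment lines recording tool version, config hash and seed so any output
file identifies the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import CNVSegment, ConsensusProfile, segments_to_frame
from .genome import BinCounts, CopyNumberProfile, GenomeBins

__all__ = [
    "write_table", "read_table", "write_bins", "read_bins",
    "write_seg", "read_seg", "write_segments_bed", "run_header", "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_header(seed: int | None = None, cfg_hash: str | None = None) -> list[str]:
    from . import __version__

    lines = [f"cnvassay {__version__}"]
    if cfg_hash is not None:
        lines.append(f"config {cfg_hash}")
    if seed is not None:
        lines.append(f"seed {seed}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sep: str = ",",
    header_lines: list[str] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_bins(
    genome: GenomeBins,
    path: str | Path,
    counts: BinCounts | None = None,
    header_lines: list[str] | None = None,
) -> None:
    """5-column BED-like TSV; a 6th column carries counts when given."""
    df = genome.bins[["chrom", "start", "end"]].copy()
    df["name"] = [f"bin{i}" for i in range(genome.n_bins)]
    df["gc"] = genome.bins["gc"].round(6)
    if counts is not None:
        genome.require_same_backbone(counts.genome)
        df["count"] = counts.counts
    write_table(df, path, sep="\t", header_lines=header_lines)


def read_bins(
    path: str | Path,
    bin_width: int | None = None,
    arm_boundaries: dict[str, int] | None = None,
    sample: str = "sample",
):
    """Read a BED-like bin TSV back into a genome (and counts if present)."""
    df = read_table(path, sep="\t")
    widths = (df["end"] - df["start"]).to_numpy()
    if bin_width is None:
        bin_width = int(np.bincount(widths).argmax()) if len(widths) else 0
    genome = GenomeBins(
        bins=df[["chrom", "start", "end", "gc"]].reset_index(drop=True),
        bin_width=bin_width,
        arm_boundaries=arm_boundaries or {},
    )
    if "count" in df.columns:
        return genome, BinCounts(df["count"].to_numpy(), genome, sample=sample)
    return genome, None


def write_seg(
    profile: CopyNumberProfile | ConsensusProfile,
    path: str | Path,
    sample: str | None = None,
    header_lines: list[str] | None = None,
) -> None:
    """SEG-style per-bin TSV: sample, chrom, start, end, state."""
    genome = profile.genome
    df = genome.bins[["chrom", "start", "end"]].copy()
    df.insert(0, "sample", sample or getattr(profile, "sample", "sample"))
    df["state"] = profile.states
    write_table(df, path, sep="\t", header_lines=header_lines)


def read_seg(path: str | Path) -> pd.DataFrame:
    return read_table(path, sep="\t")


def write_segments_bed(
    segments: list[CNVSegment],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """BED: chrom, start, end, state|classification."""
    df = segments_to_frame(segments)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    else:
        df["name"] = df["state"].astype(str) + "|" + df["classification"]
        df = df[["chrom", "start", "end", "name"]]
    write_table(df, path, sep="\t", header_lines=header_lines)
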