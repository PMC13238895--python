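"""End-to-end orchestration: simulate → normalize → call → consensus →
classify → diff → quantify → ELDA → growth, from one YAML configuration.

Every stage is timed and logged to stderr; a stage failure aborts the run
with a stage-named error while earlier outputs stay on disk.  Outputs are
deterministic given (config, seed): each stochastic stage draws from a seed
derived from the run seed, and every output file header records the tool
version, config hash and seed.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import yaml

from . import io, qpcr, simulate, xenograft
from .callers import HmmConfig, call_cnv_hmm, call_cnv_median_window, call_cnv_ratio_threshold
from .consensus import (
    aberrant_fraction, classify_segments, compare_profiles, consensus_calls,
    segment_profile, segments_to_frame,
)
from .elda import elda_fit, elda_heterogeneity_test, elda_single_hit_test
from .genome import (
    CELL_LINE_KARYOTYPE, TUMOR_KARYOTYPE, KaryotypeSpec,
    grch38_genome, make_karyotype_profile, toy_genome,
)
from .normalize import estimate_dispersion, normalize_counts

__all__ = ["load_config", "default_config", "run_pipeline"]

log = logging.getLogger(__name__)

NAMED_KARYOTYPES = {
    "tumor": TUMOR_KARYOTYPE,
    "cell_line": CELL_LINE_KARYOTYPE,
    "diploid": KaryotypeSpec(()),
}


def default_config() -> dict:
    """Packaged demo configuration: Table-style tumor/cell-line karyotype
    fixtures on the desk-scale genome, plus the quantitative assays."""
    return {
        "seed": 0,
        "genome": {"kind": "grch38", "bin_width": 500_000},
        "samples": {
            "tumor": {"karyotype": "tumor"},
            "cell_line": {"karyotype": "cell_line"},
        },
        "depth": 500.0,
        "dispersion": 50.0,
        "gc_bias": {"peak": 0.45, "curvature": 6.0},
        "normalize_target": 500.0,
        "caller": {"p_stay": 0.98, "window": 5},
        "min_support": 2,
        "compare": [["tumor", "cell_line"]],
        "qpcr": {
            "true_rel_expr": {"parental": 1.0, "KO_1C3": 0.0638, "KO_1B6": 0.0878},
            "noise_sd": 0.05,
        },
        "elda": {
            "groups": {"parental": 1.0e-4, "knockout": 1.0e-4},
            "doses": [1_000_000, 100_000, 10_000, 1_000, 100],
            "n_per_dose": 9,
        },
        "growth": {"A": 5.0, "doubling_hours": 18.6, "duration": 144.0,
                   "interval": 3.0, "noise_sd": 0.5},
    }


def load_config(path: str | Path | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


#: mappings of user entries (not nested option groups): replaced, not merged
_REPLACE_KEYS = {"samples", "groups", "true_rel_expr", "compare"}


def _deep_update(base: dict, extra: dict) -> None:
    for key, value in extra.items():
        if (key not in _REPLACE_KEYS and isinstance(value, dict)
                and isinstance(base.get(key), dict)):
            _deep_update(base[key], value)
        else:
            base[key] = value


def _resolve_karyotype(spec) -> KaryotypeSpec:
    if isinstance(spec, str):
        try:
            return NAMED_KARYOTYPES[spec]
        except KeyError:
            raise ValueError(f"unknown named karyotype {spec!r}") from None
    return KaryotypeSpec.from_pairs(spec)


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - stage-named abort is the contract
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def build_genome(cfg: dict, seed: int):
    kind = cfg["genome"].get("kind", "toy")
    bin_width = int(cfg["genome"].get("bin_width", 500_000))
    if kind == "toy":
        return toy_genome(seed=seed, bin_width=bin_width)
    if kind == "grch38":
        return grch38_genome(seed=seed, bin_width=bin_width)
    raise ValueError(f"unknown genome kind {kind!r}")


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the full chain and write outputs plus a JSON summary under ``outdir``."""
    cfg = default_config()
    _deep_update(cfg, config)
    seed = int(cfg["seed"] if seed is None else seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg)
    header = io.run_header(seed=seed, cfg_hash=chash)
    summary: dict = {"seed": seed, "config_hash": chash}

    with _stage("simulate"):
        genome = build_genome(cfg, seed=seed)
        truth, counts = {}, {}
        for i, (name, scfg) in enumerate(sorted(cfg["samples"].items())):
            profile = make_karyotype_profile(
                genome, _resolve_karyotype(scfg["karyotype"]), sample=name)
            truth[name] = profile
            counts[name] = simulate.simulate_bin_counts(
                profile,
                mean_depth_per_diploid_bin=float(scfg.get("depth", cfg["depth"])),
                dispersion=float(scfg.get("dispersion", cfg["dispersion"])),
                gc_bias=cfg["gc_bias"],
                seed=seed + 101 + i,
            )
            io.write_bins(genome, outdir / f"{name}.bins.tsv", counts[name], header)
            io.write_seg(profile, outdir / f"{name}.truth.seg.tsv", header_lines=header)

    with _stage("call"):
        results = {}
        for name, bc in counts.items():
            norm = normalize_counts(bc, genome, target=float(cfg["normalize_target"]))
            hmm_cfg = HmmConfig(
                mu=norm.diploid_mean,
                r=estimate_dispersion(norm),
                p_stay=float(cfg["caller"]["p_stay"]),
            )
            results[name] = [
                call_cnv_hmm(norm, hmm_cfg),
                call_cnv_ratio_threshold(norm),
                call_cnv_median_window(norm, window=int(cfg["caller"]["window"])),
            ]

    with _stage("consensus"):
        profiles = {}
        for name, res in results.items():
            cons = consensus_calls(res, min_support=int(cfg["min_support"]))
            profiles[name] = cons
            io.write_seg(cons.as_profile(name), outdir / f"{name}.consensus.seg.tsv",
                         header_lines=header)
        summary["aberrant_fraction"] = {
            name: aberrant_fraction(p) for name, p in profiles.items()}

    with _stage("classify"):
        seg_counts = {}
        for name, cons in profiles.items():
            segs = classify_segments(segment_profile(cons))
            io.write_segments_bed(segs, outdir / f"{name}.segments.bed", header)
            io.write_table(segments_to_frame(segs), outdir / f"{name}.segments.tsv",
                           sep="\t", header_lines=header)
            counts_by_class = segments_to_frame(segs)
            seg_counts[name] = (
                counts_by_class["classification"].value_counts().to_dict()
                if len(counts_by_class) else {})
        summary["segment_classes"] = seg_counts

    with _stage("diff"):
        diffs = {}
        for a, b in cfg.get("compare", []):
            diff = compare_profiles(profiles[a], profiles[b])
            diffs[f"{a}_vs_{b}"] = diff.to_dict()
        summary["profile_diffs"] = diffs
        (outdir / "profile_diffs.json").write_text(json.dumps(diffs, indent=2))

    with _stage("quantify"):
        plate = simulate.simulate_qpcr_plate(
            cfg["qpcr"]["true_rel_expr"],
            cq_noise_sd=float(cfg["qpcr"].get("noise_sd", 0.0)),
            seed=seed + 211,
        )
        io.write_table(plate, outdir / "qpcr_plate.csv", header_lines=header)
        expr = qpcr.ddcq_fold_change(plate)
        summary["expression"] = [
            {"sample": e.sample, "gene": e.gene,
             "fold_change": e.fold_change,
             "percent_of_calibrator": e.percent_of_calibrator}
            for e in expr
        ]

    with _stage("elda"):
        tables = {}
        for j, (group, freq) in enumerate(sorted(cfg["elda"]["groups"].items())):
            tables[group] = simulate.simulate_dilution_assay(
                float(freq),
                doses=tuple(cfg["elda"]["doses"]),
                n_per_dose=int(cfg["elda"]["n_per_dose"]),
                group=group,
                seed=seed + 307 + j,
            )
        import pandas as pd

        io.write_table(pd.concat(tables.values(), ignore_index=True),
                       outdir / "dilution.csv", header_lines=header)
        elda_out = {}
        for group, table in tables.items():
            fit = elda_fit(table)
            entry = {"frequency": fit.frequency, "one_in_n": fit.one_in_n,
                     "ci_one_in_n": list(fit.ci_one_in_n), "bounded": fit.bounded}
            try:
                test = elda_single_hit_test(table)
                entry["single_hit"] = {"chi_square": test.chi_square,
                                       "p_value": test.p_value, "slope": test.slope}
            except ValueError as exc:
                entry["single_hit"] = {"error": str(exc)}
            elda_out[group] = entry
        if len(tables) >= 2:
            het = elda_heterogeneity_test(tables)
            elda_out["heterogeneity"] = {
                "chi_square": het.chi_square, "df": het.df, "p_value": het.p_value}
        summary["elda"] = elda_out

    with _stage("growth"):
        gcfg = cfg["growth"]
        curve = simulate.simulate_growth_curve(
            A=float(gcfg["A"]),
            B=np.log(2) / float(gcfg["doubling_hours"]),
            duration=float(gcfg["duration"]),
            interval=float(gcfg.get("interval", 3.0)),
            noise_sd=float(gcfg.get("noise_sd", 0.0)),
            seed=seed + 401,
        )
        io.write_table(curve, outdir / "growth_curve.csv", header_lines=header)
        fit = xenograft.doubling_time(curve)
        summary["growth"] = {
            "doubling_time_hours": fit.doubling_time_hours,
            "r_squared": fit.r_squared,
            "window": list(fit.window),
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
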