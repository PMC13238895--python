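"""Call copy-number states from simulated binned read counts, end to end.

Simulates negative-binomial read counts over the packaged cell-line
karyotype, normalizes for library size and GC, runs the NB-HMM plus the two
reference callers, and reports consensus segments with threshold
pathogenicity classes.
"""

import cnvassay as ca

genome = ca.grch38_genome(seed=11)
truth = ca.make_karyotype_profile(genome, ca.CELL_LINE_KARYOTYPE)
counts = ca.simulate_bin_counts(truth, mean_depth_per_diploid_bin=500,
                                dispersion=50, seed=12)

norm = ca.normalize_counts(counts, genome)
print(f"diploid baseline estimate: {norm.diploid_mean:.1f} "
      f"(reads per 500 kb bin at copy number 2)")
print(f"NB size estimate:          {ca.estimate_dispersion(norm):.1f}")

hmm = ca.call_cnv_hmm(norm)
callers = [hmm, ca.call_cnv_ratio_threshold(norm), ca.call_cnv_median_window(norm)]
consensus = ca.consensus_calls(callers, min_support=2)

for res in callers:
    acc = (res.states == truth.states).mean()
    print(f"caller {res.caller:<7s} per-bin accuracy vs truth: {acc:.4f}")
print(f"consensus (>=2 callers)  per-bin accuracy vs truth: "
      f"{(consensus.states == truth.states).mean():.4f}")

segments = ca.classify_segments(ca.segment_profile(consensus))
print(f"\n{len(segments)} consensus CNV segments; first five:")
for seg in segments[:5]:
    print(f"  {seg.chrom}:{seg.start}-{seg.end}  state {seg.state}  "
          f"{seg.n_bins} bins  {seg.classification} (demo score {seg.score:.2f})")
print(f"\naberrant genome fraction: {ca.aberrant_fraction(consensus):.3f}")
print("(fraction of autosomal length not at the diploid two-copy state)")
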