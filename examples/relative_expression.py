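"""Relative expression by the 2^-ddCq method on a simulated qPCR plate.

Simulates a Cq plate for a parental line and two knockouts with known
residual expression (6.38% and 8.78% of parental), runs the ddCq chain with
two reference genes, and reports fold changes and fold reductions.
"""

import cnvassay as ca

plate = ca.simulate_qpcr_plate(
    true_rel_expr={"parental": 1.0, "ko_1c3": 0.0638, "ko_1b6": 0.0878},
    reference_genes=("HPRT1", "COPE"),
    cq_noise_sd=0.0,
    seed=0,
)
print(f"simulated plate: {len(plate)} wells "
      f"({plate['sample'].nunique()} samples x genes x 4 replicates)\n")

for e in ca.ddcq_fold_change(plate, calibrator="parental"):
    line = (f"{e.sample:<9s} ddCq {e.delta_delta_cq:+6.3f}  "
            f"fold change {e.fold_change:.4f}  "
            f"({e.percent_of_calibrator:.2f}% of parental)")
    if e.fold_change < 1:
        line += f"  -> {ca.fold_reduction(e.fold_change)}-fold reduction"
    print(line)

print("\nA fold change of 0.0638 means the knockout retains 6.38% of the "
      "parental transcript level, i.e. a 15.7-fold knockdown.")
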