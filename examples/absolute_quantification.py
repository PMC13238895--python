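"""Absolute qPCR quantification of human DNA via a standard curve.

Fits a 5-point 5-fold serial dilution series, reports slope/efficiency, and
quantifies unknown micrometastasis samples, flagging signals outside the
curve's dynamic range.
"""

import numpy as np

import cnvassay as ca
from cnvassay.qpcr import micrometastasis_positive

# perfect-efficiency series: Cq drops log2(5) cycles per 5-fold step
quantities = np.array([100.0, 20.0, 4.0, 0.8, 0.16])  # ng human gDNA
cqs = 22.0 - np.log10(quantities) / np.log10(2)

curve = ca.fit_standard_curve(quantities, cqs)
print(f"standard curve: slope {curve.slope:.4f} cycles/decade, "
      f"efficiency {100 * curve.efficiency:.1f}%, R^2 {curve.r_squared:.4f}")
print(f"dynamic range: {curve.quantity_range[0]}-{curve.quantity_range[1]} ng\n")

unknowns = {"lung A": 18.5, "liver A": 23.8, "spleen A": 31.0}
for tissue, cq in unknowns.items():
    q = ca.absolute_quantity(curve, cq)
    flag = "  [extrapolated: outside the standard range]" if q.extrapolated else ""
    print(f"{tissue:<9s} Cq {cq:5.1f} -> {q.quantity:8.4f} ng human gDNA{flag}")

replicates = [18.5, 18.7, 18.4]
print(f"\nlung A positivity over 3 technical replicates: "
      f"{micrometastasis_positive(curve, replicates)}")
print("(a tissue counts as metastasis-positive when >= 2 of 3 replicates "
      "interpolate inside the curve's dynamic range)")
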