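"""Compare two copy-number landscapes bin by bin.

Renders the packaged tumor and derived cell-line karyotypes on the GRCh38
backbone and summarizes where they agree, where they differ, and which
regions 'normalized' (aberrant in the first profile, diploid in the second).
"""

import numpy as np

import cnvassay as ca
from cnvassay.consensus import ConsensusProfile

genome = ca.grch38_genome(seed=0)
tumor = ca.make_karyotype_profile(genome, ca.TUMOR_KARYOTYPE)
cell_line = ca.make_karyotype_profile(genome, ca.CELL_LINE_KARYOTYPE)


def as_consensus(profile):
    support = np.where(profile.states != 2, 3, 0)
    return ConsensusProfile(states=profile.states, support=support,
                            genome=genome, callers=("truth",))


diff = ca.compare_profiles(as_consensus(tumor), as_consensus(cell_line))
print("tumor vs derived cell line, per 500 kb bin:")
for key, count in diff.bins.items():
    mb = diff.lengths_bp[key] / 1e6
    print(f"  {key:<14s} {count:5d} bins  ({mb:8.1f} Mb)")
print(f"\n'normalized' bins (aberrant in tumor, diploid in cell line): "
      f"{diff.normalized_bins}")
print(f"aberrant fraction  tumor: {ca.aberrant_fraction(tumor):.3f}   "
      f"cell line: {ca.aberrant_fraction(cell_line):.3f}")
print("(the cell line kept part of the tumor's landscape, lost some events, "
      "and acquired new single-copy losses during culture)")
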