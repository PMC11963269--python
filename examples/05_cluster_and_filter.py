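"""Cluster LTRs at 90% identity and apply the 2% PRARE size filter.

Three families of LTRs form three clusters; an element whose LTR deviates by
2.2% from its cluster's consensus size is excluded from the PRARE set.
"""

import numpy as np

from prare.clustering import cluster_ltrs, consensus_sizes, prare_filter
from prare.seqtools import random_dna, substitute_dna


class Sized:
    def __init__(self, ltr, internal):
        self.ltr_size, self.internal_size = ltr, internal


rng = np.random.default_rng(11)
seqs, elements = {}, {}
for fam in range(3):
    ltr = random_dna(rng, 500)
    for k in range(4):
        eid = f"fam{fam}_copy{k}"
        seqs[eid] = substitute_dna(rng, ltr, range(0, 3 * k, 3))  # <= 98.8% identity
        elements[eid] = Sized(500, 10_000)
elements["fam0_copy3"] = Sized(511, 10_000)  # 2.2% off the 500-bp consensus

clusters = cluster_ltrs(seqs, identity_cutoff=0.90)
print(f"{len(seqs)} LTRs -> {len(clusters)} clusters")
for cl in clusters:
    consensus_sizes(cl, elements)
    ps = prare_filter(cl, elements, tolerance=0.02)
    print(f"  {cl.cluster_id}: consensus LTR {cl.consensus_ltr_size} bp, "
          f"{len(ps.retained)} PRAREs, excluded: "
          + (", ".join(f"{m} (dev {d:.3f})" for m, d, _ in ps.excluded) or "none"))
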