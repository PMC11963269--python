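"""Reconstruct full elements around RT hits: identical LTR pair + TSD.

One intact element and one diverged-LTR decoy are planted; the builder
recovers the intact element with exact boundaries and rejects the decoy with
a reason code.
"""

import numpy as np

from prare import ElementSpec, GenomeRecord, build_elements, find_rt_hits, plant_element
from prare.io import package_data_path
from prare.rtsearch import load_queries
from prare.seqtools import random_dna

rng = np.random.default_rng(5)
queries = load_queries(package_data_path("retand_rt_queries.synthetic.faa"))
spec = ElementSpec(ltr_length=500, internal_length=9_000, rt_protein=queries[0].sequence)
decoy = ElementSpec(ltr_length=500, internal_length=9_000,
                    rt_protein=queries[0].sequence, ltr_divergence=4)

genome = GenomeRecord("chr1", random_dna(rng, 120_000))
genome, truth = plant_element(genome, spec, 25_000, rng)
genome, _ = plant_element(genome, decoy, 80_000, rng)

hits = find_rt_hits(genome, queries)
elements, rejections = build_elements(genome, hits)
print(f"{len(hits)} RT hits -> {len(elements)} elements, {len(rejections)} rejections")
for e in elements:
    print(f"  element {e.element_span}, LTR {e.ltr_size} bp, TSD '{e.tsd_sequence}', "
          f"boundaries exact: {tuple(e.ltr5_span) == tuple(truth.ltr5_span)}")
for r in rejections:
    print(f"  rejected hit at {r.rt_hit.start:,}: {r.reason} "
          "(diverged LTRs leave no identical pair / matching TSD)")
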