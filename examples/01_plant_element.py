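"""Plant one Retand-like element into a random genome and inspect the truth.

The element gets two identical 600-bp LTRs, a 10-kb internal region with a
gag-pol ORF (GAG-AP-RT-RH-INT), a TRP28-bearing antisense ORF, a tandem
array, and a 5-bp target-site duplication at the insertion point.
"""

import numpy as np

from prare import ElementSpec, GenomeRecord, plant_element
from prare.panels import load_retand_queries
from prare.seqtools import random_dna

rng = np.random.default_rng(0)
genome = GenomeRecord("toy", random_dna(rng, 20_000))
rt = load_retand_queries()[0].seq

spec = ElementSpec(
    ltr_length=600, internal_length=10_000, rt_protein=rt,
    tandem_arrays=((24, 8, "pol-adjacent"),),
)
planted, truth = plant_element(genome, spec, position=8_000, rng_seed=1)

s, e = truth.element_span
print(f"genome grew {len(genome.seq):,} -> {len(planted.seq):,} bp "
      f"(element {e - s:,} bp + {spec.tsd_length}-bp TSD)")
print(f"TSD '{truth.tsd_sequence}' flanks the element: "
      f"{planted.seq[s - 5:s]} ... {planted.seq[e:e + 5]}")
l5, l3 = truth.ltr5_span, truth.ltr3_span
print(f"LTRs at {l5} and {l3} are identical: "
      f"{planted.seq[l5[0]:l5[1]] == planted.seq[l3[0]:l3[1]]}")
print(f"{len(truth.features)} planted features (ORFs, domains, arrays) "
      "recorded with exact spans for recovery tests")
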