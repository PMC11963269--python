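"""Structural annotation of a reconstructed element.

ORFs (sense/antisense relative to the RT reading direction), protein-domain
hits, the POL-3'LTR region and tandem arrays; autonomy is 'complete' only if
GAG, AP, RT, RH and INT are all encoded on sense ORFs.
"""

import numpy as np

from prare import (
    ElementSpec, GenomeRecord, annotate_element, build_elements, find_rt_hits,
    load_profiles, plant_element,
)
from prare.io import package_data_path
from prare.rtsearch import load_queries
from prare.seqtools import random_dna

rng = np.random.default_rng(9)
queries = load_queries(package_data_path("retand_rt_queries.synthetic.faa"))
spec = ElementSpec(
    ltr_length=600, internal_length=10_000, rt_protein=queries[0].sequence,
    pol_3ltr_length=4_600, antisense_orf_lengths=(1_200,),
    tandem_arrays=((24, 10, "pol-adjacent"),), missing_domains=frozenset({"GAG"}),
)
genome = GenomeRecord("chr1", random_dna(rng, 60_000))
genome, truth = plant_element(genome, spec, 25_000, rng)

elements, _ = build_elements(genome, find_rt_hits(genome, queries))
ann = annotate_element(genome, elements[0], load_profiles())
print(f"layout {ann.gag_pol_layout}; autonomy {ann.autonomy} "
      f"(missing: {sorted(ann.missing_domains) or 'none'})")
for o in ann.orfs:
    print(f"  ORF {o.start}-{o.end} ({o.orientation}) domains: "
          f"{sorted(o.domain_names()) or 'none'}")
print(f"POL-3'LTR region: {ann.pol_3ltr_length} bp "
      f"(planted {spec.pol_3ltr_length} bp)")
for t in ann.tandem_arrays:
    if t.period >= 8:
        print(f"  tandem array {t.start}-{t.end}: period {t.period}, {t.copies} copies")
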