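"""Assign candidate RT domains to lineages by NJ clade membership.

Candidates are aligned with the packaged 62-sequence model panel (Retand plus
13 other lineages and a Caulimoviridae outgroup), an NJ tree is built on
p-distances and midpoint-rooted, and each candidate is labelled by the
smallest clean reference clade containing it.  Only Retand-labelled hits
continue through the pipeline.
"""

from prare.panels import load_model_panel, load_retand_queries
from prare.phylo import assign_lineage

panel = {r.id: r.seq for r in load_model_panel()}
queries = load_retand_queries()
athila = next(seq for name, seq in panel.items() if name.startswith("Athila|"))

candidates = {
    "candidate_A": queries[0].seq,   # identical to a Retand query
    "candidate_B": athila,           # an outgroup-lineage RT
}
labels = assign_lineage(candidates, panel)
for name, lineage in labels.items():
    kept = "kept" if lineage == "Retand" else "dropped"
    print(f"{name}: {lineage} -> {kept}")
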