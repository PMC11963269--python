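"""Summary statistics over the packaged reference table of 63 Retand clusters.

Reproduces the published text summaries: LTRs 315-1,194 bp (mean 635),
internal regions 7,380-12,869 bp (mean 10,364), POL-3'LTR minimum 2,933 bp.
"""

from prare import load_reference_cluster_table, summarize_clusters

rows = load_reference_cluster_table()
stats = summarize_clusters(rows)
print(f"{stats['n_clusters']} clusters, {stats['total_copies']} element copies")
for key, label in (("ltr_bp", "LTR"), ("internal_bp", "internal region"),
                   ("pol3ltr_bp", "POL-3'LTR region")):
    s = stats[key]
    print(f"{label}: {s['min']:,}-{s['max']:,} bp, mean {s['mean']:,} bp")
print(f"defective clusters: {stats['defective_clusters']} "
      f"(patterns: {stats['defective_patterns']})")
print(f"TRP28 status over clusters: {stats['trp28_status']}")
print(f"tandem arrays reported across clusters: {stats['total_tandem_arrays']}")
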