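"""End-to-end PRARE discovery pipeline.

Stages: RT-domain search → lineage assignment (keep Retand) → element
reconstruction (identical LTRs + TSD) → LTR clustering at 90% identity →
2% size-deviation filter (the PRARE definition) → structural annotation →
cluster summaries, consensus RT tree and report files.

``run_pipeline`` is a thin composition of the stage modules; every stage is
importable and testable on its own.  All randomness (bootstrap resampling)
derives from the configured seed, and report files are written
deterministically, so identical (input, config) pairs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import rtsearch
from .align import align_panel
from .annotation import annotate_element
from .clustering import (
    cluster_ltrs,
    consensus_sizes,
    pick_representative,
    prare_filter,
)
from .elements import BuilderParams, build_elements
from .io import GenomeRecord, GffFeature, package_data_path, write_fasta, write_gff3
from .phylo import assign_lineage, bootstrap_support, p_distance_matrix
from .profiles import load_profiles
from .report import ClusterSummary, consensus_sequence, summarize_clusters


@dataclass
class PipelineConfig:
    seed: int = 0
    min_score: float = rtsearch.DEFAULT_MIN_SCORE
    min_rt_len: int = rtsearch.RT_MIN_LEN
    max_rt_len: int = rtsearch.RT_MAX_LEN
    window: int = 10_000
    min_ltr: int = 100
    max_ltr: int = 3_000
    tsd_len: int = 5
    tsd_tolerance: tuple = ()
    identity_cutoff: float = 0.90
    size_tolerance: float = 0.02
    min_orf: int = 600
    min_tandem_copies: int = 3
    reported_tandem_min_period: int = 8  # periods below this are chance homopolymer runs
    max_tandem_period: int = 100
    tandem_identity: float = 0.8
    cluster_tree_replicates: int = 1_000
    min_copies_for_tree: int = 10
    sequence_name_keep: str | None = None  # regex; e.g. "^chr" for chromosome-only
    queries_path: str | None = None
    panel_path: str | None = None
    profiles_path: str | None = None


@dataclass
class PipelineResult:
    hits: list = field(default_factory=list)
    lineages: dict = field(default_factory=dict)
    elements: list = field(default_factory=list)
    rejections: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    prare_sets: list = field(default_factory=list)
    annotations: dict = field(default_factory=dict)
    representatives: dict = field(default_factory=dict)
    cluster_summaries: list = field(default_factory=list)
    summary_stats: dict = field(default_factory=dict)
    cluster_tree_newick: str | None = None
    run_log: dict = field(default_factory=dict)

    @property
    def prare_ids(self) -> set:
        return {eid for ps in self.prare_sets for eid in ps.retained}


def _hit_id(hit) -> str:
    return f"{hit.genome_id}:{hit.start}-{hit.end}({hit.strand})"


def _trp28_status(annotation) -> str:
    full = short = False
    for orf in annotation.orfs:
        if orf.orientation != "antisense" or "TRP28" not in orf.domain_names():
            continue
        if orf.short:
            short = True
        else:
            full = True
    return "YES" if full else ("SHORT" if short else "NO")


def _cluster_summary(cluster, prare_set, annotations, config) -> ClusterSummary:
    rep = annotations[cluster.representative_structural]
    core = set()
    other = set()
    for orf in rep.orfs:
        names = orf.domain_names()
        if orf.orientation == "sense":
            core |= names & {"GAG", "AP", "RH", "INT"}
        else:
            other |= names - {"GAG", "AP", "RH", "INT", "RT", "TRP28"}
    arrays = [
        t for t in rep.tandem_arrays if t.period >= config.reported_tandem_min_period
    ]
    return ClusterSummary(
        cluster=cluster.cluster_id,
        copy_number=len(prare_set.retained),
        ltr_bp=cluster.consensus_ltr_size,
        internal_bp=cluster.consensus_internal_size,
        pol3ltr_bp=rep.pol_3ltr_length,
        gag="GAG" in core,
        ap="AP" in core,
        rh="RH" in core,
        int_="INT" in core,
        trp28=_trp28_status(rep),
        other_domains=tuple(sorted(other)),
        tandem_arrays=len(arrays),
    )


def run_pipeline(genomes, config: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Run the full discovery pipeline over a set of genome records."""
    config = config or PipelineConfig()
    result = PipelineResult()
    genomes = list(genomes)
    if config.sequence_name_keep is not None:
        import re

        pat = re.compile(config.sequence_name_keep)
        genomes = [g for g in genomes if pat.search(g.id)]
    if not genomes:
        warnings.warn("no genome sequences to analyse; returning an empty report")
        result.run_log = {"stages": {}, "config": dataclasses.asdict(config)}
        if out_dir is not None:
            _write_outputs(result, genomes, config, out_dir)
        return result

    queries = rtsearch.load_queries(
        config.queries_path or package_data_path("retand_rt_queries.synthetic.faa")
    )
    from .io import read_fasta

    panel = {
        r.id: r.seq
        for r in read_fasta(config.panel_path or package_data_path("model_rt_panel.synthetic.faa"))
    }
    profiles = load_profiles(config.profiles_path)

    # 1. RT-domain search
    by_id = {g.id: g for g in genomes}
    hits = []
    for g in genomes:
        hits.extend(
            rtsearch.find_rt_hits(
                g, queries, config.min_score, config.min_rt_len, config.max_rt_len
            )
        )
    result.hits = hits

    # 2. lineage assignment; only Retand candidates continue
    candidates = {_hit_id(h): h.protein for h in hits}
    result.lineages = assign_lineage(candidates, panel) if candidates else {}
    retand_hits = [h for h in hits if result.lineages.get(_hit_id(h)) == "Retand"]

    # 3. element reconstruction
    params = BuilderParams(
        window=config.window, min_ltr=config.min_ltr, max_ltr=config.max_ltr,
        tsd_len=config.tsd_len, tsd_tolerance=config.tsd_tolerance,
    )
    elements = []
    for g in genomes:
        per = [h for h in retand_hits if h.genome_id == g.id]
        els, rejs = build_elements(g, per, params)
        elements.extend(els)
        result.rejections.extend(rejs)
    result.elements = elements
    by_eid = {e.element_id: e for e in elements}

    # 4. annotation
    for e in elements:
        result.annotations[e.element_id] = annotate_element(
            by_id[e.genome_id], e, profiles,
            min_orf=config.min_orf,
            min_tandem_copies=config.min_tandem_copies,
            max_tandem_period=config.max_tandem_period,
            tandem_identity=config.tandem_identity,
        )

    # 5. clustering + PRARE size filter
    if elements:
        from .seqtools import revcomp

        # cluster LTRs in element-sense orientation so copies inserted on
        # opposite genomic strands land in the same cluster
        oriented_ltrs = {
            e.element_id: (e.ltr_sequence if e.strand == "+" else revcomp(e.ltr_sequence))
            for e in elements
        }
        clusters = cluster_ltrs(oriented_ltrs, config.identity_cutoff)
        for cl in clusters:
            consensus_sizes(cl, by_eid)
            ps = prare_filter(cl, by_eid, config.size_tolerance)
            cl.representative_structural = pick_representative(cl, result.annotations, by_eid)
            result.prare_sets.append(ps)
            result.cluster_summaries.append(
                _cluster_summary(cl, ps, result.annotations, config)
            )
        result.clusters = clusters
        result.summary_stats = summarize_clusters(result.cluster_summaries)

    # 6. cluster consensus RT tree (for clusters with enough copies)
    eligible = []
    for cl, ps in zip(result.clusters, result.prare_sets):
        if len(ps.retained) >= config.min_copies_for_tree:
            rts = {eid: by_eid[eid].rt_hit.protein for eid in ps.retained}
            msa = align_panel(rts)
            eligible.append((cl.cluster_id, consensus_sequence(msa.rows)))
    if len(eligible) >= 3:
        msa = align_panel(dict(eligible))
        tree, _ = bootstrap_support(msa, config.cluster_tree_replicates, config.seed)
        result.cluster_tree_newick = tree.as_string(schema="newick").strip()

    result.run_log = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {
            "genomes": len(genomes),
            "rt_hits": len(hits),
            "retand_hits": len(retand_hits),
            "elements": len(elements),
            "rejections": len(result.rejections),
            "clusters": len(result.clusters),
            "prares": len(result.prare_ids),
        },
    }
    if out_dir is not None:
        _write_outputs(result, genomes, config, out_dir)
    return result


def _membership_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for cl, ps in zip(result.clusters, result.prare_sets):
        devs = {m: (0.0, 0.0) for m in ps.retained}
        devs.update({m: (dl, di) for m, dl, di in ps.excluded})
        for m in sorted(cl.member_ids):
            e = next(e for e in result.elements if e.element_id == m)
            dl = abs(e.ltr_size - cl.consensus_ltr_size) / cl.consensus_ltr_size
            di = (
                abs(e.internal_size - cl.consensus_internal_size)
                / cl.consensus_internal_size
            )
            rows.append(
                {
                    "element_id": m,
                    "cluster_id": cl.cluster_id,
                    "is_prare": m in ps.retained,
                    "ltr_dev": round(dl, 6),
                    "internal_dev": round(di, 6),
                }
            )
    return pd.DataFrame(
        rows, columns=["element_id", "cluster_id", "is_prare", "ltr_dev", "internal_dev"]
    )


def _write_outputs(result: PipelineResult, genomes, config, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hit_rows = [
        {
            "genome": h.genome_id, "start": h.start, "end": h.end, "strand": h.strand,
            "frame": h.frame, "query": h.query_id, "length_aa": h.length_aa,
            "score": h.score, "lineage": result.lineages.get(_hit_id(h), ""),
        }
        for h in sorted(result.hits, key=lambda h: (h.genome_id, h.start))
    ]
    pd.DataFrame(
        hit_rows,
        columns=["genome", "start", "end", "strand", "frame", "query", "length_aa",
                 "score", "lineage"],
    ).to_csv(out / "rt_hits.tsv", sep="\t", index=False)
    with open(out / "rt_hits.bed", "w") as fh:
        for r in hit_rows:
            fh.write(
                f"{r['genome']}\t{r['start']}\t{r['end']}\t{r['query']}\t"
                f"{int(r['score'])}\t{r['strand']}\n"
            )

    pd.DataFrame(
        [
            {"genome": rj.genome_id, "start": rj.rt_hit.start, "end": rj.rt_hit.end,
             "reason": rj.reason}
            for rj in sorted(result.rejections, key=lambda r: (r.genome_id, r.rt_hit.start))
        ],
        columns=["genome", "start", "end", "reason"],
    ).to_csv(out / "rejections.tsv", sep="\t", index=False)

    _membership_frame(result).to_csv(out / "clusters.tsv", sep="\t", index=False)

    by_id = {g.id: g for g in genomes}
    elem_records, ltr_records, gff = [], [], []
    for e in sorted(result.elements, key=lambda e: (e.genome_id, e.element_span)):
        seq = by_id[e.genome_id].seq[e.element_span[0] : e.element_span[1]]
        elem_records.append(GenomeRecord(e.element_id, seq))
        ltr_records.append(GenomeRecord(e.element_id + "|LTR", e.ltr_sequence))
        ann = result.annotations[e.element_id]
        gff.append(
            GffFeature(e.genome_id, "LTR_retrotransposon", *e.element_span, e.strand,
                       attributes={"ID": e.element_id, "tsd": e.tsd_sequence,
                                   "autonomy": ann.autonomy})
        )
        for name, span in (("five_prime_LTR", e.ltr5_span), ("three_prime_LTR", e.ltr3_span)):
            gff.append(
                GffFeature(e.genome_id, name, *span, e.strand,
                           attributes={"Parent": e.element_id})
            )
        for i, orf in enumerate(ann.orfs):
            gspan = ann.to_genome_span((orf.start, orf.end))
            strand = orf.strand if e.strand == "+" else ("-" if orf.strand == "+" else "+")
            attrs = {
                "Parent": e.element_id, "ID": f"{e.element_id}.orf{i}",
                "orientation": orf.orientation,
                "domains": ",".join(sorted(orf.domain_names())) or "none",
            }
            if orf.short:
                attrs["short"] = "true"
            gff.append(GffFeature(e.genome_id, "ORF", *gspan, strand, attributes=attrs))
        for t in ann.tandem_arrays:
            gspan = ann.to_genome_span((t.start, t.end))
            gff.append(
                GffFeature(
                    e.genome_id, "tandem_repeat", *gspan, "+",
                    attributes={"Parent": e.element_id, "period": t.period,
                                "copies": t.copies},
                )
            )
        if ann.pol_3ltr_span is not None:
            gspan = ann.to_genome_span(ann.pol_3ltr_span)
            gff.append(
                GffFeature(e.genome_id, "pol_3ltr_region", *gspan, e.strand,
                           attributes={"Parent": e.element_id})
            )
    write_fasta(elem_records, out / "elements.fasta")
    write_fasta(ltr_records, out / "ltrs.fasta")
    write_gff3(gff, out / "annotations.gff3")

    summary_rows = [dataclasses.asdict(s) for s in result.cluster_summaries]
    pd.DataFrame(summary_rows).to_csv(out / "cluster_summaries.tsv", sep="\t", index=False)

    if result.cluster_tree_newick:
        (out / "cluster_rt_tree.nwk").write_text(result.cluster_tree_newick + "\n")
    (out / "run_log.json").write_text(
        json.dumps({**result.run_log, "summary_stats": _jsonable(result.summary_stats)},
                   indent=1, sort_keys=True)
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
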