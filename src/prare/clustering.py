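"""LTR-identity clustering, consensus sizes, and the PRARE 2% size filter.

Clustering mirrors the greedy incremental strategy of CD-HIT-style tools at
desk scale: sequences are sorted longest-first (ties by id) and each either
joins the first cluster whose *representative* it matches at >= the identity
cutoff (default 90%), or founds a new cluster.  Identity is matches divided
by alignment length of one optimal global alignment — exact, not a k-mer
estimate.

A cluster's consensus LTR and internal sizes are member medians (even counts
take the lower middle value).  An element is a PRARE only if BOTH its LTR and
its internal size deviate from the consensus by at most the tolerance
(default 2%): the published removal rule drops elements whose LTR *or*
internal sequence deviates by more than 2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .elements import LtrElement


@dataclass
class Cluster:
    cluster_id: str
    representative_id: str  # clustering representative (founder)
    member_ids: list
    consensus_ltr_size: int | None = None
    consensus_internal_size: int | None = None
    representative_structural: str | None = None  # set by pick_representative callers

    @property
    def copy_number(self) -> int:
        return len(self.member_ids)


@dataclass
class PrareSet:
    cluster_id: str
    retained: list
    excluded: list  # (element_id, ltr_deviation, internal_deviation)


def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0  # megaBLAST-style nucleotide scoring
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def dna_identity(a: str, b: str, aligner=None) -> float:
    """Matches / alignment length of one optimal global DNA alignment."""
    if a == b:
        return 1.0
    if aligner is None:
        aligner = _dna_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def cluster_ltrs(ltr_sequences: dict, identity_cutoff: float = 0.90) -> list[Cluster]:
    """Greedy incremental clustering of LTR sequences by global identity.

    ``ltr_sequences`` maps element id -> LTR sequence.  Deterministic: input
    order never matters (processing order is length-descending, then id).
    """
    if not ltr_sequences:
        raise ValueError("no LTR sequences to cluster")
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError("identity cutoff must be in (0, 1]")
    aligner = _dna_aligner()
    order = sorted(ltr_sequences, key=lambda k: (-len(ltr_sequences[k]), k))
    clusters: list[Cluster] = []
    for eid in order:
        seq = ltr_sequences[eid]
        placed = False
        for cl in clusters:
            rep_seq = ltr_sequences[cl.representative_id]
            if dna_identity(seq, rep_seq, aligner) >= identity_cutoff:
                cl.member_ids.append(eid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(f"cluster_{len(clusters) + 1}", eid, [eid]))
    return clusters


def _lower_median(values) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def consensus_sizes(cluster: Cluster, elements: dict) -> tuple[int, int]:
    """(consensus LTR size, consensus internal size): member medians.

    Even member counts take the lower middle value.  The result is stored on
    the cluster.
    """
    if not cluster.member_ids:
        raise ValueError("empty cluster")
    ltrs = [elements[m].ltr_size for m in cluster.member_ids]
    internals = [elements[m].internal_size for m in cluster.member_ids]
    cluster.consensus_ltr_size = _lower_median(ltrs)
    cluster.consensus_internal_size = _lower_median(internals)
    return cluster.consensus_ltr_size, cluster.consensus_internal_size


def prare_filter(cluster: Cluster, elements: dict, tolerance: float = 0.02) -> PrareSet:
    """Split members into retained PRAREs and size-deviant excluded elements.

    Retained iff |size - consensus| / consensus <= tolerance for BOTH the LTR
    and the internal size.
    """
    if cluster.consensus_ltr_size is None:
        consensus_sizes(cluster, elements)
    cl, ci = cluster.consensus_ltr_size, cluster.consensus_internal_size
    if not cl or not ci:
        raise ValueError("consensus size is zero")
    retained, excluded = [], []
    for m in cluster.member_ids:
        dl = abs(elements[m].ltr_size - cl) / cl
        di = abs(elements[m].internal_size - ci) / ci
        if dl <= tolerance and di <= tolerance:
            retained.append(m)
        else:
            excluded.append((m, dl, di))
    return PrareSet(cluster.cluster_id, retained, excluded)


def structure_vector(annotation) -> tuple:
    """Structural fingerprint used to pick cluster representatives."""
    orfs = tuple(
        sorted((o.orientation, o.end - o.start >= annotation.min_orf) for o in annotation.orfs)
    )
    domains = frozenset(h.name for o in annotation.orfs for h in o.domain_hits)
    return (orfs, domains, len(annotation.tandem_arrays))


def pick_representative(cluster: Cluster, annotations: dict, elements: dict) -> str:
    """The member whose structure matches the cluster's modal structure.

    Ties are broken by smallest total size deviation from the consensus, then
    lexicographic element id; deterministic and independent of member order.
    """
    if cluster.consensus_ltr_size is None:
        consensus_sizes(cluster, elements)
    vectors = {m: structure_vector(annotations[m]) for m in cluster.member_ids}
    counts: dict = {}
    for v in vectors.values():
        counts[v] = counts.get(v, 0) + 1
    modal = max(counts.items(), key=lambda kv: (kv[1], repr(kv[0])))[0]

    def deviation(m):
        e = elements[m]
        return (
            abs(e.ltr_size - cluster.consensus_ltr_size) / cluster.consensus_ltr_size
            + abs(e.internal_size - cluster.consensus_internal_size)
            / cluster.consensus_internal_size
        )

    candidates = sorted(
        (m for m in cluster.member_ids if vectors[m] == modal),
        key=lambda m: (deviation(m), m),
    )
    return candidates[0]
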