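"""Reconstruct full LTR elements around Retand RT hits.

For each RT-domain hit, a 10-kb window on each side is extracted, the best
identical LTR pair (a maximal exact direct repeat with one copy on each side
of the RT domain) is located, and the element is accepted only if the 5-bp
sequences immediately flanking it are identical (the target-site duplication
left by integration).  Elements failing either criterion are recorded with a
reason code instead of being silently dropped.

"Identical LTRs" is operationalised as exact string equality: candidate
repeats are found by anchoring shared 21-mers between the upstream and
downstream flanks and extending each anchor to its maximal exact match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GenomeRecord
from .rtsearch import RtHit

DEFAULT_WINDOW = 10_000
DEFAULT_MIN_LTR = 100
DEFAULT_MAX_LTR = 3_000
DEFAULT_TSD_LEN = 5
_ANCHOR_K = 21


@dataclass
class FlankWindow:
    """A genome window around an RT hit, with offset bookkeeping."""

    genome_id: str
    seq: str
    offset: int  # genome coordinate of window position 0
    rt_span: tuple  # within the window
    left_truncated: bool
    right_truncated: bool

    def to_genome(self, pos: int) -> int:
        return pos + self.offset

    def to_window(self, pos: int) -> int:
        return pos - self.offset


@dataclass
class LtrElement:
    genome_id: str
    element_id: str
    element_span: tuple  # 5'LTR start .. 3'LTR end, genome coords
    ltr5_span: tuple
    ltr3_span: tuple
    ltr_sequence: str
    tsd_sequence: str
    internal_span: tuple
    strand: str
    rt_hit: RtHit

    @property
    def ltr_size(self) -> int:
        return self.ltr5_span[1] - self.ltr5_span[0]

    @property
    def internal_size(self) -> int:
        return self.internal_span[1] - self.internal_span[0]


@dataclass
class Rejection:
    genome_id: str
    rt_hit: RtHit
    reason: str  # no-ltr-pair | no-tsd | edge


def extract_flanks(genome: GenomeRecord, hit: RtHit, window: int = DEFAULT_WINDOW) -> FlankWindow:
    """Window of up to ``window`` bp on each side of the hit (truncation flagged)."""
    start = max(0, hit.start - window)
    end = min(len(genome.seq), hit.end + window)
    return FlankWindow(
        genome_id=genome.id,
        seq=genome.seq[start:end],
        offset=start,
        rt_span=(hit.start - start, hit.end - start),
        left_truncated=hit.start - window < 0,
        right_truncated=hit.end + window > len(genome.seq),
    )


def _maximal_repeats(window: str, rt_span, min_len: int):
    """Maximal exact direct repeats with one copy strictly upstream and one
    strictly downstream of rt_span; returned as (u_start, d_start, length)."""
    rt_start, rt_end = rt_span
    upstream_limit = rt_start
    k = _ANCHOR_K
    if upstream_limit < k or len(window) - rt_end < k:
        return []
    anchors: dict[str, list[int]] = {}
    for i in range(upstream_limit - k + 1):
        anchors.setdefault(window[i : i + k], []).append(i)
    pairs = set()
    for j in range(rt_end, len(window) - k + 1):
        kmer = window[j : j + k]
        for i in anchors.get(kmer, ()):
            # extend the anchor to a maximal exact match
            li, lj = i, j
            while li > 0 and lj > rt_end and window[li - 1] == window[lj - 1]:
                li -= 1
                lj -= 1
            ri, rj = i + k, j + k
            while ri < rt_start and rj < len(window) and window[ri] == window[rj]:
                ri += 1
                rj += 1
            if ri - li >= min_len:
                pairs.add((li, lj, ri - li))
    return sorted(pairs)


def find_ltr_pair(
    window: str,
    rt_span,
    min_ltr: int = DEFAULT_MIN_LTR,
    max_ltr: int = DEFAULT_MAX_LTR,
):
    """Best identical LTR pair in a window, or None.

    Candidates are maximal exact repeats of length in [min_ltr, max_ltr] with
    one copy entirely 5' and one entirely 3' of the RT span; the longest wins,
    ties broken by the outermost placement (widest element), then leftmost.
    """
    if min_ltr > max_ltr:
        raise ValueError("min_ltr > max_ltr")
    candidates = [
        (u, d, length)
        for u, d, length in _maximal_repeats(window, rt_span, min_ltr)
        if length <= max_ltr and u + length <= rt_span[0] and d >= rt_span[1]
    ]
    if not candidates:
        return None
    best = max(candidates, key=lambda c: (c[2], (c[1] + c[2]) - c[0], -c[0]))
    u, d, length = best
    return (u, u + length), (d, d + length)


def check_insertion_repeat(genome: GenomeRecord, element_span, tsd_len: int = DEFAULT_TSD_LEN):
    """The TSD sequence if the tsd_len bases flanking the element are identical.

    Returns (tsd_or_None, at_edge): at_edge is True when the element sits too
    close to a contig end for the comparison to be made.
    """
    start, end = element_span
    if start - tsd_len < 0 or end + tsd_len > len(genome.seq):
        return None, True
    left = genome.seq[start - tsd_len : start]
    right = genome.seq[end : end + tsd_len]
    return (left, False) if left == right else (None, False)


@dataclass
class BuilderParams:
    window: int = DEFAULT_WINDOW
    min_ltr: int = DEFAULT_MIN_LTR
    max_ltr: int = DEFAULT_MAX_LTR
    tsd_len: int = DEFAULT_TSD_LEN
    tsd_tolerance: tuple = ()  # extra TSD lengths to try, e.g. (4, 6)


def build_elements(
    genome: GenomeRecord, hits, params: BuilderParams | None = None
) -> tuple[list[LtrElement], list[Rejection]]:
    """One LtrElement per hit passing the identical-LTR and TSD criteria.

    Output order follows genomic position and is independent of hit input
    order.  Failures carry a reason code: no-ltr-pair, no-tsd, or edge.
    """
    params = params or BuilderParams()
    elements, rejections = [], []
    for hit in sorted(hits, key=lambda h: (h.start, h.end, h.query_id)):
        fw = extract_flanks(genome, hit, params.window)
        pair = find_ltr_pair(fw.seq, fw.rt_span, params.min_ltr, params.max_ltr)
        if pair is None:
            rejections.append(Rejection(genome.id, hit, "no-ltr-pair"))
            continue
        ltr5_w, ltr3_w = pair
        ltr5 = (fw.to_genome(ltr5_w[0]), fw.to_genome(ltr5_w[1]))
        ltr3 = (fw.to_genome(ltr3_w[0]), fw.to_genome(ltr3_w[1]))
        span = (ltr5[0], ltr3[1])
        tsd = None
        at_edge = False
        for tlen in (params.tsd_len, *params.tsd_tolerance):
            tsd, at_edge = check_insertion_repeat(genome, span, tlen)
            if tsd is not None:
                break
        if tsd is None:
            rejections.append(Rejection(genome.id, hit, "edge" if at_edge else "no-tsd"))
            continue
        eid = f"{genome.id}:{span[0]}-{span[1]}"
        elements.append(
            LtrElement(
                genome_id=genome.id,
                element_id=eid,
                element_span=span,
                ltr5_span=ltr5,
                ltr3_span=ltr3,
                ltr_sequence=genome.seq[ltr5[0] : ltr5[1]],
                tsd_sequence=tsd,
                internal_span=(ltr5[1], ltr3[0]),
                strand=hit.strand,
                rt_hit=hit,
            )
        )
    return elements, rejections
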