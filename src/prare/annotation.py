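"""Structural annotation of reconstructed elements.

Everything here works on the element sequence *oriented so that the RT domain
reads forward* ("sense" = the gag-pol reading direction); spans are 0-based
half-open in that orientation, with helpers to map back to genome coordinates.

ORFs are maximal ATG-to-stop (first ATG after the previous in-frame stop,
through the stop codon) in all six frames; ORFs shorter than the reporting
threshold (600 bp) are kept only when they carry a TRP28 domain hit, flagged
``short``.  Tandem arrays are runs of >= 3 consecutive period-length copies
matching the run consensus at >= the identity floor; overlapping candidates
are resolved by largest copies x period, ties to the smaller period, higher
copy-to-consensus identity, then leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import LtrElement
from .io import GenomeRecord
from .profiles import CORE_DOMAINS, POL_DOMAINS, DomainHit, scan_domains
from .seqtools import revcomp, translate

MIN_ORF = 600
_RESCUE_MIN = 150  # shortest ORF (bp) even considered for the TRP28 rescue


@dataclass
class OrfAnnotation:
    start: int  # oriented element coords; includes the stop codon
    end: int
    strand: str  # '+' = same strand as the RT domain
    orientation: str  # sense | antisense, relative to the gag-pol direction
    protein: str  # without the terminal stop
    domain_hits: list = field(default_factory=list)
    short: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def domain_names(self):
        return {h.name for h in self.domain_hits}


@dataclass
class TandemArray:
    start: int
    end: int
    period: int
    copies: int
    consensus: str
    mean_identity: float


@dataclass
class AnnotatedElement:
    element_id: str
    orfs: list
    gag_pol_layout: str  # one-ORF | two-ORF | none
    pol_3ltr_span: tuple | None  # oriented element coords
    tandem_arrays: list
    autonomy: str  # complete | defective
    missing_domains: frozenset
    min_orf: int = MIN_ORF
    strand: str = "+"  # orientation of the element on the genome
    element_span: tuple = (0, 0)

    @property
    def pol_3ltr_length(self) -> int | None:
        if self.pol_3ltr_span is None:
            return None
        return self.pol_3ltr_span[1] - self.pol_3ltr_span[0]

    def to_genome_span(self, span) -> tuple:
        """Map an oriented-element span back to forward-strand genome coords."""
        s, e = self.element_span
        if self.strand == "+":
            return (s + span[0], s + span[1])
        return (e - span[1], e - span[0])


def find_orfs(seq: str, min_len: int = MIN_ORF, profiles=None) -> list[OrfAnnotation]:
    """Maximal ATG-to-stop ORFs in all six frames of an oriented element.

    ORFs of length >= min_len are always reported; shorter ones only when
    ``profiles`` includes TRP28 and the ORF's protein carries a TRP28 hit
    (reported with ``short=True``).  Reported spans include the stop codon.
    """
    trp28 = None
    if profiles:
        by_name = profiles if isinstance(profiles, dict) else {p.name: p for p in profiles}
        trp28 = by_name.get("TRP28")
    floor = min_len if trp28 is None else min(min_len, max(_RESCUE_MIN, 3 * len(trp28) + 6))
    out = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            prot = translate(s[frame:])
            start_m = None
            for i, aa in enumerate(prot + "*"):
                if aa == "M" and start_m is None:
                    start_m = i
                if aa == "*":
                    if start_m is not None and i < len(prot):
                        length = 3 * (i - start_m + 1)
                        if length >= floor:
                            a = frame + 3 * start_m
                            b = frame + 3 * (i + 1)
                            span = (a, b) if strand == "+" else (n - b, n - a)
                            out.append(
                                OrfAnnotation(
                                    start=span[0],
                                    end=span[1],
                                    strand=strand,
                                    orientation="sense" if strand == "+" else "antisense",
                                    protein=prot[start_m:i],
                                    short=length < min_len,
                                )
                            )
                    start_m = None
    for orf in out:
        if profiles:
            orf.domain_hits = scan_domains(
                orf.protein,
                by_name.values() if isinstance(profiles, dict) else profiles,
            )
    kept = [
        o for o in out if not o.short or (trp28 is not None and "TRP28" in o.domain_names())
    ]
    kept.sort(key=lambda o: (o.start, o.end, o.strand))
    return kept


def delimit_pol_3ltr(orfs, internal_end: int) -> tuple | None:
    """Span from the stop of the 3'-most pol-domain-bearing sense ORF to the
    3'LTR start (``internal_end``), in oriented element coordinates."""
    pol_orfs = [
        o
        for o in orfs
        if o.orientation == "sense" and o.domain_names() & set(POL_DOMAINS)
    ]
    if not pol_orfs:
        return None
    last_end = max(o.end for o in pol_orfs)
    return (last_end, internal_end)


def _exact_arrays(s: str, period: int, min_copies: int):
    """Maximal runs of exact period-length copies (leftmost convention)."""
    n = len(s)
    if n < 2 * period:
        return []
    x = np.frombuffer(s.encode(), dtype=np.uint8)
    d = x[: n - period] == x[period:]
    out = []
    i = 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], d.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        copies = (b - a) // period + 1
        if copies >= min_copies:
            out.append(
                TandemArray(int(a), int(a + copies * period), period, int(copies),
                            s[a : a + period], 1.0)
            )
    return out


def _unit_identity(window: str, consensus: str) -> float:
    return sum(a == b for a, b in zip(window, consensus)) / len(consensus)


def _consensus_of(copies) -> str:
    cols = zip(*copies)
    return "".join(max(sorted(set(col)), key=col.count) for col in cols)


def _approx_arrays(s: str, period: int, min_copies: int, min_identity: float):
    """Anchor-and-extend detection of near-exact arrays for one period."""
    n = len(s)
    if n < 2 * period:
        return []
    x = np.frombuffer(s.encode(), dtype=np.uint8)
    d = (x[: n - period] == x[period:]).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(d)))
    limit = n - 2 * period
    out = []
    visited = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(
        (cum[period : limit + period + 1] - cum[: limit + 1]) / period >= min_identity
    )
    for a in starts:
        a = int(a)
        if visited[a]:
            continue
        copies = [s[a : a + period], s[a + period : a + 2 * period]]
        start = a
        end = a + 2 * period
        while end + period <= n:
            cons = _consensus_of(copies)
            if _unit_identity(s[end : end + period], cons) < min_identity:
                break
            copies.append(s[end : end + period])
            end += period
        while start - period >= 0:
            cons = _consensus_of(copies)
            if _unit_identity(s[start - period : start], cons) < min_identity:
                break
            copies.insert(0, s[start - period : start])
            start -= period
        cons = _consensus_of(copies)
        idents = [_unit_identity(c, cons) for c in copies]
        if len(copies) >= min_copies and min(idents) >= min_identity:
            out.append(
                TandemArray(start, end, period, len(copies), cons,
                            float(np.mean(idents)))
            )
            visited[start:end] = True
    return out


def find_tandem_arrays(
    seq: str,
    min_copies: int = 3,
    min_period: int = 1,
    max_period: int = 100,
    min_identity: float = 0.8,
) -> list[TandemArray]:
    """Tandem arrays of >= min_copies consecutive unit copies.

    Exact arrays are detected first for every period; with ``min_identity``
    below 1, near-exact arrays are added where no exact array claims the
    region.  Overlaps are resolved by highest copies x period, ties broken by
    smaller period, higher mean identity, then leftmost start.
    """
    if min_period > max_period:
        raise ValueError("min_period > max_period")
    if not 0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    seq = seq.upper()
    candidates = []
    for p in range(min_period, min(max_period, max(1, len(seq) // 2)) + 1):
        candidates.extend(_exact_arrays(seq, p, min_copies))
        if min_identity < 1.0:
            candidates.extend(_approx_arrays(seq, p, min_copies, min_identity))
    candidates.sort(
        key=lambda t: (-(t.copies * t.period), t.period, -t.mean_identity, t.start)
    )
    kept: list[TandemArray] = []
    for t in candidates:
        if any(t.start < k.end and k.start < t.end for k in kept):
            continue
        kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


def classify_autonomy(orfs) -> tuple[str, frozenset]:
    """('complete', {}) iff GAG, AP, RT, RH and INT all occur on sense ORFs."""
    present = set()
    for o in orfs:
        if o.orientation == "sense":
            present |= o.domain_names() & set(CORE_DOMAINS)
    missing = frozenset(set(CORE_DOMAINS) - present)
    return ("complete" if not missing else "defective", missing)


def annotate_element(
    genome: GenomeRecord,
    element: LtrElement,
    profiles: dict,
    min_orf: int = MIN_ORF,
    min_tandem_copies: int = 3,
    max_tandem_period: int = 100,
    tandem_identity: float = 0.8,
) -> AnnotatedElement:
    """Full structural annotation of one reconstructed element."""
    s, e = element.element_span
    oriented = genome.seq[s:e]
    if element.strand == "-":
        oriented = revcomp(oriented)
    L = element.ltr_size
    internal = (L, L + element.internal_size)

    orfs = [
        o
        for o in find_orfs(oriented, min_orf, profiles)
        if o.start >= internal[0] and o.end <= internal[1]
    ]
    layout_orfs = [
        o
        for o in orfs
        if o.orientation == "sense" and o.domain_names() & set(CORE_DOMAINS)
    ]
    layout = "none" if not layout_orfs else ("one-ORF" if len(layout_orfs) == 1 else "two-ORF")
    autonomy, missing = classify_autonomy(orfs)
    arrays = [
        TandemArray(t.start + internal[0], t.end + internal[0], t.period, t.copies,
                    t.consensus, t.mean_identity)
        for t in find_tandem_arrays(
            oriented[internal[0] : internal[1]],
            min_copies=min_tandem_copies,
            max_period=max_tandem_period,
            min_identity=tandem_identity,
        )
    ]
    return AnnotatedElement(
        element_id=element.element_id,
        orfs=orfs,
        gag_pol_layout=layout,
        pol_3ltr_span=delimit_pol_3ltr(orfs, internal[1]),
        tandem_arrays=arrays,
        autonomy=autonomy,
        missing_domains=missing,
        min_orf=min_orf,
        strand=element.strand,
        element_span=element.element_span,
    )
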