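"""Synthetic genomes with planted Retand-like elements and decoys.

The generator builds the element architecture the pipeline is designed to
recover: two identical LTRs (315–1,194 bp in the reference clusters) around a
long internal region (7,380–12,869 bp), a 5-bp target-site duplication (TSD),
gag-pol coding in one or two ORFs with an RT domain of 157–162 aa, a long
POL-3'LTR region hosting antisense ORFs (TRP28-bearing) and tandem arrays
(period 8–100, ≥ 3 copies), plus the decoy classes a real genome would offer:
diverged-LTR elements, solo LTRs, truncated elements and elements whose RT
belongs to a different lineage.

Construction guarantees that planted truth is unambiguous for the detectors:

* coding features are codon-wise ``ATG … stop`` with an in-frame stop guard
  immediately 5' of each start, so every planted ORF is maximal with an exact
  span;
* the bases adjacent to the LTR pair are resampled so the pair is a *maximal*
  exact repeat (detection recovers exact LTR boundaries);
* the bases flanking each tandem array break the array period, and array units
  are never themselves periodic, so leftmost-maximal detection recovers the
  planted (start, period, copies) exactly.

All coordinates are 0-based half-open on the forward strand.  Background
sequence is i.i.d. uniform A/C/G/T unless a GC content is configured — the
simplest null that cannot by chance contain LTR-scale exact repeats.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io import GenomeRecord, GffFeature
from .panels import build_profile_consensi, load_model_panel, load_retand_queries
from .seqtools import (
    encode_protein,
    random_dna,
    random_protein,
    revcomp,
    stratified_positions,
    substitute_dna,
)

_MIN_SPACER = 10
_GUARD = "TAA"  # in-frame stop planted immediately 5' of each ORF start


@dataclass
class ElementSpec:
    """Blueprint of a planted Retand-like element."""

    ltr_length: int
    internal_length: int
    rt_protein: str
    tsd_length: int = 5
    gag_pol_layout: str = "one-ORF"  # or "two-ORF"
    antisense_orf_lengths: tuple = (1200,)
    antisense_orf_domains: tuple | None = None  # parallel to lengths; default: TRP28 in the first
    tandem_arrays: tuple = ()  # (unit_length, copy_count, "pol-adjacent" | "ltr3-adjacent")
    ltr_divergence: int = 0  # substituted positions between the two LTR copies
    missing_domains: frozenset = frozenset()
    pol_3ltr_length: int | None = None  # None: ~55% of spare internal length

    def validate(self) -> None:
        if self.ltr_length <= 0 or self.internal_length <= 0:
            raise ValueError("ltr_length and internal_length must be positive")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if self.ltr_divergence < 0:
            raise ValueError("ltr_divergence must be >= 0")
        if self.gag_pol_layout not in ("one-ORF", "two-ORF"):
            raise ValueError(f"unknown gag_pol_layout {self.gag_pol_layout!r}")
        if not self.missing_domains <= {"GAG", "AP", "RH", "INT"}:
            raise ValueError("missing_domains must be a subset of {GAG, AP, RH, INT}")
        for length in self.antisense_orf_lengths:
            if length < 0 or length % 3:
                raise ValueError("antisense ORF lengths must be non-negative multiples of 3")
        for unit, copies, tag in self.tandem_arrays:
            if not (1 <= unit <= 100):
                raise ValueError("tandem array unit length must be in [1, 100]")
            if copies < 3:
                raise ValueError("tandem arrays need at least three copies")
            if tag not in ("pol-adjacent", "ltr3-adjacent"):
                raise ValueError(f"unknown tandem array position tag {tag!r}")


@dataclass
class TruthRecord:
    """Ground truth for one planted cassette (element or decoy)."""

    genome_id: str
    element_id: str
    kind: str  # intact | diverged_ltr | solo_ltr | truncated | non_retand_rt
    element_span: tuple
    ltr5_span: tuple | None
    ltr3_span: tuple | None
    tsd_sequence: str
    strand: str
    rt_span: tuple | None
    features: list = field(default_factory=list)
    is_prare_eligible: bool = True
    family: str = ""


@dataclass
class _Feature:
    type: str  # orf | domain | tandem_array
    name: str
    start: int
    end: int
    strand: str
    extra: dict = field(default_factory=dict)


def _make_orf(rng, parts) -> tuple[str, list]:
    """Codon-wise ORF from (domain_name_or_None, protein) parts.

    Returns the ORF DNA (``ATG`` + body + stop) and domain features with spans
    relative to the ORF start.
    """
    dna = ["ATG"]
    feats = []
    aa_off = 1  # the initial M
    for name, prot in parts:
        if name is not None:
            feats.append(_Feature("domain", name, 3 * aa_off, 3 * (aa_off + len(prot)), "+"))
        dna.append(encode_protein(rng, prot, stop=False))
        aa_off += len(prot)
    dna.append("TAA")
    return "".join(dna), feats


def _nonperiodic_unit(rng, length: int) -> str:
    """Random DNA unit that is not itself a repeat of a shorter period."""
    while True:
        unit = random_dna(rng, length)
        ok = all(
            unit != unit[:d] * (length // d)
            for d in range(1, length)
            if length % d == 0
        )
        if ok:
            return unit


def _shift(feats, offset: int):
    return [
        _Feature(f.type, f.name, f.start + offset, f.end + offset, f.strand, dict(f.extra))
        for f in feats
    ]


def _build_internal(spec: ElementSpec, rng, consensi) -> tuple[str, list, tuple | None]:
    """Assemble the internal region; returns (seq, features, rt_span)."""
    linker = lambda n: random_protein(rng, n)

    pol_parts = []
    if "AP" not in spec.missing_domains:
        pol_parts += [(None, linker(5)), ("AP", consensi["AP"])]
    pol_parts += [(None, linker(5)), ("RT", spec.rt_protein)]
    if "RH" not in spec.missing_domains:
        pol_parts += [(None, linker(5)), ("RH", consensi["RH"])]
    if "INT" not in spec.missing_domains:
        pol_parts += [(None, linker(5)), ("INT", consensi["INT"])]

    has_gag = "GAG" not in spec.missing_domains
    if spec.gag_pol_layout == "two-ORF" and has_gag:
        # pad the gag ORF well past the 600-bp reporting threshold
        gag_dna, gag_feats = _make_orf(rng, [("GAG", consensi["GAG"]), (None, linker(140))])
        pol_dna, pol_feats = _make_orf(rng, pol_parts)
        coding = [(gag_dna, gag_feats, "gag"), (pol_dna, pol_feats, "pol")]
    else:
        parts = ([("GAG", consensi["GAG"]), (None, linker(5))] if has_gag else []) + pol_parts
        dna, feats = _make_orf(rng, parts)
        coding = [(dna, feats, "gag-pol")]

    aorf_blocks = []
    domains = spec.antisense_orf_domains
    if domains is None:
        domains = tuple(
            "TRP28" if i == 0 else None for i in range(len(spec.antisense_orf_lengths))
        )
    for length, dom in zip(spec.antisense_orf_lengths, domains):
        if length == 0:
            continue
        n_aa = length // 3 - 1  # protein incl. initial M; ORF dna = 3n + 3
        body_len = n_aa - 1
        if dom is not None:
            dom_seq = consensi[dom]
            if body_len < len(dom_seq):
                raise ValueError(f"antisense ORF of {length} bp too short for {dom}")
            pad = body_len - len(dom_seq)
            left = int(rng.integers(0, pad + 1))
            body = [
                (None, linker(left)) if left else None,
                (dom, dom_seq),
                (None, linker(pad - left)) if pad - left else None,
            ]
            body = [b for b in body if b is not None]
        else:
            body = [(None, linker(body_len))]
        sense_dna, sense_feats = _make_orf(rng, body)
        block = revcomp(_GUARD + sense_dna)  # ORF occupies block[0:length], '-' strand
        feats = [_Feature("orf", "aorf", 0, length, "-")]
        for f in sense_feats:
            feats.append(
                _Feature("domain", f.name, length - f.end, length - f.start, "-")
            )
        aorf_blocks.append((block, feats))

    def array_block(unit_len, copies):
        unit = _nonperiodic_unit(rng, unit_len)
        seq = unit * copies
        feats = [
            _Feature(
                "tandem_array", f"array_p{unit_len}", 0, len(seq), "+",
                {"period": unit_len, "copies": copies, "unit": unit},
            )
        ]
        return seq, feats

    pol_arrays = [array_block(u, c) for u, c, tag in spec.tandem_arrays if tag == "pol-adjacent"]
    ltr3_arrays = [array_block(u, c) for u, c, tag in spec.tandem_arrays if tag == "ltr3-adjacent"]

    # --- assemble: head | coding | [pol3ltr: arrays, aORFs, arrays] | tail ---
    coding_len = len(_GUARD) * len(coding) + sum(len(d) for d, _, _ in coding)
    pol3_blocks = pol_arrays + aorf_blocks + ltr3_arrays
    n_pol3_spacers = len(pol3_blocks) + 1
    pol3_fixed = sum(len(b) for b, _ in pol3_blocks)
    inter_orf_spacer = _MIN_SPACER if len(coding) == 2 else 0

    min_needed = coding_len + inter_orf_spacer + pol3_fixed + (n_pol3_spacers + 1) * _MIN_SPACER
    slack = spec.internal_length - min_needed
    if slack < 0:
        raise ValueError(
            f"internal_length {spec.internal_length} too small for requested "
            f"features (needs >= {min_needed})"
        )
    if spec.pol_3ltr_length is not None:
        pol3_total = spec.pol_3ltr_length
        pol3_slack = pol3_total - pol3_fixed - n_pol3_spacers * _MIN_SPACER
        head_len = spec.internal_length - coding_len - inter_orf_spacer - pol3_total
        if pol3_slack < 0 or head_len < _MIN_SPACER:
            raise ValueError("pol_3ltr_length incompatible with internal_length/features")
    else:
        pol3_slack = round(slack * 0.55)
        head_len = _MIN_SPACER + (slack - pol3_slack)
        pol3_total = pol3_fixed + n_pol3_spacers * _MIN_SPACER + pol3_slack

    shares = rng.multinomial(pol3_slack, np.full(n_pol3_spacers, 1.0 / n_pol3_spacers))
    pol3_spacers = [int(_MIN_SPACER + s) for s in shares]

    seq_parts: list[str] = []
    features: list[_Feature] = []
    pos = 0

    def emit(chunk: str, feats=None):
        nonlocal pos
        seq_parts.append(chunk)
        if feats:
            features.extend(_shift(feats, pos))
        pos += len(chunk)

    emit(random_dna(rng, head_len))
    for i, (dna, feats, label) in enumerate(coding):
        if i:
            emit(random_dna(rng, inter_orf_spacer))
        emit(_GUARD)
        orf_feats = [_Feature("orf", label, 0, len(dna), "+")] + feats
        emit(dna, orf_feats)
    for block, feats in pol3_blocks:
        emit(random_dna(rng, pol3_spacers.pop(0)))
        emit(block, feats)
    emit(random_dna(rng, pol3_spacers.pop(0)))
    assert pos == spec.internal_length, (pos, spec.internal_length)

    seq = list("".join(seq_parts))
    # break tandem-array periodicity at array boundaries
    for f in features:
        if f.type != "tandem_array":
            continue
        unit = f.extra["unit"]
        if f.start > 0 and seq[f.start - 1] == unit[-1]:
            seq[f.start - 1] = substitute_dna(rng, seq[f.start - 1], [0])
        if f.end < len(seq) and seq[f.end] == unit[0]:
            seq[f.end] = substitute_dna(rng, seq[f.end], [0])

    rt_span = None
    for f in features:
        if f.type == "domain" and f.name == "RT":
            rt_span = (f.start, f.end)
    return "".join(seq), features, rt_span


def build_element(spec: ElementSpec, rng, consensi=None) -> tuple[str, list, dict]:
    """Build the element sequence (sense orientation) and its features.

    Returns (sequence, features, spans) where spans holds ltr5/ltr3/rt spans in
    element coordinates.
    """
    spec.validate()
    if consensi is None:
        consensi = build_profile_consensi()
    ltr = random_dna(rng, spec.ltr_length)
    ltr3 = ltr
    if spec.ltr_divergence:
        positions = stratified_positions(rng, spec.ltr_length, spec.ltr_divergence)
        ltr3 = substitute_dna(rng, ltr, positions)
    internal, feats, rt_span = _build_internal(spec, rng, consensi)
    L = spec.ltr_length
    element = ltr + internal + ltr3
    features = _shift(feats, L)
    spans = {
        "ltr5": (0, L),
        "ltr3": (L + spec.internal_length, L + spec.internal_length + L),
        "rt": (rt_span[0] + L, rt_span[1] + L) if rt_span else None,
    }
    return element, features, spans


def _rc_features(features, length):
    out = []
    for f in features:
        strand = {"+": "-", "-": "+"}.get(f.strand, f.strand)
        extra = dict(f.extra)
        if "unit" in extra:
            extra["unit"] = revcomp(extra["unit"])
        out.append(_Feature(f.type, f.name, length - f.end, length - f.start, strand, extra))
    return out


def _rc_span(span, length):
    return None if span is None else (length - span[1], length - span[0])


def _pick_base_not(rng, forbidden: str) -> str:
    choices = [b for b in "ACGT" if b != forbidden]
    return choices[int(rng.integers(0, len(choices)))]


def plant_element(
    genome: GenomeRecord,
    spec: ElementSpec,
    position: int,
    rng_seed,
    strand: str = "+",
    element_id: str = "element_1",
    kind: str = "intact",
    consensi=None,
) -> tuple[GenomeRecord, TruthRecord]:
    """Insert one element at ``position`` with a TSD duplication.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.  The
    new genome is ``genome[:position+t] + element + genome[position:]`` where
    ``t = spec.tsd_length``: the ``t`` bases at the insertion point appear once
    on each side of the element, emulating integration.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    built = build_element(spec, rng, consensi)
    return _plant_built(
        genome, built, spec, position, rng, strand=strand, element_id=element_id, kind=kind
    )


def _plant_built(
    genome: GenomeRecord,
    built,
    spec: ElementSpec,
    position: int,
    rng,
    strand: str = "+",
    element_id: str = "element_1",
    kind: str = "intact",
) -> tuple[GenomeRecord, TruthRecord]:
    """Insert an already-built element (allows identical copies of one master)."""
    t = spec.tsd_length
    g = genome.seq
    if not 0 <= position <= len(g) - t:
        raise ValueError(f"position {position} out of range for genome of {len(g)} bp")

    element, features, spans = built
    if strand == "-":
        n = len(element)
        element = revcomp(element)
        features = _rc_features(features, n)
        spans = {k: _rc_span(v, n) for k, v in spans.items()}
        spans["ltr5"], spans["ltr3"] = spans["ltr3"], spans["ltr5"]

    tsd = g[position : position + t]
    # make the LTR pair a *maximal* exact repeat: resample the internal-region
    # edge bases so neither flank of the pair extends the match
    L = spec.ltr_length
    I = spec.internal_length
    elem = list(element)
    left_outside = tsd[-1] if t else (g[position - 1] if position else None)
    right_outside = tsd[0] if t else (g[position] if position < len(g) else None)
    if left_outside is not None and elem[L + I - 1] == left_outside:
        elem[L + I - 1] = _pick_base_not(rng, left_outside)
    if right_outside is not None and elem[L] == right_outside:
        elem[L] = _pick_base_not(rng, right_outside)
    element = "".join(elem)

    new_seq = g[: position + t] + element + g[position:]
    off = position + t

    def shift_span(span):
        return None if span is None else (span[0] + off, span[1] + off)

    truth = TruthRecord(
        genome_id=genome.id,
        element_id=element_id,
        kind=kind,
        element_span=(off, off + len(element)),
        ltr5_span=shift_span(spans["ltr5"]),
        ltr3_span=shift_span(spans["ltr3"]),
        tsd_sequence=tsd,
        strand=strand,
        rt_span=shift_span(spans["rt"]),
        features=[
            dataclasses.asdict(f)
            for f in _shift(features, off)
        ],
        is_prare_eligible=(kind == "intact" and spec.ltr_divergence == 0),
    )
    return GenomeRecord(genome.id, new_seq, genome.description), truth


def _plant_solo_ltr(genome, ltr_length, position, rng, tsd_length=5, element_id="solo"):
    """A lone LTR with a TSD — the footprint of inter-LTR recombination."""
    g = genome.seq
    ltr = random_dna(rng, ltr_length)
    tsd = g[position : position + tsd_length]
    new_seq = g[: position + tsd_length] + ltr + g[position:]
    off = position + tsd_length
    truth = TruthRecord(
        genome_id=genome.id, element_id=element_id, kind="solo_ltr",
        element_span=(off, off + ltr_length), ltr5_span=(off, off + ltr_length),
        ltr3_span=None, tsd_sequence=tsd, strand="+", rt_span=None,
        is_prare_eligible=False,
    )
    return GenomeRecord(genome.id, new_seq, genome.description), truth


def _plant_truncated(genome, spec, position, rng, element_id="trunc", consensi=None):
    """5'-truncated element: RT through the 3'LTR, no 5'LTR and no TSD."""
    element, features, spans = build_element(spec, rng, consensi)
    cut = max(0, spans["rt"][0] - 300)  # keep the RT domain and everything 3' of it
    cassette = element[cut:]
    g = genome.seq
    new_seq = g[:position] + cassette + g[position:]
    off = position - cut
    feats = [f for f in _shift(features, off) if f.start >= position]
    truth = TruthRecord(
        genome_id=genome.id, element_id=element_id, kind="truncated",
        element_span=(position, position + len(cassette)),
        ltr5_span=None,
        ltr3_span=(spans["ltr3"][0] + off, spans["ltr3"][1] + off),
        tsd_sequence="", strand="+",
        rt_span=(spans["rt"][0] + off, spans["rt"][1] + off),
        features=[dataclasses.asdict(f) for f in feats],
        is_prare_eligible=False,
    )
    return GenomeRecord(genome.id, new_seq, genome.description), truth


# ---------------------------------------------------------------------------
# scenario generation
# ---------------------------------------------------------------------------

@dataclass
class FamilyConfig:
    name: str
    ltr_length: int
    internal_length: int
    pol_3ltr_length: int
    rt_query: str  # id of a packaged Retand query
    n_intact: int
    gag_pol_layout: str = "one-ORF"
    antisense_orf_lengths: tuple = (1200,)
    tandem_arrays: tuple = ()
    missing_domains: tuple = ()
    tsd_length: int = 5


@dataclass
class ScenarioConfig:
    genome_length: int = 5_000_000
    n_contigs: int = 5
    gc: float | None = None
    min_gap: int = 25_000
    edge_margin: int = 15_000
    families: tuple = ()
    n_diverged_ltr: int = 3
    diverged_ltr_substitutions: int = 4
    n_solo_ltr: int = 3
    n_truncated: int = 2
    n_non_retand_rt: int = 2
    non_retand_lineage: str = "Athila"


def default_scenario_config(genome_length: int = 5_000_000) -> ScenarioConfig:
    """The stated-world default: three families, 12 intact elements, 10 decoys.

    Family geometry sits inside the reference ranges (LTR 315–1,194 bp,
    internal 7,380–12,869 bp, POL-3'LTR 2,933–6,566 bp, TSD 5 bp, tandem
    arrays of period 8–100 with ≥ 3 copies).
    """
    families = (
        FamilyConfig(
            name="famA", ltr_length=600, internal_length=10_000, pol_3ltr_length=4_600,
            rt_query="Tat4-1", n_intact=5, gag_pol_layout="one-ORF",
            antisense_orf_lengths=(1200,), tandem_arrays=((24, 10, "pol-adjacent"),),
        ),
        FamilyConfig(
            name="famB", ltr_length=450, internal_length=9_000, pol_3ltr_length=3_900,
            rt_query="Gret1", n_intact=4, gag_pol_layout="two-ORF",
            antisense_orf_lengths=(1200, 900),
        ),
        FamilyConfig(
            name="famC", ltr_length=1_000, internal_length=12_000, pol_3ltr_length=5_500,
            rt_query="Cinful-1", n_intact=3, gag_pol_layout="one-ORF",
            antisense_orf_lengths=(1500,),
            tandem_arrays=((8, 12, "pol-adjacent"), (40, 5, "ltr3-adjacent")),
        ),
    )
    return ScenarioConfig(genome_length=genome_length, families=families)


def _family_spec(fam: FamilyConfig, rt_proteins, **overrides) -> ElementSpec:
    kwargs = dict(
        ltr_length=fam.ltr_length,
        internal_length=fam.internal_length,
        pol_3ltr_length=fam.pol_3ltr_length,
        rt_protein=rt_proteins[fam.rt_query],
        tsd_length=fam.tsd_length,
        gag_pol_layout=fam.gag_pol_layout,
        antisense_orf_lengths=tuple(fam.antisense_orf_lengths),
        tandem_arrays=tuple(tuple(a) for a in fam.tandem_arrays),
        missing_domains=frozenset(fam.missing_domains),
    )
    kwargs.update(overrides)
    return ElementSpec(**kwargs)


def generate_scenario(config: ScenarioConfig, rng_seed: int):
    """Generate (genomes, truth_records) for a planted-element scenario.

    Deterministic for a fixed (config, seed) pair.  Raises if the requested
    plantings cannot be packed into the genome at the configured spacing.
    """
    rng = np.random.default_rng(rng_seed)
    consensi = build_profile_consensi()
    rt_proteins = {r.id.split("|")[-1]: r.seq for r in load_retand_queries()}
    panel = load_model_panel()
    outgroup = [r for r in panel if r.id.startswith(config.non_retand_lineage + "|")]
    if not outgroup:
        raise ValueError(f"no panel member for lineage {config.non_retand_lineage!r}")

    if not config.families:
        raise ValueError("scenario config names no families")
    fam_by_idx = list(config.families)

    # one master element per family: intact copies are byte-identical copies of
    # it (recently active = no divergence yet), so LTR clustering groups them
    masters = {}
    for fam in fam_by_idx:
        spec = _family_spec(fam, rt_proteins)
        masters[fam.name] = (spec, build_element(spec, rng, consensi))

    jobs = []  # (kind, family, spec_or_params)
    for fam in fam_by_idx:
        for _ in range(fam.n_intact):
            jobs.append(("intact", fam.name, masters[fam.name]))
    decoy_fam = fam_by_idx[0]
    for _ in range(config.n_diverged_ltr):
        jobs.append(
            (
                "diverged_ltr", decoy_fam.name + "-div",
                _family_spec(decoy_fam, rt_proteins,
                             ltr_divergence=config.diverged_ltr_substitutions),
            )
        )
    solo_fam = fam_by_idx[min(1, len(fam_by_idx) - 1)]
    for _ in range(config.n_solo_ltr):
        jobs.append(("solo_ltr", solo_fam.name + "-solo", solo_fam.ltr_length))
    for _ in range(config.n_truncated):
        jobs.append(("truncated", decoy_fam.name + "-trunc", _family_spec(decoy_fam, rt_proteins)))
    nr_fam = fam_by_idx[-1]
    for _ in range(config.n_non_retand_rt):
        jobs.append(
            (
                "non_retand_rt", nr_fam.name + "-nonretand",
                _family_spec(nr_fam, rt_proteins, rt_protein=outgroup[0].seq),
            )
        )

    order = rng.permutation(len(jobs))
    jobs = [jobs[i] for i in order]

    contig_len = config.genome_length // config.n_contigs
    per_contig = [[] for _ in range(config.n_contigs)]
    for i, job in enumerate(jobs):
        per_contig[i % config.n_contigs].append(job)

    genomes, truths = [], []
    counter = 0
    for ci, contig_jobs in enumerate(per_contig):
        gid = f"chr{ci + 1}"
        genome = GenomeRecord(gid, random_dna(rng, contig_len, config.gc))
        k = len(contig_jobs)
        if k:
            usable = contig_len - 2 * config.edge_margin
            slot = usable // k
            if slot < config.min_gap:
                raise ValueError("infeasible packing: genome too short for requested plantings")
            positions = [
                config.edge_margin + i * slot + int(rng.integers(0, max(1, slot - config.min_gap)))
                for i in range(k)
            ]
            added = 0
            for (kind, family, payload), pos in zip(contig_jobs, positions):
                counter += 1
                eid = f"{family}_{counter:03d}"
                cur = pos + added
                if kind == "solo_ltr":
                    genome, truth = _plant_solo_ltr(genome, payload, cur, rng, element_id=eid)
                elif kind == "truncated":
                    genome, truth = _plant_truncated(genome, payload, cur, rng, element_id=eid,
                                                     consensi=consensi)
                elif kind == "intact":
                    spec, built = payload
                    strand = "+" if rng.integers(0, 2) == 0 else "-"
                    genome, truth = _plant_built(
                        genome, built, spec, cur, rng, strand=strand, element_id=eid,
                        kind=kind,
                    )
                else:
                    strand = "+" if rng.integers(0, 2) == 0 else "-"
                    genome, truth = plant_element(
                        genome, payload, cur, rng, strand=strand, element_id=eid,
                        kind=kind, consensi=consensi,
                    )
                truth.family = family
                truths.append(truth)
                added = len(genome.seq) - contig_len
        genomes.append(genome)
    return genomes, truths


# ---------------------------------------------------------------------------
# truth-record serialization
# ---------------------------------------------------------------------------

def truth_to_jsonl_records(truths) -> list[dict]:
    """One JSON record per planted feature, plus one per element."""
    out = []
    for t in truths:
        base = dataclasses.asdict(t)
        feats = base.pop("features")
        base["record_type"] = "element"
        out.append(base)
        for f in feats:
            rec = dict(f)
            rec["record_type"] = "feature"
            rec["element_id"] = t.element_id
            rec["genome_id"] = t.genome_id
            out.append(rec)
    return out


def truth_to_gff(truths) -> list[GffFeature]:
    feats = []
    for t in truths:
        attrs = {"ID": t.element_id, "kind": t.kind, "eligible": str(t.is_prare_eligible)}
        feats.append(
            GffFeature(t.genome_id, "planted_element", t.element_span[0], t.element_span[1],
                       t.strand, attributes=attrs)
        )
        for name, span in (("ltr5", t.ltr5_span), ("ltr3", t.ltr3_span), ("rt_domain", t.rt_span)):
            if span is not None:
                feats.append(
                    GffFeature(t.genome_id, name, span[0], span[1], t.strand,
                               attributes={"Parent": t.element_id})
                )
        for f in t.features:
            feats.append(
                GffFeature(
                    t.genome_id, f["type"], f["start"], f["end"], f["strand"],
                    attributes={"Parent": t.element_id, "Name": f["name"]},
                )
            )
    return feats


# ---------------------------------------------------------------------------
# scenario config files (TOML)
# ---------------------------------------------------------------------------

def save_scenario_config(config: ScenarioConfig, path) -> None:
    """Write a ScenarioConfig as TOML (readable by :func:`load_scenario_config`)."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, str):
            return f'"{v}"'
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return str(v)

    lines = []
    for f in dataclasses.fields(ScenarioConfig):
        if f.name == "families":
            continue
        value = getattr(config, f.name)
        if value is None:
            continue
        lines.append(f"{f.name} = {fmt(value)}")
    for fam in config.families:
        lines.append("\n[[families]]")
        for f in dataclasses.fields(FamilyConfig):
            value = getattr(fam, f.name)
            if f.name == "tandem_arrays":
                value = [list(a) for a in value]
            elif isinstance(value, tuple):
                value = list(value)
            lines.append(f"{f.name} = {fmt(value)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_scenario_config(path) -> ScenarioConfig:
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    families = tuple(
        FamilyConfig(
            **{
                **fam,
                "antisense_orf_lengths": tuple(fam.get("antisense_orf_lengths", (1200,))),
                "tandem_arrays": tuple(tuple(a) for a in fam.get("tandem_arrays", ())),
                "missing_domains": tuple(fam.get("missing_domains", ())),
            }
        )
        for fam in raw.pop("families", [])
    )
    return ScenarioConfig(families=families, **raw)
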