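"""Cluster consensus sequences, conservation profiles and summary statistics.

``summarize_clusters`` reproduces the style of the reference cluster table:
per-cluster copy number, LTR / internal / POL-3'LTR sizes, core-domain
presence, TRP28 status and tandem-array counts, reduced to min / max / mean
statistics (means rounded half-up to integer bp, matching the printed style
of the reference values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

import pandas as pd

from .io import package_data_path
from .seqtools import AA_ALPHABET

CONSERVATION_BINS = (0.45, 0.35, 0.25)  # dark red / red / pink thresholds


@dataclass
class ConservationColumn:
    index: int
    frequencies: dict  # residue -> fraction of non-gap residues
    gap_fraction: float
    bin: str  # ">45%" | ">35%" | ">25%" | "below"
    majority_gapped: bool = False


@dataclass
class ClusterSummary:
    cluster: str
    copy_number: int
    ltr_bp: int
    internal_bp: int
    pol3ltr_bp: int | None
    gag: bool
    ap: bool
    rh: bool
    int_: bool
    trp28: str  # YES | NO | SHORT
    other_domains: tuple = ()
    tandem_arrays: int = 0
    group: str = ""


_RESIDUE_ORDER = AA_ALPHABET  # fixed tie-break ordering for consensus calls


def consensus_sequence(rows) -> str:
    """Per-column majority residue of an alignment (gaps excluded from the
    vote); columns that are >= 50% gaps are dropped.  Ties go to the residue
    earliest in the fixed ordering."""
    rows = list(rows)
    if not rows:
        raise ValueError("empty alignment")
    out = []
    for col in zip(*rows):
        residues = [c for c in col if c != "-"]
        if 2 * len(residues) <= len(col):  # gap fraction >= 0.5: drop
            continue
        counts = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        best = min(
            counts,
            key=lambda c: (
                -counts[c],
                _RESIDUE_ORDER.index(c) if c in _RESIDUE_ORDER else len(_RESIDUE_ORDER),
            ),
        )
        out.append(best)
    return "".join(out)


def conservation_profile(rows) -> list[ConservationColumn]:
    """Exact per-column residue frequencies with figure-style bins.

    The bin is assigned from the maximum non-gap residue frequency:
    > 45% dark-red, > 35% red, > 25% pink, otherwise "below".  Columns with
    >= 50% gaps are kept but flagged ``majority_gapped``.
    """
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("conservation profile needs >= 2 sequences")
    out = []
    n = len(rows)
    for j, col in enumerate(zip(*rows)):
        residues = [c for c in col if c != "-"]
        freqs = {}
        for c in residues:
            freqs[c] = freqs.get(c, 0) + Fraction(1)
        total = sum(freqs.values())
        if total:
            freqs = {c: v / total for c, v in freqs.items()}
        top = max(freqs.values()) if freqs else Fraction(0)
        if top > Fraction(45, 100):
            label = ">45%"
        elif top > Fraction(35, 100):
            label = ">35%"
        elif top > Fraction(25, 100):
            label = ">25%"
        else:
            label = "below"
        out.append(
            ConservationColumn(
                index=j,
                frequencies={c: float(v) for c, v in freqs.items()},
                gap_fraction=(n - len(residues)) / n,
                bin=label,
                majority_gapped=2 * (n - len(residues)) >= n,
            )
        )
    return out


def _round_half_up(value: Fraction) -> int:
    return int(
        Decimal(value.numerator) / Decimal(value.denominator)
    ) if value.denominator == 1 else int(
        (Decimal(value.numerator) / Decimal(value.denominator)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_clusters(summaries) -> dict:
    """Summary statistics over per-cluster rows (exact integer arithmetic).

    Returns min/max/mean for LTR, internal and POL-3'LTR sizes, the number of
    clusters, per-missing-domain-pattern defective counts, TRP28 status
    counts, and the total tandem-array count.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no cluster summaries")

    def stats(values):
        values = [v for v in values if v is not None]
        if not values:
            return None
        total = Fraction(sum(values), len(values))
        return {"min": min(values), "max": max(values), "mean": _round_half_up(total)}

    patterns = {}
    for s in summaries:
        missing = tuple(
            name
            for name, flag in (("GAG", s.gag), ("AP", s.ap), ("RH", s.rh), ("INT", s.int_))
            if not flag
        )
        if missing:
            patterns[missing] = patterns.get(missing, 0) + 1
    trp28 = {"YES": 0, "NO": 0, "SHORT": 0}
    for s in summaries:
        trp28[s.trp28] = trp28.get(s.trp28, 0) + 1
    return {
        "n_clusters": len(summaries),
        "ltr_bp": stats([s.ltr_bp for s in summaries]),
        "internal_bp": stats([s.internal_bp for s in summaries]),
        "pol3ltr_bp": stats([s.pol3ltr_bp for s in summaries]),
        "total_copies": sum(s.copy_number for s in summaries),
        "defective_clusters": sum(patterns.values()),
        "defective_patterns": patterns,
        "trp28_status": trp28,
        "total_tandem_arrays": sum(s.tandem_arrays for s in summaries),
    }


def load_reference_cluster_table(path=None) -> list[ClusterSummary]:
    """The packaged literature-derived table of 63 Retand PRARE clusters."""
    if path is None:
        path = package_data_path("retand_cluster_table.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(
            ClusterSummary(
                cluster=r["cluster"],
                copy_number=int(r["copy_number"]),
                ltr_bp=int(r["ltr_bp"]),
                internal_bp=int(r["internal_bp"]),
                pol3ltr_bp=int(r["pol3ltr_bp"]),
                gag=r["gag"] == "YES",
                ap=r["ap"] == "YES",
                rh=r["rh"] == "YES",
                int_=r["int"] == "YES",
                trp28=str(r["trp28"]),
                other_domains=tuple(
                    [] if r["other_domains"] == "-" else str(r["other_domains"]).split("/")
                ),
                tandem_arrays=int(r["tandem_arrays"]),
                group=str(r["group"]),
            )
        )
    return out
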