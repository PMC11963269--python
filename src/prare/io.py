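"""FASTA / GFF3 / TSV / JSON-lines readers and writers.

All in-memory coordinates are 0-based half-open on the forward strand; GFF3
output converts to the format's 1-based inclusive convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence with free-text provenance."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GffFeature:
    seqid: str
    type: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."
    source: str = "prare"
    score: str = "."
    attributes: dict = field(default_factory=dict)


def read_fasta(path) -> list[GenomeRecord]:
    return [
        GenomeRecord(rec.id, str(rec.seq).upper(), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path) -> None:
    seqs = [
        SeqRecord(Seq(rec.seq), id=rec.id, description=rec.description)
        for rec in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def _fmt_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        str(f.score),
                        f.strand,
                        ".",
                        _fmt_attrs(f.attributes),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GffFeature]:
    """Read a GFF3 file back into GffFeature records (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for f in db.all_features(order_by=("seqid", "start")):
        attrs = {k: v[0] if len(v) == 1 else ",".join(v) for k, v in f.attributes.items()}
        out.append(
            GffFeature(
                seqid=f.seqid,
                source=f.source,
                type=f.featuretype,
                start=f.start - 1,
                end=f.end,
                strand=f.strand or ".",
                score=str(f.score) if f.score is not None else ".",
                attributes=attrs,
            )
        )
    return out


def write_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if dataclasses.is_dataclass(rec):
                rec = dataclasses.asdict(rec)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def package_data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name
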