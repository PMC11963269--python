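"""Small DNA/protein sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

DNA_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

# Codon preferred per amino acid (first codon in the standard table); used for
# deterministic codon-wise construction of planted coding regions.
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(dna: str) -> str:
    """Translate a DNA string (standard code); partial tail codons dropped,
    ambiguous (N-containing) codons become X, stops become ``*``."""
    usable = len(dna) - len(dna) % 3
    if usable == 0:
        return ""
    return str(Seq(dna[:usable]).translate())


def random_dna(rng: np.random.Generator, length: int, gc: float | None = None) -> str:
    """I.i.d. random DNA; uniform base composition unless ``gc`` is given."""
    if gc is None:
        probs = None
    else:
        at = (1.0 - gc) / 2.0
        probs = [at, gc / 2.0, gc / 2.0, at]
    idx = rng.choice(4, size=length, p=probs)
    return "".join(DNA_ALPHABET[i] for i in idx)


def random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 20, size=length)
    return "".join(AA_ALPHABET[i] for i in idx)


def encode_protein(rng: np.random.Generator, protein: str, stop: bool = True) -> str:
    """Codon-wise DNA for a protein, with rng-chosen synonymous codons.

    The protein is encoded as given (no start codon is prepended); append an
    ``ATG``-initiated protein yourself if a translatable ORF is wanted.
    """
    parts = []
    for aa in protein:
        codons = _CODONS[aa.upper()]
        parts.append(codons[int(rng.integers(0, len(codons)))])
    if stop:
        parts.append(STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))])
    return "".join(parts)


def mutate_protein(rng: np.random.Generator, protein: str, n_subs: int) -> str:
    """Substitute ``n_subs`` distinct positions with different residues."""
    if n_subs == 0:
        return protein
    seq = list(protein)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        choices = [a for a in AA_ALPHABET if a != seq[pos]]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def substitute_dna(rng: np.random.Generator, seq: str, positions) -> str:
    """Substitute the given positions with a different base each."""
    out = list(seq)
    for pos in positions:
        choices = [b for b in DNA_ALPHABET if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def stratified_positions(rng: np.random.Generator, length: int, k: int) -> list[int]:
    """k distinct positions, one drawn per equal-length segment of [0, length).

    Keeps the longest untouched run at roughly ``length / (k + 1)``; used for
    diverged-LTR decoys so no long exact repeat survives by chance.
    """
    if k <= 0:
        return []
    bounds = np.linspace(0, length, k + 1).astype(int)
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out.append(int(rng.integers(lo, max(lo + 1, hi))))
    return sorted(set(out))


def mutate_protein_interior(
    rng: np.random.Generator, protein: str, n_subs: int, protect: int = 8
) -> str:
    """Substitute ``n_subs`` interior positions, never the first/last ``protect``.

    Used by the synthetic RT panel builder: real RT domains are delimited by
    conserved motifs, so keeping the termini invariant makes cross-lineage
    local alignments span the complete domain as they do for real sequences.
    """
    if n_subs == 0:
        return protein
    seq = list(protein)
    interior = np.arange(protect, len(seq) - protect)
    positions = rng.choice(interior, size=min(n_subs, len(interior)), replace=False)
    for pos in positions:
        choices = [a for a in AA_ALPHABET if a != seq[pos]]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)
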