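"""Synthetic reference RT panels.

The mining stage needs two protein inputs: a small set of Retand reverse
transcriptase (RT) domain queries (named after four well characterised Retand
elements: Tat4-1, Gret1, Cinful-1 and Grande1-4; 159/159/159/160 aa) and a
62-sequence model panel spanning the plant Gypsy and Copia lineages plus two
Caulimoviridae outgroup sequences, used to decide whether a candidate RT
clusters with the Retand lineage.

The real accession sequences are not shipped; the packaged FASTA files
(``*.synthetic.faa``) are deterministic synthetic stand-ins built by
:func:`build_panels`: a random 160-aa ancestral RT is diverged into lineage
ancestors (35% substitutions; 55% for the Caulimoviridae outgroup) and each
lineage ancestor into member sequences (8% substitutions).  This preserves the
property the pipeline relies on — within-lineage distances are much smaller
than between-lineage distances — without claiming biological realism.
"""

from __future__ import annotations

import numpy as np

from .io import GenomeRecord, package_data_path, read_fasta
from .seqtools import mutate_protein_interior, random_protein

PANEL_SEED = 20240914

RETAND_QUERY_NAMES = ("Tat4-1", "Gret1", "Cinful-1", "Grande1-4")
RETAND_QUERY_LENGTHS = (159, 159, 159, 160)

GYPSY_LINEAGES = (
    "Athila", "Clamyvir", "CRM", "Galadriel", "Ogre", "Phygy",
    "Reina", "Selgy", "Tat", "Tcn1", "Tekay",
)
COPIA_LINEAGES = ("Ale", "Angela", "Ivana")

_RT_LEN = 160
_LINEAGE_DIVERGENCE = 0.35
_OUTGROUP_DIVERGENCE = 0.55
_MEMBER_DIVERGENCE = 0.08


def build_panels(seed: int = PANEL_SEED):
    """Return (retand_queries, model_panel) as lists of (header, sequence).

    Headers follow the ``lineage|name`` convention used by the lineage
    assignment stage.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    root = random_protein(rng, _RT_LEN)

    def members(ancestor: str, lineage: str, names):
        out = []
        for name in names:
            seq = mutate_protein_interior(rng, ancestor, round(_MEMBER_DIVERGENCE * len(ancestor)))
            out.append((f"{lineage}|{name}", seq))
        return out

    retand_ancestor = mutate_protein_interior(rng, root, round(_LINEAGE_DIVERGENCE * _RT_LEN))
    queries = []
    for name, length in zip(RETAND_QUERY_NAMES, RETAND_QUERY_LENGTHS):
        seq = mutate_protein_interior(rng, retand_ancestor, round(_MEMBER_DIVERGENCE * _RT_LEN))
        if length < len(seq):  # trim from the N-terminus to hit the stated length
            seq = seq[len(seq) - length :]
        queries.append((f"Retand|{name}", seq))

    panel = list(queries)
    for lineage in GYPSY_LINEAGES + COPIA_LINEAGES:
        ancestor = mutate_protein_interior(rng, root, round(_LINEAGE_DIVERGENCE * _RT_LEN))
        panel.extend(members(ancestor, lineage, [f"{lineage}-{i}" for i in range(1, 5)]))
    caulimo = mutate_protein_interior(rng, root, round(_OUTGROUP_DIVERGENCE * _RT_LEN))
    panel.extend(members(caulimo, "Caulimoviridae", ["CaMV-like", "BSV-like"]))
    return queries, panel


def retand_ancestor_rt(seed: int = PANEL_SEED) -> str:
    """The Retand lineage ancestral RT used as the RT domain-profile consensus."""
    rng = np.random.default_rng(seed)
    root = random_protein(rng, _RT_LEN)
    return mutate_protein_interior(rng, root, round(_LINEAGE_DIVERGENCE * _RT_LEN))


def load_retand_queries() -> list[GenomeRecord]:
    return read_fasta(package_data_path("retand_rt_queries.synthetic.faa"))


def load_model_panel() -> list[GenomeRecord]:
    return read_fasta(package_data_path("model_rt_panel.synthetic.faa"))


AUX_DOMAIN_LENGTHS = {
    "TRP28": 60,
    "GAG": 70,
    "AP": 55,
    "RH": 65,
    "INT": 85,
    "Smc": 60,
    "DNA-topoisomerase-2": 60,
    "DNA-pol-III-gamma-tau": 60,
    "Mis12": 50,
    "mitotic-checkpoint": 50,
    "TolA": 50,
    "recombination-inhibitor": 50,
}


def build_profile_consensi(seed: int = PANEL_SEED) -> dict[str, str]:
    """Deterministic consensus peptides for the packaged toy domain profiles.

    The RT consensus is the synthetic Retand ancestral RT so that planted RT
    regions (exact copies of the packaged queries, 8% diverged from that
    ancestor) score far above a null-calibrated threshold.
    """
    rng = np.random.default_rng(seed + 1)
    consensi = {"RT": retand_ancestor_rt(seed)}
    for name, length in AUX_DOMAIN_LENGTHS.items():
        consensi[name] = random_protein(rng, length)
    return consensi
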