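"""Protein multiple alignment: a small native progressive aligner.

Pairwise guide distances come from global alignments (Biopython
``PairwiseAligner``, BLOSUM62, affine gaps); the guide tree is UPGMA (scipy
linkage, 'average'); profiles are merged by profile–profile dynamic
programming with column scores ``f_i^T B f_j`` (frequency-weighted BLOSUM62
over non-gap residues) and affine gap penalties.  Removing gap columns always
recovers the input sequences — the aligner only inserts gaps.

This is deliberately modest: panels here are tens of sequences of ~160
residues, where a simple progressive strategy is accurate and exactly
reproducible.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqtools import AA_ALPHABET

_GAP_OPEN = -11.0
_GAP_EXT = -1.0
_B62 = substitution_matrices.load("BLOSUM62")
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
# average substitution score for an unknown residue, used for X etc.
_B20 = np.array([[float(_B62[a, b]) for b in AA_ALPHABET] for a in AA_ALPHABET])


class MultipleAlignment:
    """An ordered protein MSA: ids plus equal-length gapped rows."""

    def __init__(self, ids, rows):
        if len(set(len(r) for r in rows)) > 1:
            raise ValueError("alignment rows differ in length")
        self.ids = list(ids)
        self.rows = list(rows)

    def __len__(self):
        return len(self.rows)

    @property
    def n_columns(self):
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id):
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id):
        return self.row(seq_id).replace("-", "")

    def column(self, j):
        return [r[j] for r in self.rows]

    def take_columns(self, indices) -> "MultipleAlignment":
        rows = ["".join(r[j] for j in indices) for r in self.rows]
        return MultipleAlignment(self.ids, rows)


def _global_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _B62
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXT
    return aligner


def pairwise_identity(a: str, b: str, aligner=None) -> float:
    """Matches / alignment length of one optimal global alignment."""
    if a == b:
        return 1.0
    if aligner is None:
        aligner = _global_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def _profile_freqs(rows):
    """(L, 20) per-column amino-acid frequencies over non-gap residues;
    unknown residues count as uniform background."""
    L = len(rows[0])
    F = np.zeros((L, 20))
    for r in rows:
        for j, aa in enumerate(r):
            if aa == "-":
                continue
            k = _AA_INDEX.get(aa)
            if k is None:
                F[j] += 1.0 / 20.0
            else:
                F[j, k] += 1.0
    totals = F.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return F / totals


def _align_profiles(rows_a, rows_b):
    """Global profile–profile alignment; returns merged (rows_a', rows_b')."""
    Fa = _profile_freqs(rows_a)
    Fb = _profile_freqs(rows_b)
    S = Fa @ _B20 @ Fb.T  # (La, Lb) expected column-pair score
    La, Lb = S.shape
    NEG = -1e9
    H = np.full((La + 1, Lb + 1), NEG)
    E = np.full((La + 1, Lb + 1), NEG)  # gap in A (consume B)
    F_ = np.full((La + 1, Lb + 1), NEG)  # gap in B (consume A)
    ptr = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0 diag, 1 up(A), 2 left(B)
    H[0, 0] = 0.0
    for j in range(1, Lb + 1):
        E[0, j] = _GAP_OPEN + (j - 1) * _GAP_EXT
        H[0, j] = E[0, j]
        ptr[0, j] = 2
    for i in range(1, La + 1):
        F_[i, 0] = _GAP_OPEN + (i - 1) * _GAP_EXT
        H[i, 0] = F_[i, 0]
        ptr[i, 0] = 1
    for i in range(1, La + 1):
        Erow = E[i]
        Hrow = H[i]
        Hprev = H[i - 1]
        Fprev = F_[i - 1]
        Frow = F_[i]
        Si = S[i - 1]
        for j in range(1, Lb + 1):
            Erow[j] = max(Erow[j - 1] + _GAP_EXT, Hrow[j - 1] + _GAP_OPEN)
            Frow[j] = max(Fprev[j] + _GAP_EXT, Hprev[j] + _GAP_OPEN)
            diag = Hprev[j - 1] + Si[j - 1]
            best = diag
            p = 0
            if Frow[j] > best:
                best, p = Frow[j], 1
            if Erow[j] > best:
                best, p = Erow[j], 2
            Hrow[j] = best
            ptr[i, j] = p
    # traceback
    i, j = La, Lb
    ops = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            ops.append("D")
            i, j = i - 1, j - 1
        elif p == 1 and i > 0:
            ops.append("A")
            i -= 1
        else:
            ops.append("B")
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "A"):
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            ia += 1
        else:
            for r_out in out_a:
                r_out.append("-")
        if op in ("D", "B"):
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
        else:
            for r_out in out_b:
                r_out.append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align_panel(sequences) -> MultipleAlignment:
    """Progressive multiple alignment of named protein sequences.

    ``sequences``: mapping id -> sequence, or iterable of (id, sequence).
    Requires at least two sequences (one is returned as-is).
    """
    if hasattr(sequences, "items"):
        items = list(sequences.items())
    else:
        items = [(i, s) for i, s in sequences]
    if not items:
        raise ValueError("no sequences to align")
    ids = [i for i, _ in items]
    seqs = [s.upper() for _, s in items]
    if len(items) == 1:
        return MultipleAlignment(ids, seqs)

    aligner = _global_aligner()
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - pairwise_identity(seqs[i], seqs[j], aligner)
    Z = linkage(squareform(D, checks=False), method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b = _align_profiles(rows_a, rows_b)
        clusters[n + step] = (idx_a + idx_b, new_a + new_b)
    order, rows = clusters.popitem()[1]
    # restore input order
    by_input = dict(zip(order, rows))
    return MultipleAlignment(ids, [by_input[i] for i in range(n)])
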