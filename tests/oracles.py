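"""Independent brute-force oracles used to validate the pipeline's detectors.

Everything here is deliberately written from the operation definitions, not
from the package implementations: plain dynamic programming and exhaustive
enumeration, at sizes where that is affordable.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = _B62.alphabet
_AIDX = {a: i for i, a in enumerate(_ALPHA)}
_MAT = np.array(_B62)

GAP_OPEN = 12.0  # first gapped position; a length-k gap costs 11 + k
GAP_EXT = 1.0


def sw_best_local(target: str, query: str):
    """Best local alignment (score, t_start, t_end) by full affine-gap DP.

    Returns (0.0, 0, 0) when no positive-scoring alignment exists.  Ties are
    resolved toward the smallest (end, start) — matching nothing in the
    implementation; callers compare scores and spans of planted hits, which
    are unique optima by construction.
    """
    n, m = len(target), len(query)
    t = np.array([_AIDX[c] for c in target], dtype=np.int64)
    q = np.array([_AIDX[c] for c in query], dtype=np.int64)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    F = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    S = _MAT[t[:, None], q[None, :]]
    for i in range(1, n + 1):
        Ei = E[i]
        Hi = H[i]
        Him1 = H[i - 1]
        F[i] = np.maximum(F[i - 1] - GAP_EXT, Him1 - GAP_OPEN)
        row_s = S[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Ei[j - 1] - GAP_EXT, Hi[j - 1] - GAP_OPEN)
            Hi[j] = max(0.0, Him1[j - 1] + row_s[j - 1], Ei[j], F[i, j])
    best = float(H.max())
    if best <= 0:
        return 0.0, 0, 0
    ends = np.argwhere(H == best)
    i, j = map(int, ends[min(range(len(ends)), key=lambda k: (ends[k][0], ends[k][1]))])
    # traceback to find t_start
    ti, tj = i, j
    state = "H"
    while ti > 0 and tj > 0:
        if state == "H":
            h = H[ti, tj]
            if h == 0:
                break
            if h == H[ti - 1, tj - 1] + S[ti - 1, tj - 1]:
                ti, tj = ti - 1, tj - 1
            elif h == E[ti, tj]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            from_h = E[ti, tj] == H[ti, tj - 1] - GAP_OPEN
            tj -= 1
            state = "H" if from_h else "E"
        else:  # F
            from_h = F[ti, tj] == H[ti - 1, tj] - GAP_OPEN
            ti -= 1
            state = "H" if from_h else "F"
    return best, ti, i


def sw_all_hits(target: str, query: str, min_score: float):
    """All non-overlapping local alignments >= min_score, best-first (masking)."""
    hits = []
    work = target
    while True:
        score, a, b = sw_best_local(work, query)
        if score < min_score or b == a:
            break
        hits.append((a, b, score))
        work = work[:a] + "*" * (b - a) + work[b:]
    return hits


def orf_scan_oracle(seq: str, min_len: int):
    """Maximal ATG-to-stop ORFs by literal codon walking in all six frames.

    Returns a set of (start, end, strand) spans in forward coordinates, ends
    including the stop codon.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    stops = {"TAA", "TAG", "TGA"}
    out = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
        for frame in range(3):
            pos = frame
            start = None
            while pos + 3 <= n:
                codon = s[pos : pos + 3]
                if start is None and codon == "ATG":
                    start = pos
                if codon in stops and start is not None:
                    a, b = start, pos + 3
                    if b - a >= min_len:
                        span = (a, b) if strand == "+" else (n - b, n - a)
                        out.add((span[0], span[1], strand))
                    start = None
                elif codon in stops:
                    start = None
                pos += 3
    return out


def tandem_oracle(seq: str, min_copies: int = 3, max_period: int = 20):
    """Exhaustive exact tandem-array search over all (start, period).

    Leftmost-maximal arrays with >= min_copies exact copies; overlaps resolved
    by (copies * period) descending, then smaller period, then leftmost start
    — the same resolution order the detector documents.
    Returns [(start, end, period, copies)].
    """
    n = len(seq)
    candidates = []
    for p in range(1, max_period + 1):
        for start in range(0, n - 2 * p):
            unit = seq[start : start + p]
            m = 1
            while seq[start + m * p : start + (m + 1) * p] == unit:
                m += 1
            if m < min_copies:
                continue
            if start >= 1 and seq[start - 1] == seq[start - 1 + p]:
                continue  # not leftmost
            candidates.append((start, start + m * p, p, m))
    candidates = sorted(set(candidates), key=lambda c: (-(c[3] * c[2]), c[2], c[0]))
    kept = []
    for c in candidates:
        if any(c[0] < k[1] and k[0] < c[1] for k in kept):
            continue
        kept.append(c)
    return sorted(kept)


def enumerate_topologies(labels):
    """All distinct unrooted binary topologies as frozensets of bipartitions."""
    # trees as nested tuples, grown by inserting each leaf into every edge
    def _replace(tree, path, new):
        if not path:
            return new
        k = path[0]
        return tuple(
            _replace(child, path[1:], new) if i == k else child
            for i, child in enumerate(tree)
        )

    base = (labels[0], labels[1], labels[2])
    trees = [base]
    for leaf in labels[3:]:
        nxt = []
        for t in trees:
            # insert at every edge: every child position of every internal tuple
            def edges(node, path):
                res = []
                if isinstance(node, tuple):
                    for k, child in enumerate(node):
                        res.append(path + (k,))
                        res.extend(edges(child, path + (k,)))
                return res
            for path in edges(t, ()):
                sub = t
                for k in path:
                    sub = sub[k]
                nxt.append(_replace(t, path, (sub, leaf)))
        trees = nxt

    def bipartitions(tree, all_labels):
        full = frozenset(all_labels)
        splits = set()
        def leaves(node):
            if isinstance(node, tuple):
                out = set()
                for ch in node:
                    out |= leaves(ch)
                return out
            return {node}
        def rec(node):
            if not isinstance(node, tuple):
                return
            for ch in node:
                ls = frozenset(leaves(ch))
                if 1 < len(ls) < len(all_labels) - 1:
                    splits.add(min(ls, full - ls, key=lambda s: (len(s), sorted(s))))
                rec(ch)
        rec(tree)
        return frozenset(splits)

    seen = {}
    for t in trees:
        key = bipartitions(t, labels)
        seen.setdefault(key, t)
    return list(seen.keys())


def ls_best_topology(labels, D):
    """Exhaustive least-squares topology search for an additive matrix.

    For each topology, branch lengths are fit by unconstrained least squares
    on the path-incidence system; the topology with the smallest residual is
    returned as a frozenset of bipartitions (leaf-name frozensets).
    """
    labels = list(labels)
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    pairs = list(itertools.combinations(range(n), 2))
    y = np.array([D[i, j] for i, j in pairs])
    best = None
    for splits in enumerate_topologies(labels):
        # edges: one terminal edge per leaf + one internal edge per split
        cols = [frozenset([l]) for l in labels] + list(splits)
        A = np.zeros((len(pairs), len(cols)))
        for r, (i, j) in enumerate(pairs):
            for c, side in enumerate(cols):
                # edge separates i from j iff exactly one of them is in `side`
                a, b = labels[i] in side, labels[j] in side
                if a != b:
                    A[r, c] = 1.0
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ coef - y) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, splits)
    return best[1]


def random_additive_matrix(labels, rng):
    """A random additive distance matrix and its generating topology.

    A random unrooted binary tree over ``labels`` is drawn (sequential leaf
    insertion at a uniformly chosen edge, branch lengths uniform in
    [0.5, 2.0]); returns (matrix, frozenset-of-bipartitions).
    """
    import collections
    import heapq

    topo = (labels[0], labels[1], labels[2])

    def _replace(tree, path, new):
        if not path:
            return new
        k = path[0]
        return tuple(
            _replace(c, path[1:], new) if i == k else c for i, c in enumerate(tree)
        )

    def edges(node, path):
        res = []
        if isinstance(node, tuple):
            for k, c in enumerate(node):
                res.append(path + (k,))
                res.extend(edges(c, path + (k,)))
        return res

    for leaf in labels[3:]:
        es = edges(topo, ())
        path = es[int(rng.integers(0, len(es)))]
        sub = topo
        for k in path:
            sub = sub[k]
        topo = _replace(topo, path, (sub, leaf))

    G = collections.defaultdict(list)
    counter = [0]

    def build(node):
        if not isinstance(node, tuple):
            return node
        nid = f"__n{counter[0]}"
        counter[0] += 1
        for c in node:
            cid = build(c)
            w = float(rng.uniform(0.5, 2.0))
            G[nid].append((cid, w))
            G[cid].append((nid, w))
        return nid

    build(topo)
    n = len(labels)
    M = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        pq = [(0.0, src)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist.get(u, 1e18):
                continue
            for v, w in G[u]:
                if d + w < dist.get(v, 1e18):
                    dist[v] = d + w
                    heapq.heappush(pq, (d + w, v))
        for j, dst in enumerate(labels):
            M[i, j] = dist[dst]

    def leaves(node):
        if isinstance(node, tuple):
            s = set()
            for c in node:
                s |= leaves(c)
            return s
        return {node}

    full = frozenset(labels)
    splits = set()

    def rec(nd):
        if not isinstance(nd, tuple):
            return
        for c in nd:
            ls = frozenset(leaves(c))
            if 1 < len(ls) < n - 1:
                splits.add(min(ls, full - ls, key=lambda s: (len(s), sorted(s))))
            rec(c)

    rec(topo)
    return M, frozenset(splits)
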