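"""Distance phylogenetics: p-distances, neighbor-joining, bootstrap, lineage calls.

The NJ implementation is authored here (rather than delegated) because exact
reproducibility requires a fixed tie-break: when several pairs minimise the
Saitou–Nei Q criterion, the pair whose sorted cluster labels are
lexicographically smallest is joined (a cluster is labelled by its smallest
member leaf name).  Negative branch-length estimates are clamped to zero.
Trees are returned as dendropy objects (midpoint rooting, bipartitions,
Newick I/O come from dendropy).
"""

from __future__ import annotations

import numpy as np
import dendropy

from .align import MultipleAlignment


class _Node:
    __slots__ = ("children", "label", "mask", "edge_length")

    def __init__(self, label, mask, edge_length=None):
        self.children = []
        self.label = label
        self.mask = mask
        self.edge_length = edge_length


def p_distance_matrix(msa: MultipleAlignment):
    """Pairwise p-distances over ungapped shared columns.

    Returns (ids, matrix).  Pairs sharing no ungapped column get distance 1.
    """
    ids = list(msa.ids)
    enc = _encode(msa)
    M, V = _match_shared(enc, np.arange(enc.shape[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(V > 0, (V - M) / np.maximum(V, 1), 1.0)
    np.fill_diagonal(D, 0.0)
    return ids, D


def _encode(msa: MultipleAlignment):
    """Rows as int codes; gap = -1."""
    alphabet = sorted(set("".join(msa.rows)) - {"-"})
    index = {c: i for i, c in enumerate(alphabet)}
    out = np.full((len(msa.rows), msa.n_columns), -1, dtype=np.int16)
    for i, r in enumerate(msa.rows):
        for j, c in enumerate(r):
            if c != "-":
                out[i, j] = index[c]
    return out


def _match_shared(enc, cols):
    """(matches, shared-column counts) for all pairs over the given columns."""
    sub = enc[:, cols]
    K = int(sub.max()) + 1 if sub.size else 1
    n, L = sub.shape
    onehot = np.zeros((n, K * L), dtype=np.float32)
    for k in range(K):
        onehot[:, k * L : (k + 1) * L] = sub == k
    M = onehot @ onehot.T
    ng = (sub >= 0).astype(np.float32)
    V = ng @ ng.T
    return M, V


def check_distance_matrix(D) -> None:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any() or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distances must be >= 0 with a zero diagonal")


def _nj_nodes(labels, D):
    """Core NJ; returns the root _Node of a tree with a trifurcating base
    (or a 2-child base for matrices reduced to two clusters)."""
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    D = np.asarray(D, dtype=float).copy()
    check_distance_matrix(D)
    nodes = [_Node(labels[i], 1 << i) for i in range(n)]
    labs = list(labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin))
        best = min(
            (tuple(sorted((labs[active[i]], labs[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        ai, aj = active[i], active[j]
        d_ij = sub[i, j]
        bu = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        bv = d_ij - bu
        u, v = nodes[ai], nodes[aj]
        u.edge_length = max(0.0, bu)
        v.edge_length = max(0.0, bv)
        new = _Node(min(u.label, v.label), u.mask | v.mask)
        new.children = [u, v]
        new_d = 0.5 * (D[ai, active] + D[aj, active] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = new_d
        D[active, -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(new)
        labs.append(new.label)
        active = [a for a in active if a not in (ai, aj)] + [len(labs) - 1]

    # final star: three-point formulas
    a, b, c = active
    root = _Node(min(labs[a], labs[b], labs[c]), nodes[a].mask | nodes[b].mask | nodes[c].mask)
    d_ab, d_ac, d_bc = D[a, b], D[a, c], D[b, c]
    for node, bl in (
        (nodes[a], 0.5 * (d_ab + d_ac - d_bc)),
        (nodes[b], 0.5 * (d_ab + d_bc - d_ac)),
        (nodes[c], 0.5 * (d_ac + d_bc - d_ab)),
    ):
        node.edge_length = max(0.0, bl)
        root.children.append(node)
    return root


def _collect_masks(root, n_taxa):
    """Normalized bipartition masks for all internal edges."""
    full = (1 << n_taxa) - 1
    masks = set()

    def walk(node):
        for ch in node.children:
            if ch.children:  # internal edge
                masks.add(min(ch.mask, full ^ ch.mask))
            walk(ch)

    walk(root)
    return masks


def _to_dendropy(root, labels, supports=None, replicates=None) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    full = (1 << len(labels)) - 1

    def build(node, dnode):
        dnode.edge.length = node.edge_length
        if not node.children:
            dnode.taxon = ns.get_taxon(node.label)
            return
        if supports is not None:
            mask = min(node.mask, full ^ node.mask)
            if node.mask != full:
                dnode.label = str(supports.get(mask, 0))
        for ch in node.children:
            build(ch, dnode.new_child())

    build(root, tree.seed_node)
    tree.is_rooted = False
    return tree


def nj_tree(labels, D) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix (ids in ``labels``)."""
    root = _nj_nodes(list(labels), D)
    return _to_dendropy(root, list(labels))


def tree_bipartitions(labels, D) -> set:
    """Normalized bipartition masks of the NJ tree (taxon i ↔ bit i)."""
    root = _nj_nodes(list(labels), D)
    return _collect_masks(root, len(labels))


def bootstrap_support(
    msa: MultipleAlignment, replicates: int, rng_seed: int
):
    """NJ tree with bootstrap supports from alignment-column resampling.

    Returns (tree, supports): supports maps each internal bipartition of the
    full-alignment NJ tree (as a frozenset of leaf names on the smaller side)
    to the number of replicate trees containing it, on the replicate scale.
    Bipartitions absent from a replicate count 0.  Deterministic per seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if msa.n_columns < 2:
        raise ValueError("alignment must have at least 2 columns")
    labels = list(msa.ids)
    enc = _encode(msa)
    n_cols = enc.shape[1]
    rng = np.random.default_rng(rng_seed)

    ids, D = p_distance_matrix(msa)
    base_root = _nj_nodes(labels, D)
    base_masks = _collect_masks(base_root, len(labels))

    counts = {mask: 0 for mask in base_masks}
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        M, V = _match_shared(enc, cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            Dr = np.where(V > 0, (V - M) / np.maximum(V, 1), 1.0)
        np.fill_diagonal(Dr, 0.0)
        Dr = 0.5 * (Dr + Dr.T)  # exact symmetry against float noise
        try:
            rep_masks = _collect_masks(_nj_nodes(labels, Dr), len(labels))
        except ValueError:
            continue
        for mask in base_masks & rep_masks:
            counts[mask] += 1

    supports = {mask: counts[mask] for mask in base_masks}
    tree = _to_dendropy(base_root, labels, supports=supports)
    named = {
        frozenset(
            labels[i] for i in range(len(labels)) if mask >> i & 1
        ): count
        for mask, count in supports.items()
    }
    return tree, named


def midpoint_rooted(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=True)
    return t


def _lineage_of(header: str) -> str:
    return header.split("|")[0] if "|" in header else ""


def assign_lineage(
    candidate_seqs: dict,
    panel_seqs: dict,
    retand_ids=None,
    aligner_fn=None,
) -> dict:
    """Label candidate RT proteins by reference clade membership.

    ``panel_seqs`` maps ``lineage|name`` headers to sequences; ``retand_ids``
    defaults to every panel id whose lineage is ``Retand``.  Candidates and
    panel are aligned together, an NJ tree is built on p-distances and
    midpoint-rooted; for each lineage, its reference clade is the smallest
    clade containing all its members — valid only if it contains no other
    panel member.  A candidate gets the lineage label of the smallest valid
    clade containing it, or "unassigned".
    """
    from .align import align_panel

    if retand_ids is None:
        retand_ids = [k for k in panel_seqs if _lineage_of(k) == "Retand"]
    if not retand_ids:
        raise ValueError("panel contains no Retand references")
    if not candidate_seqs:
        return {}
    overlap = set(candidate_seqs) & set(panel_seqs)
    if overlap:
        raise ValueError(f"candidate ids collide with panel ids: {sorted(overlap)[:3]}")

    seqs = {**panel_seqs, **candidate_seqs}
    msa = (aligner_fn or align_panel)(seqs)
    ids, D = p_distance_matrix(msa)
    tree = midpoint_rooted(nj_tree(ids, D))

    leaf_of = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    panel_lineages = {pid: _lineage_of(pid) for pid in panel_seqs}
    lineages = sorted(set(panel_lineages.values()))

    clades = []  # (size, lineage, set of leaf labels)
    for lineage in lineages:
        members = [pid for pid, lin in panel_lineages.items() if lin == lineage]
        mrca = tree.mrca(taxa=[leaf_of[m].taxon for m in members])
        leaves = {l.taxon.label for l in mrca.leaf_iter()}
        foreign = {
            l for l in leaves if l in panel_lineages and panel_lineages[l] != lineage
        }
        if not foreign:
            clades.append((len(leaves), lineage, leaves))
    clades.sort(key=lambda c: (c[0], c[1]))

    labels = {}
    for cid in candidate_seqs:
        labels[cid] = "unassigned"
        for _, lineage, leaves in clades:
            if cid in leaves:
                labels[cid] = lineage
                break
    return labels
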