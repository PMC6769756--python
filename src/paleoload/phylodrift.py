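"""Pseudo-haploid distances and neighbor-joining drift diagnostics.

Low sequencing depth distorts diploid distance estimates, so every genome
is reduced to a single allele per site drawn proportionally to its read
counts — the standard pseudo-haploid convention in ancient-DNA work.
Pairwise distances are mismatch fractions over nearly-neutral sites
(phyloP below the constraint threshold, at most one missing call across
the panel), and a Saitou-Nei neighbor-joining tree is built from them.
Internal branch lengths, in substitutions per nearly-neutral site, act as
proxies for genetic drift: a breed that went through a strong bottleneck
accumulates a long stem branch.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .datamodel import AlleleCountMatrix

MISSING = -1


def pseudo_haploidize(acm: AlleleCountMatrix, rng: np.random.Generator) -> np.ndarray:
    """One allele per (sample, site): deleterious with probability r/d.

    Returns an int8 matrix with 1 = deleterious allele, 0 = major allele,
    -1 = missing (no reads).  Deterministic given the generator state.
    """
    d = acm.d
    r = acm.r
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(d > 0, r / np.maximum(d, 1), 0.0)
    draw = (rng.random(p.shape) < p).astype(np.int8)
    draw[d == 0] = MISSING
    return draw


def neutral_site_filter(
    sites: Sequence,
    haploid: np.ndarray,
    max_missing: int = 1,
    phylop_threshold: float = 1.5,
) -> np.ndarray:
    """Mask of nearly-neutral sites usable for distance estimation:
    phyloP below threshold and at most ``max_missing`` missing calls."""
    neutral = np.array([s.phylop < phylop_threshold for s in sites])
    n_missing = (haploid == MISSING).sum(axis=0)
    return neutral & (n_missing <= max_missing)


def pairwise_distance(haploid: np.ndarray, site_mask: Optional[np.ndarray] = None):
    """Mismatch-fraction distance matrix over shared non-missing sites.

    Returns ``(D, n_shared)``; a pair with no shared site gets NaN, which
    :func:`nj_build` rejects.
    """
    h = haploid if site_mask is None else haploid[:, site_mask]
    n = h.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    present = h != MISSING
    D = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = present[i][None, :] & present
        diff = (h[i][None, :] != h) & both
        cnt = both.sum(axis=1)
        shared[i] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(cnt > 0, diff.sum(axis=1) / np.maximum(cnt, 1), np.nan)
    np.fill_diagonal(D, 0.0)
    return D, shared


def nj_build(D: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining, deterministic and exact on additive input.

    Joins minimise the standard Q criterion with ties broken by the lowest
    index pair; negative branch lengths are clamped to zero with the
    deficit shifted onto the sibling branch.  Returns an unrooted dendropy
    tree with branch lengths.
    """
    D = np.array(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix over at least three taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains missing entries")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        ci, cj = nodes[active[i]], nodes[active[j]]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        # distances from the new node to the remaining taxa
        new_idx = active[i]
        others = [a for k, a in enumerate(active) if k not in (i, j)]
        for a in others:
            D[new_idx, a] = D[a, new_idx] = 0.5 * (
                D[active[i], a] + D[active[j], a] - dij
            )
        nodes[new_idx] = parent
        active = [a for k, a in enumerate(active) if k != j]

    # final star join of the last three clusters
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float):
    """Clamp a negative branch to zero, moving the deficit to its sibling."""
    if li < 0.0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0.0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def root_tree(
    tree: dendropy.Tree,
    outgroup: Optional[str] = None,
    midpoint: bool = False,
) -> dendropy.Tree:
    """Root a tree at an outgroup taxon or at its midpoint."""
    rooted = tree.clone(depth=1)
    if outgroup is not None:
        og = rooted.taxon_namespace.get_taxon(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        node = rooted.find_node_with_taxon_label(outgroup)
        rooted.to_outgroup_position(node, update_bipartitions=False)
    elif midpoint:
        rooted.reroot_at_midpoint(update_bipartitions=False)
    else:
        raise ValueError("specify an outgroup or midpoint=True")
    rooted.is_rooted = True
    return rooted


def internal_branches(tree: dendropy.Tree, clades: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Stem branch length of each named clade, sorted descending.

    A clade that is not monophyletic in the tree is reported with a
    missing length.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # stem lengths are read relative to the seed node
    rows = []
    for name, tips in clades.items():
        tips = set(tips)
        mrca = tree.mrca(taxon_labels=sorted(tips))
        length = np.nan
        if mrca is not None:
            leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
            if leaves == tips and mrca.edge.length is not None:
                length = float(mrca.edge.length)
        rows.append({"clade": name, "n_tips": len(tips), "stem_length": length})
    df = pd.DataFrame(rows)
    return df.sort_values("stem_length", ascending=False, na_position="last").reset_index(
        drop=True
    )


def _bipartitions(tree: dendropy.Tree) -> set:
    tree.encode_bipartitions()
    out = set()
    n_leaves = len(tree.taxon_namespace)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.tail_node is None:
            continue
        bp = edge.bipartition.split_bitmask
        out.add(bp)
    return out


def bootstrap_support(
    haploid: np.ndarray,
    labels: Sequence[str],
    n_replicates: int,
    rng: np.random.Generator,
    site_mask: Optional[np.ndarray] = None,
):
    """Site-resampling bootstrap supports for the internal edges of the
    NJ tree.

    Returns ``(tree, supports)``: the tree built from the full data with
    internal-node labels set to the support fraction, and a dict keyed by
    split bitmask.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    h = haploid if site_mask is None else haploid[:, site_mask]
    D, _ = pairwise_distance(h)
    tree = nj_build(D, labels)
    counts: dict = {bp: 0 for bp in _bipartitions(tree)}
    n_sites = h.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        Db, _ = pairwise_distance(h[:, cols])
        rep = nj_build(Db, labels)
        for bp in _bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    supports = {bp: c / n_replicates for bp, c in counts.items()}
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.tail_node is None:
            continue
        sup = supports.get(edge.bipartition.split_bitmask)
        if sup is not None:
            edge.head_node.label = f"{100 * sup:.0f}"
    return tree, supports
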