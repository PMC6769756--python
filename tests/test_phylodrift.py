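"""Pseudo-haploid distances and neighbor joining, with an all-topology oracle."""
import itertools

import dendropy
import numpy as np
import pytest

from paleoload import phylodrift as pf
from paleoload.datamodel import AlleleCountMatrix, SampleMeta, SiteAnnotation


# ---------------------------------------------------------------------------
# oracle machinery: enumerate every unrooted topology, fit branch lengths by
# least squares on the path matrix, and find the (unique) additive fit


def _edge(a, b):
    return tuple(sorted((a, b)))


def enumerate_topologies(labels):
    """All unrooted binary topologies by stepwise tip insertion.

    A topology is a frozenset of edges between node ids; tips are 0..n-1,
    internal nodes get ids >= n.  Yields 1, 3, 15, 105 ... topologies.
    """
    n = len(labels)
    if n < 2:
        return [frozenset()]
    topologies = [frozenset([_edge(0, 1)])]
    for tip in range(2, n):
        new_topos = []
        for topo in topologies:
            internal = max([max(e) for e in topo] + [n - 1]) + 1
            for edge in topo:
                a, b = edge
                edges = set(topo)
                edges.remove(edge)
                edges.add(_edge(a, internal))
                edges.add(_edge(b, internal))
                edges.add(_edge(tip, internal))
                new_topos.append(frozenset(edges))
        topologies = new_topos
    return topologies


def paths_from_topology(edges, n_tips):
    """Tip-to-tip edge paths via adjacency walks."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    edge_list = sorted(edges)
    edge_index = {e: k for k, e in enumerate(edge_list)}
    paths = {}
    for i in range(n_tips):
        # BFS from tip i recording the edge path
        stack = [(i, None, [])]
        seen = {i}
        while stack:
            node, _, path = stack.pop()
            if node < n_tips and node != i:
                paths[(i, node)] = path
            for nb in adj.get(node, []):
                if nb not in seen:
                    seen.add(nb)
                    e = edge_index[_edge(node, nb)]
                    stack.append((nb, node, path + [e]))
    return edge_list, paths


def least_squares_fit(D, edges, n_tips):
    """OLS branch lengths for a fixed topology; returns (lengths, residual)."""
    edge_list, paths = paths_from_topology(edges, n_tips)
    rows, y = [], []
    for i in range(n_tips):
        for j in range(i + 1, n_tips):
            row = np.zeros(len(edge_list))
            row[paths[(i, j)]] = 1.0
            rows.append(row)
            y.append(D[i, j])
    A = np.array(rows)
    lengths, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    residual = float(np.abs(A @ lengths - y).max())
    return dict(zip(edge_list, lengths)), residual


def random_additive_tree(n, rng):
    """Random topology with positive branch lengths and its distance matrix."""
    topos = enumerate_topologies(list(range(n)))
    edges = sorted(topos[rng.integers(0, len(topos))])
    lengths = {e: rng.uniform(0.5, 3.0) for e in edges}
    edge_list, paths = paths_from_topology(frozenset(edges), n)
    D = np.zeros((n, n))
    for (i, j), path in paths.items():
        D[i, j] = D[j, i] = sum(lengths[edge_list[k]] for k in path)
    return edges, lengths, D


def tree_splits(tree):
    tree.encode_bipartitions()
    labels = [t.label for t in tree.taxon_namespace]
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None or edge.head_node.is_leaf():
            continue
        mask = edge.bipartition.split_bitmask
        side = frozenset(l for k, l in enumerate(labels) if (mask >> k) & 1)
        splits.add(min(side, frozenset(labels) - side, key=sorted))
    return splits


def topology_splits(edges, n_tips):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    splits = set()
    for a, b in edges:
        if a < n_tips and b < n_tips:
            continue
        # tips on the a-side of the (a, b) edge
        stack, seen = [a], {a, b}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_tips:
                side.add(str(node))
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 2 <= len(side) <= n_tips - 2:
            all_tips = frozenset(str(i) for i in range(n_tips))
            splits.add(min(frozenset(side), all_tips - side, key=sorted))
    return splits


# ---------------------------------------------------------------------------


class TestPseudoHaploidize:
    def _acm(self, r, d):
        r = np.asarray(r)
        samples = [SampleMeta(f"s{i}", "b", "other", 0.0, 5.0) for i in range(r.shape[0])]
        sites = [
            SiteAnnotation.from_fields("chr1", j + 1, "intergenic", 0.2, {"A": 45, "G": 1})
            for j in range(r.shape[1])
        ]
        return AlleleCountMatrix(samples, sites, r=r, d=np.asarray(d))

    def test_pure_reads_are_deterministic(self, rng):
        acm = self._acm([[5, 0, 0]], [[5, 5, 0]])
        hap = pf.pseudo_haploidize(acm, rng)
        assert hap.tolist() == [[1, 0, pf.MISSING]]

    def test_balanced_reads_draw_half(self):
        rng = np.random.default_rng(0)
        n = 40000
        acm = self._acm(np.full((1, n), 500), np.full((1, n), 1000))
        hap = pf.pseudo_haploidize(acm, rng)
        assert abs(hap.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_seeded_reproducibility(self):
        acm = self._acm([[3, 1], [2, 2]], [[6, 4], [4, 4]])
        h1 = pf.pseudo_haploidize(acm, np.random.default_rng(9))
        h2 = pf.pseudo_haploidize(acm, np.random.default_rng(9))
        np.testing.assert_array_equal(h1, h2)


class TestNeutralFilter:
    def test_phylop_and_missingness_rules(self):
        sites = [
            SiteAnnotation.from_fields("chr1", 1, "intergenic", 0.2, {"A": 45, "G": 1}),
            SiteAnnotation.from_fields("chr1", 2, "intergenic", 1.6, {"A": 45, "G": 1}),
            SiteAnnotation.from_fields("chr1", 3, "intergenic", -1.0, {"A": 45, "G": 1}),
        ]
        hap = np.array(
            [[0, 0, pf.MISSING], [1, 0, pf.MISSING], [0, 0, 1]], dtype=np.int8
        )
        mask = pf.neutral_site_filter(sites, hap)
        # site 1: neutral, complete -> kept; site 2: constrained -> dropped;
        # site 3: neutral but two missing calls -> dropped
        assert mask.tolist() == [True, False, False]


class TestPairwiseDistance:
    def test_hand_counts(self):
        hap = np.array(
            [
                [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
            ],
            dtype=np.int8,
        )
        D, shared = pf.pairwise_distance(hap)
        assert D[0, 1] == pytest.approx(0.3)
        assert D[0, 2] == pytest.approx(1.0)
        assert D[0, 0] == 0.0
        np.testing.assert_allclose(D, D.T)
        assert (shared == 10).all()

    def test_missing_pairs_shrink_denominator(self):
        hap = np.array([[0, 0, pf.MISSING, 1], [1, 0, 1, pf.MISSING]], dtype=np.int8)
        D, shared = pf.pairwise_distance(hap)
        assert shared[0, 1] == 2
        assert D[0, 1] == pytest.approx(0.5)

    def test_site_permutation_invariance(self, rng):
        hap = rng.integers(0, 2, size=(4, 50)).astype(np.int8)
        D1, _ = pf.pairwise_distance(hap)
        D2, _ = pf.pairwise_distance(hap[:, rng.permutation(50)])
        np.testing.assert_allclose(D1, D2)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # matrix from the tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = pf.nj_build(D, list("ABCD"))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(D[i, j])

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        tree = pf.nj_build(D, list("ABC"))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.4 - 0.3) / 2)

    def test_tied_star_matrix_is_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = pf.nj_build(D, list("ABCD")).as_string(schema="newick")
        t2 = pf.nj_build(D, list("ABCD")).as_string(schema="newick")
        assert t1 == t2

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_recovery_on_random_additive_matrices(self, n):
        # oracle: enumerate all topologies; the true one is the unique
        # zero-residual least-squares fit, and NJ must return it exactly
        rng = np.random.default_rng(n)
        for _ in range(5):
            edges, lengths, D = random_additive_tree(n, rng)
            zero_fits = [
                topo
                for topo in enumerate_topologies(list(range(n)))
                if least_squares_fit(D, topo, n)[1] < 1e-9
            ]
            assert len(zero_fits) == 1
            assert topology_splits(sorted(zero_fits[0]), n) == topology_splits(
                edges, n
            )
            tree = pf.nj_build(D, [str(i) for i in range(n)])
            assert tree_splits(tree) == topology_splits(edges, n)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i, j in itertools.combinations(range(n), 2):
                assert pdm.patristic_distance(
                    taxa[str(i)], taxa[str(j)]
                ) == pytest.approx(D[i, j], abs=1e-9)

    def test_incomplete_matrix_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            pf.nj_build(D, list("ABC"))


class TestInternalBranches:
    def _tree(self):
        return dendropy.Tree.get(
            data="((A:1,B:1):2,((C:1,D:1):3,E:1):1):0;", schema="newick"
        )

    def test_two_tip_clade_stem_length(self):
        out = pf.internal_branches(self._tree(), {"cd": ["C", "D"], "ab": ["A", "B"]})
        assert out.set_index("clade").loc["cd", "stem_length"] == 3.0
        assert out.set_index("clade").loc["ab", "stem_length"] == 2.0
        assert out.iloc[0]["clade"] == "cd"  # sorted descending

    def test_non_monophyletic_clade_is_missing(self):
        out = pf.internal_branches(self._tree(), {"ac": ["A", "C"]})
        assert np.isnan(out.iloc[0]["stem_length"])


class TestBootstrap:
    def _haploid_with_signal(self, rng, n_sites=300):
        # two clean clades: (s0, s1) vs (s2, s3)
        hap = np.zeros((4, n_sites), dtype=np.int8)
        clade_sites = rng.random(n_sites) < 0.5
        hap[0, clade_sites] = 1
        hap[1, clade_sites] = 1
        noise = rng.random((4, n_sites)) < 0.02
        return np.where(noise, 1 - hap, hap).astype(np.int8)

    def test_clean_signal_gets_high_support(self, rng):
        hap = self._haploid_with_signal(rng)
        tree, supports = pf.bootstrap_support(hap, [f"s{i}" for i in range(4)], 100, rng)
        assert supports and min(supports.values()) >= 0.95

    def test_single_replicate_support_is_binary(self, rng):
        hap = self._haploid_with_signal(rng)
        _, supports = pf.bootstrap_support(hap, [f"s{i}" for i in range(4)], 1, rng)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_signal_free_data_has_low_support(self):
        # resampling the observed noise still leans toward the observed
        # resolution, so null support sits above 1/3 but clearly below the
        # clean-signal regime
        rng = np.random.default_rng(7)
        hap = rng.integers(0, 2, size=(4, 400)).astype(np.int8)
        _, supports = pf.bootstrap_support(hap, [f"s{i}" for i in range(4)], 200, rng)
        assert all(s < 0.9 for s in supports.values())
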