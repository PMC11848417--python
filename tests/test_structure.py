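import io

import numpy as np
import pytest
from skbio import TreeNode

from conftest import make_matrix
from fawtrack.structure import (
    DistanceMatrix,
    bootstrap_support,
    dosage_pca,
    ibs_distance,
    neighbor_joining,
)


class TestDosagePca:
    def test_two_fixed_populations_separate_on_pc1(self, two_pop_fixed_matrix):
        r = dosage_pca(two_pop_fixed_matrix, maf_min=0.05)
        pc1 = r.coordinates[:, 0]
        assert r.explained_fraction[0] > 0.99
        assert len(set(np.round(pc1[:4], 6))) == 1
        assert len(set(np.round(pc1[4:], 6))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[4])

    def test_duplicate_individuals_coincide(self):
        rng = np.random.default_rng(31)
        dos = rng.integers(0, 3, size=(6, 40)).astype(float)
        dos[5] = dos[0]
        r = dosage_pca(make_matrix(dos), maf_min=0.0)
        informative = r.explained_fraction > 1e-9
        assert np.allclose(
            r.coordinates[0, informative], r.coordinates[5, informative]
        )

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(32)
        dos = rng.integers(0, 3, size=(8, 50)).astype(float)
        r = dosage_pca(make_matrix(dos), maf_min=0.0, n_components=8)
        assert r.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert (r.explained_fraction >= 0).all()

    def test_matches_explicit_eigendecomposition(self):
        rng = np.random.default_rng(33)
        dos = rng.integers(0, 3, size=(6, 30)).astype(float)
        r = dosage_pca(make_matrix(dos), maf_min=0.0)
        # independent route: form the normalized matrix explicitly
        p = dos.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        Z = (dos[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        lam = np.sort(np.linalg.eigvalsh(Z @ Z.T / Z.shape[1]))[::-1]
        assert np.allclose(r.explained_fraction, (lam / lam.sum())[: r.explained_fraction.size])

    def test_sample_reorder_invariance_up_to_sign(self):
        rng = np.random.default_rng(34)
        dos = rng.integers(0, 3, size=(7, 40)).astype(float)
        r1 = dosage_pca(make_matrix(dos), maf_min=0.0)
        perm = rng.permutation(7)
        r2 = dosage_pca(make_matrix(dos[perm]), maf_min=0.0)
        for k in range(3):
            a, b = r1.coordinates[perm, k], r2.coordinates[:, k]
            assert np.allclose(a, b) or np.allclose(a, -b)

    def test_monomorphic_input_names_maf_filter(self):
        with pytest.raises(ValueError, match="MAF"):
            dosage_pca(make_matrix(np.zeros((4, 5))))


class TestIbsDistance:
    def test_closed_form_examples(self):
        dm = ibs_distance(make_matrix([[0.0, 0.0], [0.0, 0.0], [2.0, 2.0], [1.0, 0.0]]))
        assert dm.values[0, 1] == 0.0          # identical
        assert dm.values[0, 2] == 1.0          # opposite homozygotes
        assert dm.values[0, 3] == 0.25         # (0.5 + 0)/2
        assert np.allclose(dm.values, dm.values.T)

    def test_no_shared_loci_is_error(self):
        with pytest.raises(ValueError, match="no called loci"):
            ibs_distance(make_matrix([[np.nan, 0.0], [1.0, np.nan]]))


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns
    (distance matrix over leaves, set of non-trivial bipartitions)."""
    import networkx as nx

    g = nx.Graph()
    nodes = [f"t{i}" for i in range(n_taxa)]
    leaves = list(nodes)
    nxt = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        new = f"i{nxt}"
        nxt += 1
        g.add_edge(new, a, weight=float(rng.uniform(0.5, 2.0)))
        g.add_edge(new, b, weight=float(rng.uniform(0.5, 2.0)))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    D = np.array([[dist[a][b] for b in leaves] for a in leaves])
    # bipartitions: removing each internal edge splits the leaves
    bips = set()
    for a, b in g.edges:
        h = g.copy()
        h.remove_edge(a, b)
        side = frozenset(x for x in nx.node_connected_component(h, a) if x in leaves)
        if 2 <= len(side) <= n_taxa - 2:
            bips.add(min(side, frozenset(leaves) - side, key=sorted))
    return leaves, D, bips


def newick_bipartitions(nwk, leaves):
    tree = TreeNode.read(io.StringIO(nwk))
    all_set = frozenset(leaves)
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(leaves) - 2:
            bips.add(min(side, all_set - side, key=sorted))
    return bips, tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        nwk = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        tree = TreeNode.read(io.StringIO(nwk))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)): additive distances
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        nwk = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        bips, tree = newick_bipartitions(nwk, list("ABCD"))
        assert bips == {frozenset({"A", "B"})}
        tt = tree.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert tt[a, b] == pytest.approx(D[i, j])

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_trees_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        leaves, D, true_bips = random_additive_tree(rng, n)
        nwk = neighbor_joining(DistanceMatrix(leaves, D))
        bips, tree = newick_bipartitions(nwk, leaves)
        assert bips == true_bips
        tt = tree.tip_tip_distances()
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                assert tt[a, b] == pytest.approx(D[i, j], abs=1e-9)

    def test_tie_breaks_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        nwk1 = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        nwk2 = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        assert nwk1 == nwk2

    def test_outgroup_rooting(self):
        D = np.array(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], float
        )
        nwk = neighbor_joining(DistanceMatrix(["A", "B", "O1", "O2"], D),
                               outgroup=["O1", "O2"])
        tree = TreeNode.read(io.StringIO(nwk))
        kids = [frozenset(t.name for t in c.tips()) for c in tree.children]
        assert frozenset({"O1", "O2"}) in kids

    def test_missing_outgroup_raises(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(KeyError):
            neighbor_joining(DistanceMatrix(list("ABC"), D), outgroup=["Z"])


class TestBootstrap:
    def test_fixed_clades_get_full_support(self):
        dos = np.vstack([np.zeros((5, 200)), np.full((5, 200), 2.0)])
        m = make_matrix(dos)
        nwk = bootstrap_support(m, n_reps=25, seed=1)
        tree = TreeNode.read(io.StringIO(nwk))
        supports = [
            float(n.name) for n in tree.non_tips() if n.name is not None
        ]
        sides = {
            frozenset(t.name for t in n.tips()): n.name
            for n in tree.non_tips()
        }
        clade = frozenset(f"s{i}" for i in range(5))
        comp = frozenset(f"s{i}" for i in range(5, 10))
        labelled = {k: v for k, v in sides.items() if k in (clade, comp) and v}
        assert labelled and all(float(v) == 1.0 for v in labelled.values())
        assert all(0.0 <= s <= 1.0 for s in supports)

    def test_zero_replicates_rejected(self):
        m = make_matrix(np.zeros((4, 10)))
        with pytest.raises(ValueError):
            bootstrap_support(m, n_reps=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(35)
        dos = rng.integers(0, 3, size=(6, 50)).astype(float)
        m = make_matrix(dos)
        assert bootstrap_support(m, n_reps=10, seed=5) == bootstrap_support(
            m, n_reps=10, seed=5
        )
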