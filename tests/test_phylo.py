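"""p-distance, neighbor joining, bootstrap supports, Newick and PCA."""


import dendropy
import numpy as np
import pytest

from popsweep import phylo
from popsweep.matrix import MISSING
from popsweep.sim import SimConfig, simulate_dataset

from conftest import make_matrix


# ---------------------------------------------------------------------------
# random additive trees: an oracle built during construction


def random_additive_matrix_full(n, rng):
    """Additive matrix with all pairwise entries, by leaf-path bookkeeping."""
    # each active node: dict leaf -> distance to that leaf
    nodes = [{i: 0.0} for i in range(n)]
    D = np.zeros((n, n))

    def connect(a, b, extra):
        for x, dx in a.items():
            for y, dy in b.items():
                D[x, y] = D[y, x] = dx + dy + extra

    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.uniform(0.1, 2.0, size=2)
        b = nodes.pop(j)
        a = nodes.pop(i)
        connect({k: v + li for k, v in a.items()}, {k: v + lj for k, v in b.items()}, 0.0)
        merged = {**{k: v + li for k, v in a.items()}, **{k: v + lj for k, v in b.items()}}
        nodes.append(merged)
    lengths = rng.uniform(0.1, 2.0, size=len(nodes))
    for p in range(len(nodes)):
        for q in range(p + 1, len(nodes)):
            connect(
                {k: v + lengths[p] for k, v in nodes[p].items()},
                {k: v + lengths[q] for k, v in nodes[q].items()},
                0.0,
            )
    return D


class TestPDistance:
    def test_identical_samples_zero(self):
        m = make_matrix(np.array([[0, 1, 2], [0, 1, 2]]))
        dm = phylo.p_distance(m)
        assert dm.values[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        m = make_matrix(np.array([[0] * 5, [2] * 5]))
        assert phylo.p_distance(m).values[0, 1] == 1.0

    def test_missing_site_excluded_from_denominator(self):
        m = make_matrix(np.array([[0, 2, 1, MISSING], [1, 0, 1, 2]]))
        dm = phylo.p_distance(m)
        # comparable sites: 3; numerator |0-1|+|2-0|+|1-1| = 3
        assert dm.values[0, 1] == pytest.approx(3 / 6)
        assert dm.n_sites[0, 1] == 3

    def test_no_shared_sites_is_an_error(self):
        m = make_matrix(np.array([[0, MISSING], [MISSING, 1]]))
        with pytest.raises(ValueError, match="share no called site"):
            phylo.p_distance(m)


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): path lengths computed by hand
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        path = phylo.tree_distance_matrix(tree, ids)
        assert np.allclose(path, D, atol=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        lengths = {c.name: length for c, length in tree.children}
        assert lengths["A"] == pytest.approx(0.5 * (2 + 3 - 4))
        assert lengths["B"] == pytest.approx(0.5 * (2 + 4 - 3))
        assert lengths["C"] == pytest.approx(0.5 * (3 + 4 - 2))

    def test_equidistant_taxa_deterministic(self):
        ids = list("ABCD")
        D = np.ones((4, 4)) - np.eye(4)
        t1 = phylo.to_newick(phylo.neighbor_joining(phylo.DistanceMatrix(ids, D)))
        t2 = phylo.to_newick(phylo.neighbor_joining(phylo.DistanceMatrix(ids, D)))
        assert t1 == t2

    def test_random_additive_recovery(self):
        """NJ reconstructs 50 random additive trees exactly (n ≤ 12)."""
        rng = np.random.default_rng(12345)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            D = random_additive_matrix_full(n, rng)
            ids = [f"t{i}" for i in range(n)]
            tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
            path = phylo.tree_distance_matrix(tree, ids)
            assert np.max(np.abs(path - D)) < 1e-9

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(list("ABC"), D)


class TestBootstrap:
    def test_population_split_strongly_supported(self):
        cfg = SimConfig(
            contigs=[("c1", 150_000)],
            pop_names=["a", "b"],
            samples_per_pop=[6, 6],
            f_per_pop=[0.3, 0.3],
            snp_density=1 / 300,
            missing_rate=0.0,
            seed=17,
        )
        matrix, _ = simulate_dataset(cfg)
        assert matrix.n_variants >= 400
        tree = phylo.bootstrap_supports(matrix, n_replicates=100, seed=1)
        pop_a = frozenset(s for s in matrix.samples if s.startswith("a"))
        all_leaves = frozenset(matrix.samples)
        key = min(pop_a, all_leaves - pop_a, key=lambda s: tuple(sorted(s)))

        supports = {}

        def walk(node):
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node.support is not None:
                k = min(below, all_leaves - below, key=lambda s: tuple(sorted(s)))
                supports[k] = node.support
            return below

        for child, _ in tree.children:
            walk(child)
        assert key in supports
        assert supports[key] >= 95.0

    def test_single_replicate_supports_binary(self, two_pop_dataset):
        matrix, _ = two_pop_dataset
        sub = matrix.take_samples(matrix.samples[:8])
        tree = phylo.bootstrap_supports(sub, n_replicates=1, seed=0)
        vals = []

        def walk(node):
            for c, _ in node.children:
                if c.support is not None:
                    vals.append(c.support)
                walk(c)

        walk(tree)
        assert vals and set(vals) <= {0.0, 100.0}

    def test_seed_determinism(self, two_pop_dataset):
        matrix, _ = two_pop_dataset
        sub = matrix.take_samples(matrix.samples[:10])
        t1 = phylo.to_newick(phylo.bootstrap_supports(sub, 25, seed=3))
        t2 = phylo.to_newick(phylo.bootstrap_supports(sub, 25, seed=3))
        assert t1 == t2


class TestNewick:
    def test_round_trip_through_dendropy(self, two_pop_dataset):
        matrix, _ = two_pop_dataset
        sub = matrix.take_samples(matrix.samples[:8])
        tree = phylo.bootstrap_supports(sub, 20, seed=2)
        nwk = phylo.to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(
            sub.samples
        )
        # branch lengths preserved: compare total tree length
        total = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length is not None
        )

        def my_total(node):
            return sum(
                length + my_total(child) for child, length in node.children
            )

        assert total == pytest.approx(my_total(tree), rel=1e-6)


class TestPCA:
    def test_populations_separate_on_pc1(self):
        cfg = SimConfig(
            contigs=[("c1", 150_000)],
            pop_names=["a", "b"],
            samples_per_pop=[20, 20],
            f_per_pop=[0.2, 0.2],
            snp_density=1 / 300,
            missing_rate=0.0,
            seed=23,
        )
        matrix, _ = simulate_dataset(cfg)
        res = phylo.pca(matrix, 2)
        pc1 = res.coordinates[:, 0]
        a = pc1[:20]
        b = pc1[20:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(6, 40))
        dos[5] = dos[0]
        m = make_matrix(dos)
        res = phylo.pca(m, 3)
        assert np.allclose(res.coordinates[0], res.coordinates[5], atol=1e-9)

    def test_eigenvalues_match_dense_oracle(self):
        """Eigenvalues agree with a direct covariance eigensolve."""
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(10, 50))
        m = make_matrix(dos)
        res = phylo.pca(m, 10)
        # independent route: explicit scaled matrix + numpy eigvalsh
        g = dos.astype(float)
        mean = g.mean(axis=0)
        p = mean / 2
        keep = (p > 0) & (p < 1)
        x = (g[:, keep] - mean[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        x /= np.sqrt(keep.sum())
        ev = np.sort(np.linalg.eigvalsh(x @ x.T))[::-1]
        assert np.allclose(res.eigenvalues, ev[: len(res.eigenvalues)], atol=1e-9)

    def test_variance_conservation(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(8, 30))
        m = make_matrix(dos)
        res = phylo.pca(m, 8)
        # total eigenvalue mass equals the trace of the scaled covariance
        g = dos.astype(float)
        mean = g.mean(axis=0)
        p = mean / 2
        keep = (p > 0) & (p < 1)
        x = (g[:, keep] - mean[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        x /= np.sqrt(keep.sum())
        assert res.eigenvalues.sum() == pytest.approx(np.trace(x @ x.T), rel=1e-9)

    def test_monomorphic_input_rejected(self):
        m = make_matrix(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError, match="monomorphic"):
            phylo.pca(m)
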