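"""JTT+gamma ML distances, neighbor joining, bootstrap and clade calls."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

import copiascan as cs
from copiascan import phylo as ph
from copiascan.synth import clade_domain_protein, mutate_protein


# ---------------------------------------------------------------------------
# independent ML-distance oracle: rate matrix built from the published JTT
# data, matrix exponential via scipy.expm, gamma averaging by quadrature,
# optimum located by grid search
# ---------------------------------------------------------------------------

def _oracle_rate_matrix():
    s = np.zeros((20, 20))
    for (i, j), x in zip(itertools.combinations(range(20), 2),
                         ph._JTT_EXCHANGE):
        s[i, j] = s[j, i] = x
    pi = ph._JTT_FREQS
    r = s * pi[None, :]
    np.fill_diagonal(r, -r.sum(axis=1) + np.diag(r))
    r /= -(pi * np.diag(r)).sum()
    return r


def _oracle_distance(counts, gamma_shape, grid):
    r = _oracle_rate_matrix()
    if gamma_shape is None:
        probs = {t: expm(r * t) for t in grid}
    else:
        # 64-point quadrature over the gamma rate distribution
        qs = (np.arange(64) + 0.5) / 64
        rates = gamma_dist.ppf(qs, a=gamma_shape, scale=1.0 / gamma_shape)
        probs = {t: np.mean([expm(r * t * rate) for rate in rates], axis=0)
                 for t in grid}
    best_t, best_ll = None, -np.inf
    for t, p in probs.items():
        ll = (counts * np.log(np.clip(p, 1e-300, None))).sum()
        if ll > best_ll:
            best_t, best_ll = t, ll
    return best_t


class TestProteinDistance:
    def test_identical_sequences_distance_zero(self):
        msa = {"a": "ACDEFGHIKL" * 10, "b": "ACDEFGHIKL" * 10,
               "c": "ACDEFGHIKL" * 10}
        d = cs.protein_distance(msa)
        assert np.all(d.matrix == 0)

    @pytest.mark.parametrize("gamma_shape", [None, 1.0])
    def test_matches_grid_search_oracle(self, gamma_shape):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list(ph.AA_ORDER), 400))
        b = list(a)
        for p in rng.choice(400, 40, replace=False):
            b[p] = rng.choice([x for x in ph.AA_ORDER if x != b[p]])
        msa = {"a": a, "b": "".join(b), "c": a}
        d = cs.protein_distance(msa, gamma_shape=gamma_shape)
        la, arr = ph.encode_alignment({"a": a, "b": "".join(b)})
        counts = ph._pair_counts(arr[0], arr[1])
        grid = np.arange(0.005, 0.6, 0.002)
        oracle = _oracle_distance(counts, gamma_shape, grid)
        assert d.matrix[0, 1] == pytest.approx(oracle, abs=0.004)

    def test_gap_columns_excluded(self):
        msa = {"a": "ACDEFGHIKL" * 8, "b": "ACDEFGHIKL" * 8,
               "c": "ACDEFGHIKL" * 8}
        base = cs.protein_distance({k: v for k, v in msa.items()})
        padded = {k: v + "-----" for k, v in msa.items()}
        again = cs.protein_distance(padded)
        assert np.allclose(base.matrix, again.matrix)

    def test_disjoint_pair_raises_with_names(self):
        msa = {"left": "ACDE----", "right": "----FGHI", "mid": "ACDEFGHI"}
        with pytest.raises(ValueError, match="left.*right|right.*left"):
            cs.protein_distance(msa)

    def test_saturated_pair_capped(self):
        rng = np.random.default_rng(9)
        seqs = {k: "".join(rng.choice(list(ph.AA_ORDER), 150))
                for k in "abc"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = cs.protein_distance(seqs, max_distance=5.0)
        assert d.matrix.max() <= 5.0


class TestNjTree:
    def test_additive_four_taxon_exact(self):
        # ((A:2,B:3):1,(C:4,D:5)) pairwise path lengths
        m = np.array([[0, 5, 7, 8], [5, 0, 8, 9],
                      [7, 8, 0, 9], [8, 9, 9, 0]], float)
        tree = cs.nj_tree(cs.DistanceMatrix(list("ABCD"), m))
        assert ph.bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == {"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0}

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_additive_trees(self, seed):
        """NJ is consistent: any additive matrix returns the generating
        topology (random binary trees, <= 12 taxa)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        # random binary tree: iteratively join
        nodes = [ph.Node(name=f"t{i}") for i in range(n)]
        for node in nodes:
            node.length = float(rng.uniform(0.5, 3.0))
        pool = nodes[:]
        while len(pool) > 3:
            i, j = sorted(rng.choice(len(pool), 2, replace=False))
            parent = ph.Node(length=float(rng.uniform(0.5, 3.0)))
            parent.children = [pool[i], pool[j]]
            pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
        root = ph.Node()
        root.children = pool
        # path-length distances from the generating tree
        def leaf_dists(node, acc, out):
            if node.is_leaf:
                out[node.name] = acc
            for c in node.children:
                leaf_dists(c, acc + c.length, out)
        paths = {}
        for c in root.children:
            sub = {}
            leaf_dists(c, c.length, sub)
            paths[id(c)] = sub
        names = sorted(l.name for l in root.leaves())
        m = np.zeros((n, n))
        flat = {}
        def depth_map(node, acc, out):
            if node.is_leaf:
                out[node.name] = acc
            for c in node.children:
                depth_map(c, acc + c.length, out)
        depth = {}
        depth_map(root, 0.0, depth)
        # distance: depth_a + depth_b - 2*depth(lca); compute via splits
        def pairwise(a, b, node, acc):
            # walk tree: lca depth
            best = 0.0
            def walk(nd, d):
                nonlocal best
                leaves = nd.leaf_names()
                if a in leaves and b in leaves:
                    best = max(best, d)
                    for c in nd.children:
                        walk(c, d + c.length)
            walk(node, 0.0)
            return depth[a] + depth[b] - 2 * best
        for i, a in enumerate(names):
            for j in range(i + 1, n):
                b = names[j]
                m[i, j] = m[j, i] = pairwise(a, b, root, 0.0)
        tree = cs.nj_tree(cs.DistanceMatrix(names, m))
        assert ph.bipartitions(tree) == ph.bipartitions(root)

    def test_three_taxa_unique_topology(self):
        m = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = cs.nj_tree(cs.DistanceMatrix(list("ABC"), m))
        assert len(tree.children) == 3
        assert ph.bipartitions(tree) == set()

    def test_star_phylogeny_zero_internal_branches(self):
        m = np.full((5, 5), 2.0)
        np.fill_diagonal(m, 0.0)
        tree = cs.nj_tree(cs.DistanceMatrix(list("ABCDE"), m))
        for node in tree.postorder():
            if not node.is_leaf and node is not tree:
                assert node.length == pytest.approx(0.0, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(ValueError):
            cs.DistanceMatrix(list("ABC"), m)


@pytest.fixture(scope="module")
def clade_msa():
    """Three well-separated clades of 3 sequences (2 species each) plus a
    Gypsy outgroup; already aligned (equal length, no indels)."""
    msa, species = {}, {}
    for clade in ("GalEa", "FunCo1", "OtherCopia"):
        base, protected = clade_domain_protein(clade)
        for i in range(3):
            leaf = f"{clade}{i}"
            msa[leaf] = mutate_protein(base, 0.05, 7000 + i * 13, protected)
            species[leaf] = f"sp{i % 2}"
    msa["OUT"] = clade_domain_protein("Gypsy")[0]
    species["OUT"] = "outgroup"
    return msa, species


class TestBootstrap:
    def test_separated_clades_strongly_supported(self, clade_msa):
        msa, species = clade_msa
        tree, supports = cs.bootstrap_support(msa, 100, seed=5)
        ref = min(msa)
        for clade in ("GalEa", "FunCo1", "OtherCopia"):
            split = frozenset(f"{clade}{i}" for i in range(3))
            key = split if ref not in split else frozenset(msa) - split
            assert supports.get(key, 0.0) >= 95.0

    def test_supports_bounded(self, clade_msa):
        msa, _ = clade_msa
        _, supports = cs.bootstrap_support(msa, 50, seed=1)
        assert all(0.0 <= v <= 100.0 for v in supports.values())

    def test_deterministic_under_seed(self, clade_msa):
        msa, _ = clade_msa
        t1, s1 = cs.bootstrap_support(msa, 30, seed=3)
        t2, s2 = cs.bootstrap_support(msa, 30, seed=3)
        assert s1 == s2 and t1.newick() == t2.newick()

    def test_leaf_order_invariance(self, clade_msa):
        msa, _ = clade_msa
        _, s1 = cs.bootstrap_support(msa, 30, seed=3)
        _, s2 = cs.bootstrap_support(dict(reversed(list(msa.items()))),
                                     30, seed=3)
        assert s1 == s2

    def test_zero_replicates_rejected(self, clade_msa):
        msa, _ = clade_msa
        with pytest.raises(ValueError):
            cs.bootstrap_support(msa, 0, seed=1)


class TestCallClades:
    def test_three_clades_called(self, clade_msa):
        msa, species = clade_msa
        tree, supports = cs.bootstrap_support(msa, 100, seed=5)
        clades = cs.call_clades(tree, supports, species, "OUT")
        groups = {tuple(c.members) for c in clades}
        assert groups == {tuple(f"{cl}{i}" for i in range(3))
                          for cl in ("GalEa", "FunCo1", "OtherCopia")}
        assert all(c.support > 70 for c in clades)

    def test_support_exactly_70_not_called(self, clade_msa):
        msa, species = clade_msa
        tree, supports = cs.bootstrap_support(msa, 100, seed=5)
        lowered = {k: min(v, 70.0) for k, v in supports.items()}
        assert cs.call_clades(tree, lowered, species, "OUT") == []

    def test_single_species_subtree_not_called(self, clade_msa):
        msa, species = clade_msa
        tree, supports = cs.bootstrap_support(msa, 100, seed=5)
        mono = {leaf: ("one_species" if leaf != "OUT" else "outgroup")
                for leaf in msa}
        assert cs.call_clades(tree, supports, mono, "OUT") == []

    def test_no_called_clade_nested_in_another(self, clade_msa):
        msa, species = clade_msa
        tree, supports = cs.bootstrap_support(msa, 100, seed=5)
        clades = cs.call_clades(tree, supports, species, "OUT")
        for a, b in itertools.permutations(clades, 2):
            assert not set(a.members) < set(b.members)

    def test_missing_outgroup_rejected(self, clade_msa):
        msa, species = clade_msa
        tree, supports = cs.bootstrap_support(msa, 20, seed=5)
        with pytest.raises(ValueError):
            cs.call_clades(tree, supports, species, "NOPE")
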