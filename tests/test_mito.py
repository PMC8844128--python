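"""K2P distances, neighbor joining, bootstrap, and mitotype assignment."""

import numpy as np
import pytest

from beeadmix import simulate
from beeadmix.mito import (
    K2PSaturationError,
    MitoAlignment,
    assign_clades,
    bootstrap_support,
    clade_bipartition_supports,
    k2p_distance,
    k2p_distance_matrix,
    k2p_from_proportions,
    midpoint_root,
    mitotype_table,
    nj_tree,
    tree_distance_matrix,
    _bipartitions,
)


def random_tree_distance_matrix(n_leaves, rng):
    """Random binary tree; exact additive leaf-to-leaf distance matrix."""
    clusters = [[i] for i in range(n_leaves)]
    d = np.zeros((n_leaves, n_leaves))
    height = {i: 0.0 for i in range(n_leaves)}
    while len(clusters) > 1:
        a, b = sorted(rng.choice(len(clusters), size=2, replace=False))
        ba, bb = rng.uniform(0.1, 1.0, size=2)
        for i in clusters[a]:
            for j in clusters[b]:
                d[i, j] = d[j, i] = height[i] + ba + height[j] + bb
        for i in clusters[a]:
            height[i] += ba
        for j in clusters[b]:
            height[j] += bb
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
            clusters[a] + clusters[b]
        ]
    return d


class TestK2P:
    def test_closed_form_spot_check(self):
        # P = 0.1, Q = 0.05
        assert k2p_from_proportions(0.1, 0.05) == pytest.approx(0.17018, abs=1e-5)

    def test_sequence_counts_reproduce_closed_form(self):
        # 1000 columns: 100 transitions (A->G), 50 transversions (A->C)
        s1 = "A" * 1000
        s2 = "G" * 100 + "C" * 50 + "A" * 850
        assert k2p_distance(s1, s2) == pytest.approx(
            k2p_from_proportions(0.1, 0.05), abs=1e-12
        )

    def test_identical_sequences_have_zero_distance(self):
        assert k2p_distance("ACGTACGT" * 50, "ACGTACGT" * 50) == 0.0

    def test_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        arr1 = rng.choice(bases, 400)
        arr2 = arr1.copy()
        hit = rng.random(400) < 0.1
        arr2[hit] = rng.choice(bases, int(hit.sum()))
        s1, s2 = "".join(arr1), "".join(arr2)
        assert k2p_distance(s1, s2) == pytest.approx(k2p_distance(s2, s1))

    def test_complete_deletion_is_alignment_wide(self):
        # the gap in seq3 removes that column for the (1, 2) pair too
        aln = MitoAlignment(
            names=["a", "b", "c"],
            sequences=["AAAA" + "A" * 96, "GAAA" + "A" * 96, "-AAA" + "A" * 96],
        )
        d, cols = k2p_distance_matrix(aln)
        assert cols.size == 99
        assert d[0, 1] == 0.0  # the only mismatch column was deleted

    def test_saturation_raises(self):
        with pytest.raises(K2PSaturationError):
            k2p_from_proportions(0.5, 0.25)
        s1 = "A" * 200
        s2 = "G" * 200
        with pytest.raises(K2PSaturationError):
            k2p_distance(s1, s2)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(d, ["a", "b", "c"])
        out = tree_distance_matrix(tree, ["a", "b", "c"])
        assert np.allclose(out, d, atol=1e-12)

    def test_four_taxon_additive_matrix_roundtrip(self):
        # tree ((A:1, B:2):1, (C:3, D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        tree = nj_tree(d, labels)
        assert np.allclose(tree_distance_matrix(tree, labels), d, atol=1e-12)
        # AB|CD is the single internal bipartition
        biparts = _bipartitions(tree, frozenset(labels))
        assert frozenset(["A", "B"]) in biparts or frozenset(["C", "D"]) in biparts

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_on_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        d = random_tree_distance_matrix(n, rng)
        labels = [f"t{i}" for i in range(n)]
        tree = nj_tree(d, labels)
        assert np.allclose(tree_distance_matrix(tree, labels), d, atol=1e-9)

    def test_taxon_order_does_not_change_topology(self, rng):
        n = 8
        d = random_tree_distance_matrix(n, rng)
        labels = [f"t{i}" for i in range(n)]
        perm = rng.permutation(n)
        t1 = nj_tree(d, labels)
        t2 = nj_tree(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        b1 = set(_bipartitions(t1, frozenset(labels)))
        b2 = set(_bipartitions(t2, frozenset(labels)))
        assert b1 == b2

    def test_agrees_with_skbio_on_noisy_matrix(self, rng):
        # independent implementation cross-check on a non-additive matrix
        import skbio
        import dendropy
        from io import StringIO
        from Bio import Phylo

        n = 8
        d = random_tree_distance_matrix(n, rng)
        noise = rng.uniform(0, 0.02, size=(n, n))
        d = d + noise + noise.T
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ours = nj_tree(d, labels)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        buf = StringIO()
        Phylo.write(ours, buf, "newick")
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(d, ["a", "b"])


class TestMidpointRoot:
    def test_two_leaves_rooted_halfway(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        tree = midpoint_root(nj_tree(d, ["a", "b"]))
        depths = tree.depths()
        leaf_depths = {t.name: depth for t, depth in depths.items() if t.name}
        assert leaf_depths["a"] == pytest.approx(1.0)
        assert leaf_depths["b"] == pytest.approx(1.0)

    def test_root_bisects_the_diameter(self, rng):
        d = random_tree_distance_matrix(7, rng)
        labels = [f"t{i}" for i in range(7)]
        tree = midpoint_root(nj_tree(d, labels))
        depths = {t.name: dep for t, dep in tree.depths().items() if t.name}
        diameter = d.max()
        deepest = max(depths.values())
        assert deepest == pytest.approx(diameter / 2, abs=1e-9)

    def test_rooting_preserves_leaf_distances(self, rng):
        d = random_tree_distance_matrix(6, rng)
        labels = [f"t{i}" for i in range(6)]
        unrooted = nj_tree(d, labels)
        rooted = midpoint_root(unrooted)
        assert np.allclose(tree_distance_matrix(rooted, labels), d, atol=1e-9)


@pytest.fixture(scope="module")
def aln():
    return simulate.simulate_mito_alignment(
        {"A": 2, "M": 1, "O": 1}, refs_per_clade=2, seq_length=3000, seed=40
    )


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, aln):
        tree, info = bootstrap_support(aln, n_reps=1, seed=0)
        sup = [c.confidence for c in tree.get_nonterminals() if c.confidence is not None]
        assert set(sup) <= {0.0, 100.0}

    def test_same_seed_identical_supports(self, aln):
        t1, _ = bootstrap_support(aln, n_reps=25, seed=5)
        t2, _ = bootstrap_support(aln, n_reps=25, seed=5)
        s1 = [c.confidence for c in t1.get_nonterminals() if c.confidence is not None]
        s2 = [c.confidence for c in t2.get_nonterminals() if c.confidence is not None]
        assert s1 == s2

    def test_deep_clades_get_full_support(self):
        aln = simulate.simulate_mito_alignment(
            {"A": 3, "M": 2, "C": 1, "O": 2}, refs_per_clade=2,
            seq_length=15000, seed=41,
        )
        tree, info = bootstrap_support(aln, n_reps=100, seed=41)
        supports = clade_bipartition_supports(tree, aln)
        assert info["n_dropped"] == 0
        for clade, support in supports.items():
            assert support is not None and support >= 95.0


class TestAssignment:
    def test_query_identical_to_reference(self):
        aln = simulate.simulate_mito_alignment(
            {"A": 1}, refs_per_clade=2, divergence_within=0.0, seq_length=2000, seed=42
        )
        d, _ = k2p_distance_matrix(aln)
        tree = midpoint_root(nj_tree(d, aln.names))
        out = assign_clades(tree, aln).set_index("query")
        assert out.loc["query0", "clade"] == "A"
        assert out.loc["query0", "dist_A"] == pytest.approx(0.0)

    def test_san_diego_composition_recovered_exactly(self):
        counts = simulate.MITOTYPE_PRESETS["san_diego"]
        aln = simulate.simulate_mito_alignment(counts, seed=43)
        d, _ = k2p_distance_matrix(aln)
        tree = midpoint_root(nj_tree(d, aln.names))
        out = assign_clades(tree, aln)
        assigned = out.set_index("query")["clade"].to_dict()
        assert assigned == aln.true_query_clades
        table = mitotype_table(out, {q: "san_diego" for q in assigned})
        assert table["san_diego"].to_dict() == counts

    def test_tree_and_distance_methods_agree(self):
        aln = simulate.simulate_mito_alignment(
            {"A": 4, "M": 2, "C": 2, "O": 2}, seed=44
        )
        d, _ = k2p_distance_matrix(aln)
        tree = midpoint_root(nj_tree(d, aln.names))
        out = assign_clades(tree, aln)
        dist_cols = [c for c in out.columns if c.startswith("dist_")]
        nearest = out[dist_cols].idxmin(axis=1).str.replace("dist_", "", regex=False)
        assert (out["clade"] == nearest).all()

    def test_no_references_raises(self):
        aln = MitoAlignment(names=["q1", "q2"], sequences=["ACGT" * 50, "ACGT" * 50])
        d, _ = k2p_distance_matrix(aln)
        tree = nj_tree(d, aln.names)
        with pytest.raises(ValueError):
            assign_clades(tree, aln, reference_clades={})
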