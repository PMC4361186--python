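"""UPGMA/NJ construction, bootstrap supports, monophyly scoring."""

import numpy as np
import pytest

from barcodegap.alignments import MarkerAlignment, SequenceRecord
from barcodegap.distances import DistanceMatrix
from barcodegap.io import newick_string, tree_from_newick
from barcodegap.trees import (
    MaskedDistanceError,
    bootstrap_supports,
    clade_leaf_sets,
    is_monophyletic,
    nj_tree,
    nontrivial_splits,
    resolution_rates,
    upgma_tree,
)
from oracles import random_binary_unrooted, random_ultrametric, splits_of_adjacency


def _dm(labels, values):
    values = np.asarray(values, dtype=float)
    n = len(labels)
    return DistanceMatrix(
        list(labels), values, np.ones((n, n), bool), np.ones((n, n), np.int64)
    )


def _path_matrix(tree, labels):
    """Leaf-to-leaf path lengths via dendropy (independent of builders)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestUPGMA:
    def test_three_taxon_hand_agglomeration(self):
        tree = upgma_tree(_dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        assert newick_string(tree) == "((A:1,B:1):1,C:2);"

    def test_two_taxa(self):
        tree = upgma_tree(_dm("AB", [[0, 0.4], [0.4, 0]]))
        lengths = [leaf.edge.length for leaf in tree.leaf_node_iter()]
        assert lengths == pytest.approx([0.2, 0.2])

    def test_ultrametric_and_cophenetic_recovery(self):
        rng = np.random.default_rng(21)
        labels = [f"t{i}" for i in range(8)]
        mat = random_ultrametric(rng, 8)
        tree = upgma_tree(_dm(labels, mat))
        # ultrametricity: equal root-to-leaf depths
        depths = []
        clades = clade_leaf_sets(tree)
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9
        # exact cophenetic recovery
        assert np.allclose(_path_matrix(tree, labels), mat, atol=1e-9)

    def test_masked_matrix_refused(self):
        dm = _dm("ABC", [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        dm.defined[0, 1] = dm.defined[1, 0] = False
        with pytest.raises(MaskedDistanceError):
            upgma_tree(dm)

    def test_agrees_with_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(43)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            labels = [f"t{i}" for i in range(n)]
            base = rng.uniform(0.1, 1.0, (n, n))
            mat = (base + base.T) / 2
            np.fill_diagonal(mat, 0)
            tree = upgma_tree(_dm(labels, mat))
            ref = squareform(cophenet(average(squareform(mat))))
            assert np.allclose(_path_matrix(tree, labels), ref, atol=1e-9)

    def test_tie_break_deterministic(self):
        # all distances equal: lexicographically smallest pair joins first
        tree = upgma_tree(_dm(["b", "a", "c"], np.ones((3, 3)) - np.eye(3)))
        first_clade = min(
            (c for n, c in clade_leaf_sets(tree).items() if len(c) == 2),
            default=None,
        )
        assert first_clade == frozenset({"a", "b"})


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) pairwise path lengths
        vals = [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]]
        tree = nj_tree(_dm("ABCD", vals))
        assert not tree.is_rooted
        splits = nontrivial_splits(tree)
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits
        assert np.allclose(_path_matrix(tree, list("ABCD")), vals, atol=1e-9)

    def test_three_taxon_closed_form(self):
        vals = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = nj_tree(_dm("ABC", vals))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_two_taxa_degenerate_edge(self):
        tree = nj_tree(_dm("AB", [[0, 1.0], [1.0, 0]]))
        total = sum(leaf.edge.length for leaf in tree.leaf_node_iter())
        assert total == pytest.approx(1.0)

    def test_zero_matrix_zero_lengths(self):
        tree = nj_tree(_dm("ABCD", np.zeros((4, 4))))
        assert all(
            (e.length or 0.0) == 0.0 for e in tree.preorder_edge_iter()
        )

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(99)
        for rep in range(25):
            n = int(rng.integers(6, 13))
            labels = [f"t{i:02d}" for i in range(n)]
            adj, mat = random_binary_unrooted(rng, labels)
            tree = nj_tree(_dm(labels, mat))
            ref_splits = {
                frozenset(labels[i] for i in s)
                for s in splits_of_adjacency(adj, n)
            }
            got = set(nontrivial_splits(tree))
            assert got == ref_splits
            assert np.abs(_path_matrix(tree, labels) - mat).max() < 1e-9

    def test_agrees_with_skbio_on_generic_matrices(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(41)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            labels = [f"t{i}" for i in range(n)]
            base = rng.uniform(0.1, 1.0, (n, n))
            mat = (base + base.T) / 2
            np.fill_diagonal(mat, 0)
            mine = set(nontrivial_splits(nj_tree(_dm(labels, mat))))
            sk = skbio_nj(SkbioDM(mat, ids=labels))
            all_leaves = frozenset(labels)
            ref = set()
            for node in sk.traverse():
                if node.is_tip() or node.is_root():
                    continue
                side = frozenset(t.name for t in node.tips())
                if "t0" in side:
                    side = all_leaves - side
                if 2 <= len(side) <= n - 2:
                    ref.add(side)
            assert mine == ref

    def test_negative_estimates_clamped_and_flagged(self):
        vals = [[0, 0.1, 0.6, 0.6], [0.1, 0, 0.1, 0.1], [0.6, 0.1, 0, 0.1], [0.6, 0.1, 0.1, 0]]
        tree = nj_tree(_dm("ABCD", vals))
        assert all((e.length or 0) >= 0 for e in tree.preorder_edge_iter())
        assert tree.clamped_negative_branches >= 1


def _pattern_alignment():
    # two identical pairs: every column resample yields the same split,
    # so the bootstrap has zero effective topology variance
    a = "ACGTACGTAC" * 4
    b = "ACGTACGTAC" * 3 + "GTATACGCAT"
    rows = [("a1", "A", a), ("a2", "A", a), ("b1", "B", b), ("b2", "B", b)]
    return MarkerAlignment(
        marker="m", records=[SequenceRecord(x, s, "m", r) for x, s, r in rows]
    )


def _divergent_family(rng, n, length=120, mutations=6):
    """Closely related sequences: a shared backbone plus a few private
    substitutions each, keeping every pair far from K2P saturation."""
    base = rng.choice(list("ACGT"), size=length)
    rows = []
    for i in range(n):
        seq = base.copy()
        pos = rng.choice(length, size=mutations, replace=False)
        for p in pos:
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        rows.append((f"x{i}", "S", "".join(seq)))
    return MarkerAlignment(
        marker="m", records=[SequenceRecord(a, s, "m", r) for a, s, r in rows]
    )


class TestBootstrap:
    def test_identical_columns_force_support_100(self):
        aln = _pattern_alignment()
        tree = bootstrap_supports(aln, method="nj", n_reps=20, seed=0)
        sups = [
            int(n.label)
            for n in tree.preorder_node_iter()
            if n.label is not None
        ]
        assert sups and all(s == 100 for s in sups)

    def test_single_replicate_supports_binary(self):
        aln = _divergent_family(np.random.default_rng(2), 6)
        tree = bootstrap_supports(aln, method="upgma", n_reps=1, seed=3)
        sups = [
            int(n.label) for n in tree.preorder_node_iter() if n.label is not None
        ]
        assert set(sups) <= {0, 100}

    def test_seed_reproducibility_and_binomial_consistency(self):
        aln = _divergent_family(np.random.default_rng(4), 7)

        def sups(seed, reps=200):
            tree = bootstrap_supports(aln, method="nj", n_reps=reps, seed=seed)
            return {
                frozenset(k): int(v.label)
                for k, v in __import__(
                    "barcodegap.trees", fromlist=["nontrivial_splits"]
                ).nontrivial_splits(tree).items()
            }

        assert sups(11) == sups(11)
        a, b = sups(11), sups(12)
        for key in set(a) & set(b):
            p = a[key] / 100.0
            se = 100.0 * np.sqrt(max(p * (1 - p), 1e-4) / 200)
            assert abs(a[key] - b[key]) <= 5 * se + 1


class TestMonophyly:
    def test_rooted_positive_and_negative(self):
        tree = tree_from_newick("((A1,A2),(B1,B2));", rooted=True)
        assert is_monophyletic(tree, {"A1", "A2"})[0]
        tree2 = tree_from_newick("((A1,B1),(A2,B2));", rooted=True)
        assert not is_monophyletic(tree2, {"A1", "A2"})[0]

    def test_unrooted_complement_side_counts(self):
        tree = tree_from_newick("(A1,A2,(B1,B2));", rooted=False)
        assert is_monophyletic(tree, {"B1", "B2"})[0]
        assert is_monophyletic(tree, {"A1", "A2"})[0]

    def test_singleton_true_without_support(self):
        tree = tree_from_newick("((A1,A2),B1);", rooted=True)
        assert is_monophyletic(tree, {"B1"}) == (True, None)

    def test_support_returned(self):
        tree = tree_from_newick("((A1:1,A2:1)85:1,(B1:1,B2:1)60:1);", rooted=True)
        assert is_monophyletic(tree, {"A1", "A2"}) == (True, 85)

    def test_unknown_label_raises(self):
        tree = tree_from_newick("((A1,A2),B1);", rooted=True)
        with pytest.raises(KeyError):
            is_monophyletic(tree, {"Z9"})

    def test_invariant_under_rerooting_unrooted(self):
        rng = np.random.default_rng(17)
        base = "((A1:1,A2:1):1,((B1:1,B2:1):1,(C1:1,A3:1):1):1);"
        tree = tree_from_newick(base, rooted=False)
        target = {"B1", "B2"}
        reference = is_monophyletic(tree, target)[0]
        for leaf in list(tree.leaf_node_iter()):
            rerooted = tree_from_newick(base, rooted=False)
            node = [
                l for l in rerooted.leaf_node_iter()
                if l.taxon.label == leaf.taxon.label
            ][0]
            rerooted.reroot_at_edge(node.edge, update_bipartitions=False)
            rerooted.is_rooted = False
            assert is_monophyletic(rerooted, target)[0] == reference


class TestResolutionRates:
    def test_three_species_rates(self):
        tree = tree_from_newick(
            "(((A1:1,A2:1)95:1,(B1:1,B2:1)60:1):1,(C1:1,(C2:1,B3:1):1):1);",
            rooted=True,
        )
        species = {
            "A1": "A", "A2": "A", "B1": "B", "B2": "B",
            "B3": "B", "C1": "C", "C2": "C",
        }
        rep = resolution_rates(tree, species, support_threshold=70)
        # A mono (95, supported), B not (B3 elsewhere)... B has 3 leaves
        assert rep.n_species_evaluated == 3
        assert rep.per_species["A"]["monophyletic"]
        assert not rep.per_species["B"]["monophyletic"]
        assert not rep.per_species["C"]["monophyletic"]
        assert rep.rate == pytest.approx(33.3)
        assert rep.rate_supported == pytest.approx(33.3)

    def test_all_singletons_policy(self):
        tree = tree_from_newick("((A1,B1),C1);", rooted=True)
        species = {"A1": "A", "B1": "B", "C1": "C"}
        rep = resolution_rates(tree, species)
        assert rep.rate == 100.0
        assert rep.rate_supported == 0.0
        rep2 = resolution_rates(tree, species, singletons_count=False)
        assert rep2.rate == 0.0

    def test_matches_exhaustive_clade_scan(self):
        rng = np.random.default_rng(31)
        import dendropy

        for rep_i in range(30):
            n = int(rng.integers(4, 11))
            labels = [f"l{i}" for i in range(n)]
            taxa = dendropy.TaxonNamespace(labels)
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
                num_extant_tips=n, rng=__import__("random").Random(int(rng.integers(1 << 30))),
            )
            tree.is_rooted = True
            species = {lab: f"S{int(rng.integers(3))}" for lab in labels}
            rep = resolution_rates(tree, species, support_threshold=70)
            # oracle: dendropy MRCA-based clade scan
            for sp in set(species.values()):
                members = [l for l in labels if species[l] == sp]
                if len(members) == 1:
                    assert rep.per_species[sp]["monophyletic"]
                    continue
                mrca = tree.mrca(taxa=[taxa.get_taxon(m) for m in members])
                oracle_mono = set(
                    l.taxon.label for l in mrca.leaf_iter()
                ) == set(members)
                assert rep.per_species[sp]["monophyletic"] == oracle_mono
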