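import itertools
import math

import dendropy
import numpy as np
import pytest

from phyloprof.alphabet import rng_for
from phyloprof.msa_processing import GroupedMSA
from phyloprof.phylo import (DistanceMatrix, UndefinedDistanceError,
                             apply_losses, dollo_losses, label_internal_nodes,
                             neighbor_joining, pairwise_distance,
                             screen_paralogs, _node_id)
from phyloprof.synthetic_data import simulate_tree


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick",
                          suppress_internal_node_taxa=True,
                          preserve_underscores=True)
    t.is_rooted = True
    return label_internal_nodes(t)


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        d = pairwise_distance(GroupedMSA(["a", "b"], ["MKWV", "MKWV"]))
        assert d.matrix[0, 1] == 0.0

    def test_poisson_correction(self):
        # p = 0.1 over 10 shared columns -> -ln(0.9)
        d = pairwise_distance(GroupedMSA(["a", "b"],
                                         ["AAAAAAAAAA", "AAAAAAAAAC"]))
        assert d.matrix[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)
        assert d.matrix[0, 1] == pytest.approx(0.10536, abs=1e-5)

    def test_symmetric(self):
        msa = GroupedMSA(["a", "b", "c"], ["MKWV", "MKYV", "MRWV"])
        d = pairwise_distance(msa)
        np.testing.assert_allclose(d.matrix, d.matrix.T)

    def test_saturated_pair_clamped(self):
        d = pairwise_distance(GroupedMSA(["a", "b"], ["AAAA", "CCCC"]))
        assert d.matrix[0, 1] == 10.0

    def test_no_shared_columns_raises(self):
        with pytest.raises(UndefinedDistanceError):
            pairwise_distance(GroupedMSA(["a", "b"], ["AA--", "--CC"]))


def _splits(tree):
    """Non-trivial splits as frozensets of leaf labels (unrooted)."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            out.add(min(below, leaves - below, key=sorted))
    return out


def _random_additive_case(rng, n):
    """Random unrooted topology + positive lengths -> (ids, D, true splits)."""
    ids = [f"x{i}" for i in range(n)]
    # random binary tree by sequential joining
    nodes = {i: dendropy.Node(taxon=dendropy.Taxon(label=ids[i]))
             for i in range(n)}
    ns = dendropy.TaxonNamespace([nodes[i].taxon for i in range(n)])
    pool = list(nodes.values())
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(pool[i])
        parent.add_child(pool[j])
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for p in pool:
        root.add_child(p)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.5, 3.0))
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    taxa = {t.label: t for t in ns}
    for a in range(n):
        for b in range(n):
            if a != b:
                D[a, b] = pdm.distance(taxa[ids[a]], taxa[ids[b]])
    return ids, D, _splits(tree)


class TestNeighborJoining:
    def test_four_taxon_additive_split(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): additive distances
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], D))
        assert _splits(tree) == {frozenset({"A", "B"})}

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_additive_recovery_100_cases(self):
        rng = rng_for(31, "nj-oracle")
        for case in range(100):
            n = int(rng.integers(4, 7))
            ids, D, want = _random_additive_case(rng, n)
            tree = neighbor_joining(DistanceMatrix(ids, D))
            assert _splits(tree) == want, f"case {case}"

    def test_input_order_invariance(self):
        rng = rng_for(13, "nj-perm")
        ids, D, want = _random_additive_case(rng, 5)
        for perm in ([4, 2, 0, 1, 3], [1, 0, 3, 4, 2]):
            pids = [ids[p] for p in perm]
            pD = D[np.ix_(perm, perm)]
            tree = neighbor_joining(DistanceMatrix(pids, pD))
            assert _splits(tree) == want

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], D))


class TestScreenParalogs:
    def test_long_branch_paralogs_excluded(self):
        # orthologs form a tight clade; paralogs sit on long branches
        newick = ("((a1:0.1,(a2:0.1,a3:0.12):0.05):0.1,"
                  "(p1:2.0,p2:2.2):0.3);")
        kept = screen_paralogs(_tree(newick), ["a1", "a2", "a3"])
        assert kept == {"a1", "a2", "a3"}

    def test_all_leaves_as_references(self):
        newick = "((a:1,b:1):1,(c:1,d:1):1);"
        kept = screen_paralogs(_tree(newick), ["a", "b", "c", "d"])
        assert kept == {"a", "b", "c", "d"}

    def test_single_reference_expands_to_cherry(self):
        # asymmetric lengths give an unambiguous midpoint: exactly the cherry
        kept = screen_paralogs(_tree("((a:1,b:1):1,(c:5,d:5):5);"), ["a"])
        assert kept == {"a", "b"}
        # symmetric case: the parent clade may be larger, never just the leaf
        kept = screen_paralogs(_tree("((a:1,b:1):1,(c:1,d:1):1);"), ["a"])
        assert {"a"} < kept

    def test_monotone_in_references(self):
        newick = "(((a:1,b:1):1,c:1):1,(d:1,e:1):1);"
        small = screen_paralogs(_tree(newick), ["a"])
        large = screen_paralogs(_tree(newick), ["a", "d"])
        assert small <= large

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            screen_paralogs(_tree("((a:1,b:1):1,c:1);"), ["zz"])

    def test_fixture_paralogs_screened(self, dataset, scoring):
        from phyloprof.msa_processing import progressive_align
        from phyloprof.phylo import pairwise_distance as pdist

        truth = dataset.truth
        family = "e1_act"
        seqs = {}
        for taxon in truth.presence.index:
            for sid, s in dataset.proteomes.proteomes[taxon].items():
                if sid.startswith(f"{taxon}|{family}") and "decoy" not in sid:
                    seqs[sid] = s
        msa = progressive_align(seqs, scoring)
        gene_tree = neighbor_joining(pdist(msa))
        refs = [sid for sid in seqs if "_par" not in sid]
        kept = screen_paralogs(gene_tree, refs)
        assert set(refs) <= kept
        assert not any(p in kept for p in truth.paralogs)


class TestDolloLosses:
    def test_single_loss_cherry(self):
        tree = _tree("((A:1,B:1)n1:1,(C:1,D:1)n2:1)n0;")
        lm = dollo_losses(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert lm.n_losses == 1
        node = lm.loss_branches[0]
        # the loss branch is the (C,D) ancestor
        assert node == "n2"

    def test_all_present_no_losses(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        lm = dollo_losses(tree, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert lm.n_losses == 0

    def test_two_independent_losses(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        lm = dollo_losses(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert lm.n_losses == 2
        assert sorted(lm.loss_branches) == ["B", "D"]

    def test_all_absent_rejected(self):
        tree = _tree("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            dollo_losses(tree, {"A": 0, "B": 0, "C": 0})

    def test_missing_taxon_rejected(self):
        tree = _tree("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            dollo_losses(tree, {"A": 1, "B": 0})

    def test_roundtrip_random(self):
        rng = rng_for(17, "dollo-rt")
        for case in range(30):
            tree = simulate_tree(int(rng.integers(4, 10)), seed=case)
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            presence = {t: int(rng.integers(2)) for t in leaves}
            if not any(presence.values()):
                presence[leaves[0]] = 1
            lm = dollo_losses(tree, presence)
            back = apply_losses(tree, lm.loss_branches)
            assert back == presence

    def test_minimality_brute_force(self):
        rng = rng_for(23, "dollo-min")
        for t_seed in range(4):
            n = int(rng.integers(4, 9))
            tree = simulate_tree(n, seed=t_seed)
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            branches = [_node_id(nd) for nd in tree.preorder_node_iter()
                        if nd.parent_node is not None]
            for bits in range(1, 2 ** n):
                presence = {t: (bits >> k) & 1 for k, t in enumerate(leaves)}
                lm = dollo_losses(tree, presence)
                # no strictly smaller branch set explains the same pattern
                for k in range(lm.n_losses):
                    assert not any(
                        apply_losses(tree, subset) == presence
                        for subset in itertools.combinations(branches, k))
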