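import itertools

import dendropy
import numpy as np
import pytest

from symtrace.alignio import GeneAlignment
from symtrace.treebuild import (
    DistanceMatrix,
    collapse_low_support,
    collapse_short_branches,
    felsenstein_support,
    ls_branch_lengths,
    neighbor_joining,
    pairwise_distances,
    read_newick,
    refine_compatible,
    rf_distance,
    root_tree,
    tip_labels,
    transfer_bootstrap_expectation,
    tree_from_splits,
    write_newick,
)

from conftest import make_alignment, tree_from_newick
from oracles import (
    brute_force_rf,
    brute_force_tbe,
    path_distances,
    random_binary_tree,
    splits_as_sets,
)


def dm_from_tree(tree):
    """Additive distance matrix: leaf-to-leaf path lengths."""
    pd = path_distances(tree)
    ids = sorted(tip_labels(tree))
    d = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                d[i, j] = pd[(a, b)]
    return DistanceMatrix(ids, d)


class TestPairwiseDistances:
    def test_identical_sequences_zero(self):
        aln = make_alignment({"a": "ACGTACGT", "b": "ACGTACGT"})
        for model in ("p_distance", "JC69"):
            assert pairwise_distances(aln, model).d[0, 1] == 0.0

    def test_jc_correction_closed_form(self):
        # 1 mismatch over 10 sites: p=0.1, d = -(3/4) ln(1 - 4*0.1/3)
        aln = make_alignment({"a": "AAAAAAAAAA", "b": "CAAAAAAAAA"})
        d = pairwise_distances(aln, "JC69").d[0, 1]
        assert d == pytest.approx(0.1073256, abs=1e-6)

    def test_saturated_pair_capped(self):
        aln = make_alignment({"a": "AAAA", "b": "CCCA"})  # p = 0.75
        assert pairwise_distances(aln, "JC69").d[0, 1] == 5.0

    def test_pairwise_deletion_of_missing(self):
        # gap/N columns are excluded pair by pair
        aln = make_alignment({"a": "ACGT-N", "b": "ACTTAA", "c": "ACGTAA"})
        dm = pairwise_distances(aln, "p_distance")
        i, j = dm.strain_ids.index("a"), dm.strain_ids.index("b")
        assert dm.d[i, j] == pytest.approx(0.25)  # 1 mismatch / 4 valid sites

    def test_no_valid_sites_capped(self):
        aln = make_alignment({"a": "NN--", "b": "--NN", "c": "ACGT"})
        dm = pairwise_distances(aln, "JC69")
        i, j = dm.strain_ids.index("a"), dm.strain_ids.index("b")
        assert dm.d[i, j] == 5.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery_vs_enumeration(self, rng):
        # oracle: evaluate all 3 unrooted quartet topologies by their
        # least-squares fit to the matrix; the perfectly additive one wins
        true = tree_from_newick("((A:0.3,B:0.4):0.25,C:0.2,D:0.7);")
        dm = dm_from_tree(true)
        quartets = {
            frozenset([frozenset("AB"), frozenset("CD")]): "((A:1,B:1):1,C:1,D:1);",
            frozenset([frozenset("AC"), frozenset("BD")]): "((A:1,C:1):1,B:1,D:1);",
            frozenset([frozenset("AD"), frozenset("BC")]): "((A:1,D:1):1,B:1,C:1);",
        }
        errors = {}
        for key, nwk in quartets.items():
            fit = ls_branch_lengths(tree_from_newick(nwk), dm)
            pd = path_distances(fit)
            err = sum(
                (pd[(a, b)] - dm.d[dm.strain_ids.index(a), dm.strain_ids.index(b)]) ** 2
                for a, b in itertools.combinations(dm.strain_ids, 2)
            )
            errors[key] = err
        best = min(errors, key=errors.get)
        nj = neighbor_joining(dm)
        assert splits_as_sets(nj) == {frozenset("AB")} or splits_as_sets(nj) == {
            frozenset("CD")
        }
        assert best == frozenset([frozenset("AB"), frozenset("CD")])
        # path lengths reproduce the additive matrix exactly
        pd = path_distances(nj)
        for a, b in itertools.combinations(dm.strain_ids, 2):
            assert pd[(a, b)] == pytest.approx(
                dm.d[dm.strain_ids.index(a), dm.strain_ids.index(b)], abs=1e-12
            )

    @pytest.mark.parametrize("n_tips", [5, 8, 12])
    def test_consistency_on_additive_input(self, n_tips, rng):
        for _ in range(5):
            labels = [f"t{i}" for i in range(n_tips)]
            true = random_binary_tree(labels, rng)
            nj = neighbor_joining(dm_from_tree(true))
            assert rf_distance(nj, true) == 0
            pd_true = path_distances(true)
            pd_nj = path_distances(nj)
            for key in pd_true:
                assert pd_nj[key] == pytest.approx(pd_true[key], abs=1e-9)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_deterministic_under_ties(self):
        # perfectly symmetric matrix: result fixed by lexicographic tie-break
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(["d", "c", "b", "a"], d)
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


class TestSupports:
    def test_all_replicates_identical_gives_one(self, rng):
        ref = random_binary_tree([f"t{i}" for i in range(6)], rng)
        out = felsenstein_support(ref, [ref, ref, ref])
        sups = [nd.support for nd in out.preorder_internal_node_iter()
                if getattr(nd, "support", None) is not None]
        assert sups and all(s == 1.0 for s in sups)

    def test_star_replicates_give_zero(self, rng):
        ref = random_binary_tree([f"t{i}" for i in range(6)], rng)
        star = tree_from_newick("(t0,t1,t2,t3,t4,t5);")
        out = felsenstein_support(ref, [star, star])
        sups = [nd.support for nd in out.preorder_internal_node_iter()
                if getattr(nd, "support", None) is not None]
        assert sups and all(s == 0.0 for s in sups)

    def test_counting_three_of_four(self):
        ref = tree_from_newick("((A,B),(C,D));")
        with_split = tree_from_newick("((A,B),(C,D));")
        without = tree_from_newick("((A,C),(B,D));")
        out = felsenstein_support(ref, [with_split] * 3 + [without])
        sups = {nd.support for nd in out.preorder_internal_node_iter()
                if getattr(nd, "support", None) is not None}
        assert sups == {0.75}

    def test_tip_mismatch_rejected(self, rng):
        ref = random_binary_tree(["a", "b", "c", "d"], rng)
        rep = random_binary_tree(["a", "b", "c", "e"], rng)
        with pytest.raises(ValueError, match="tip sets"):
            felsenstein_support(ref, [rep])

    def test_tbe_matches_brute_force(self, rng):
        for trial in range(10):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            ref = random_binary_tree(labels, rng)
            reps = [random_binary_tree(labels, rng) for _ in range(8)]
            out = transfer_bootstrap_expectation(ref, reps)
            oracle = brute_force_tbe(ref, reps)
            got = {}
            all_labels = frozenset(labels)
            anchor = min(all_labels)
            for nd in out.preorder_internal_node_iter():
                if getattr(nd, "support", None) is None:
                    continue
                below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                side = below if anchor not in below else all_labels - below
                got[side] = nd.support
            assert set(got) == set(oracle)
            for side in oracle:
                assert got[side] == pytest.approx(oracle[side], abs=1e-12)

    def test_tbe_at_least_fbp_and_cherry_equality(self, rng):
        labels = [f"t{i}" for i in range(8)]
        ref = random_binary_tree(labels, rng)
        reps = [random_binary_tree(labels, rng) for _ in range(20)]
        fbp = felsenstein_support(ref, reps)
        tbe = transfer_bootstrap_expectation(ref, reps)
        n = len(labels)
        for nf, nt in zip(
            fbp.preorder_internal_node_iter(), tbe.preorder_internal_node_iter()
        ):
            sf = getattr(nf, "support", None)
            st = getattr(nt, "support", None)
            if sf is None:
                continue
            assert st >= sf - 1e-12
            below = sum(1 for _ in nf.leaf_iter())
            if min(below, n - below) == 2:
                assert st == pytest.approx(sf, abs=1e-12)


class TestCollapse:
    def tree_with_supports(self, supports):
        t = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
        nodes = [nd for nd, _, _ in
                 __import__("symtrace.treebuild", fromlist=["internal_edges"])
                 .internal_edges(t)]
        for nd, s in zip(nodes, supports):
            nd.support = s
        return t

    def test_threshold_zero_keeps_everything(self):
        t = self.tree_with_supports([0.9, 0.9, 0.4])
        out, frac = collapse_low_support(t, 0.0)
        assert frac == 0.0
        assert rf_distance(out, t) == 0

    def test_all_below_threshold_gives_star(self):
        t = self.tree_with_supports([0.1, 0.2, 0.3])
        out, frac = collapse_low_support(t, 0.9)
        assert frac == 1.0
        assert len(splits_as_sets(out)) == 0

    def test_counting_one_of_three(self):
        t = self.tree_with_supports([0.9, 0.9, 0.4])
        out, frac = collapse_low_support(t, 0.6)
        assert frac == pytest.approx(1 / 3)
        assert len(splits_as_sets(out)) == 2

    def test_strict_inequality_at_threshold(self):
        # "lower than" is strict: support exactly at threshold is kept
        t = self.tree_with_supports([0.6, 0.6, 0.6])
        _, frac = collapse_low_support(t, 0.6)
        assert frac == 0.0

    def test_unsupported_edge_rejected(self):
        t = tree_from_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(ValueError, match="support"):
            collapse_low_support(t, 0.5)

    def test_monotone_in_threshold(self, rng):
        labels = [f"t{i}" for i in range(10)]
        t = random_binary_tree(labels, rng)
        for nd, _, _ in __import__(
            "symtrace.treebuild", fromlist=["internal_edges"]
        ).internal_edges(t):
            nd.support = float(rng.uniform(0, 1))
        fracs = []
        prev_splits = None
        for thr in (0.2, 0.5, 0.8):
            out, frac = collapse_low_support(t, thr)
            fracs.append(frac)
            splits = splits_as_sets(out)
            if prev_splits is not None:
                assert splits <= prev_splits
            prev_splits = splits
        assert fracs == sorted(fracs)

    def test_short_branch_contraction(self):
        t = tree_from_newick("((A:1,B:1):0.001,(C:1,D:1):0.5,E:1);")
        out = collapse_short_branches(t, 0.01)
        assert splits_as_sets(out) == {frozenset("CD")}


class TestRobinsonFoulds:
    def test_identical_zero(self, rng):
        t = random_binary_tree(["a", "b", "c", "d", "e"], rng)
        assert rf_distance(t, t) == 0

    def test_maximum_for_disjoint_five_taxon(self):
        t1 = tree_from_newick("((A,B),(C,D),E);")
        t2 = tree_from_newick("((A,C),(B,E),D);")
        assert rf_distance(t1, t2) == 4

    def test_matches_brute_force_and_dendropy(self, rng):
        tns_pairs = []
        for _ in range(20):
            n = int(rng.integers(4, 11))
            labels = [f"t{i}" for i in range(n)]
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            got = rf_distance(t1, t2)
            assert got == brute_force_rf(t1, t2)
            tns_pairs.append((t1, t2, got))
        # independent cross-check against dendropy's implementation
        for t1, t2, got in tns_pairs[:5]:
            tns = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(
                data=t1.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns,
            )
            b = dendropy.Tree.get(
                data=t2.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns,
            )
            a.encode_bipartitions()
            b.encode_bipartitions()
            assert got == dendropy.calculate.treecompare.symmetric_difference(a, b)

    def test_metric_properties(self, rng):
        labels = [f"t{i}" for i in range(7)]
        trees = [random_binary_tree(labels, rng) for _ in range(3)]
        a, b, c = trees
        assert rf_distance(a, b) == rf_distance(b, a)
        assert rf_distance(a, b) + rf_distance(b, c) >= rf_distance(a, c)


class TestSplitsAndRefinement:
    def test_tree_from_splits_round_trip(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 10))
            labels = [f"t{i}" for i in range(n)]
            t = random_binary_tree(labels, rng)
            from symtrace.treebuild import _taxon_bits, internal_edges

            bits = _taxon_bits(labels)
            masks = {m for _, m, _ in internal_edges(t, bits)}
            rebuilt = tree_from_splits(labels, masks)
            assert rf_distance(rebuilt, t) == 0

    def test_refine_adds_only_compatible_splits(self, rng):
        labels = [f"t{i}" for i in range(8)]
        t1 = random_binary_tree(labels, rng)
        t2 = random_binary_tree(labels, rng)
        ref = refine_compatible(t1, t2)
        assert splits_as_sets(t1) <= splits_as_sets(ref)
        # refinement of identical trees is a fixed point
        same = refine_compatible(t1, t1)
        assert rf_distance(same, t1) == 0

    def test_refine_equalizes_resolution_differences(self):
        resolved = tree_from_newick("(((A,B),C),(D,E),F);")
        poly = tree_from_newick("((A,B,C),(D,E),F);")
        out = refine_compatible(poly, resolved)
        assert rf_distance(out, resolved) == 0


class TestNewickAndRooting:
    def test_round_trip_supports_and_lengths(self, tmp_path, rng):
        t = random_binary_tree(["a", "b", "c", "d", "e"], rng)
        from symtrace.treebuild import internal_edges

        for nd, _, _ in internal_edges(t):
            nd.support = 0.625
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert rf_distance(back, t) == 0
        sups = [getattr(nd, "support", None)
                for nd, _, _ in internal_edges(back)]
        assert all(s == 0.625 for s in sups)
        pd_a, pd_b = path_distances(t), path_distances(back)
        for key in pd_a:
            assert pd_b[key] == pytest.approx(pd_a[key], rel=1e-6)

    def test_outgroup_rooting(self, rng):
        t = random_binary_tree(["a", "b", "c", "d", "og"], rng)
        rooted = root_tree(t, outgroup="og")
        children = rooted.seed_node.child_nodes()
        assert any(
            ch.is_leaf() and ch.taxon.label == "og" for ch in children
        )

    def test_missing_outgroup_rejected(self, rng):
        t = random_binary_tree(["a", "b", "c", "d"], rng)
        with pytest.raises(ValueError, match="outgroup"):
            root_tree(t, outgroup="nope")

    def test_midpoint_rooting_preserves_topology(self, rng):
        t = random_binary_tree(["a", "b", "c", "d", "e", "f"], rng)
        rooted = root_tree(t)
        assert set(tip_labels(rooted)) == set(tip_labels(t))
        assert rf_distance(rooted, t) == 0


class TestLsBranchLengths:
    def test_recovers_lengths_on_additive_input(self, rng):
        labels = [f"t{i}" for i in range(6)]
        true = random_binary_tree(labels, rng)
        dm = dm_from_tree(true)
        fit = ls_branch_lengths(true, dm)
        pd_true, pd_fit = path_distances(true), path_distances(fit)
        for key in pd_true:
            assert pd_fit[key] == pytest.approx(pd_true[key], abs=1e-8)
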