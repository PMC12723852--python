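import numpy as np
import pandas as pd
import pytest

from gmspop import (DistanceMatrix, FreqTable, MISSING, allele_frequencies,
                    assign_blocks, block_jackknife, f3_distance_matrix,
                    f3_outgroup, f4, nj_tree)
from gmspop.fstats import TreeNode

from conftest import freq_table, make_matrix


class TestAlleleFrequencies:
    def test_hand_example_with_missing(self):
        calls = np.array([[0, 2], [1, MISSING], [2, 1], [1, 1]], dtype=np.int8)
        G = make_matrix(calls, populations=["P1", "P1", "P2", "P2"])
        F = allele_frequencies(G)
        assert F.populations == ["P1", "P2"]
        assert F.freq[0] == pytest.approx([1 / 4, 2 / 2])
        assert F.freq[1] == pytest.approx([3 / 4, 2 / 4])
        assert F.n_obs.tolist() == [[4, 2], [4, 4]]

    def test_all_missing_cell_is_nan(self):
        calls = np.array([[MISSING], [1]], dtype=np.int8)
        G = make_matrix(calls, populations=["P1", "P2"])
        F = allele_frequencies(G)
        assert np.isnan(F.freq[0, 0]) and F.n_obs[0, 0] == 0

    def test_unknown_population_raises(self):
        F = freq_table({"X": [0.5]})
        with pytest.raises(KeyError):
            F.index_of("nope")


class TestAssignBlocks:
    def test_fixed_mb_respects_chromosomes(self):
        snps = pd.DataFrame({
            "snp_id": list("abcdef"),
            "chrom": ["1", "1", "1", "2", "2", "2"],
            "pos_cm": 0.0,
            "pos_bp": [1e6, 4e6, 6e6, 1e6, 2e6, 9e6],
            "allele1": "A", "allele2": "G",
        })
        ids = assign_blocks(snps, "fixed_mb", 5.0)
        # chr1: [0-5), [5-10) -> blocks 0,0,1; chr2: bins 0 and 1 -> 2,2,3
        assert ids.tolist() == [0, 0, 1, 2, 2, 3]

    def test_empty_bins_compressed(self):
        snps = pd.DataFrame({
            "snp_id": ["a", "b"], "chrom": "1", "pos_cm": 0.0,
            "pos_bp": [1e6, 99e6], "allele1": "A", "allele2": "G",
        })
        ids = assign_blocks(snps, "fixed_mb", 5.0)
        assert ids.tolist() == [0, 1]  # not [0, 19]

    def test_fixed_snp_count(self):
        snps = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(7)], "chrom": "1",
            "pos_cm": 0.0, "pos_bp": np.arange(7), "allele1": "A",
            "allele2": "G",
        })
        assert assign_blocks(snps, "fixed_snp_count", 3).tolist() == [
            0, 0, 0, 1, 1, 1, 2]

    def test_unknown_scheme_raises(self):
        snps = pd.DataFrame({
            "snp_id": ["a"], "chrom": "1", "pos_cm": 0.0, "pos_bp": [1],
            "allele1": "A", "allele2": "G",
        })
        with pytest.raises(ValueError):
            assign_blocks(snps, "bogus", 1)


class TestBlockJackknife:
    def test_two_block_closed_form(self):
        # equal unit counts, sums 1 and 3: estimate 2, jackknife SE exactly 1
        est, se = block_jackknife([1.0, 3.0], [1.0, 1.0])
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(1.0)

    def test_equal_blocks_match_classic_jackknife(self, rng):
        # with equal block sizes the weighted formula reduces to the classic
        # delete-one jackknife; verify against an independent computation
        g, m = 8, 5
        vals = rng.normal(size=(g, m))
        sums, counts = vals.sum(axis=1), np.full(g, float(m))
        est, se = block_jackknife(sums, counts)
        theta = vals.mean()
        theta_j = np.array([
            np.delete(vals, j, axis=0).mean() for j in range(g)])
        var = (g - 1) / g * ((theta_j - theta_j.mean()) ** 2).sum()
        assert est == pytest.approx(theta)
        assert se == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_empty_blocks_dropped(self):
        est, se = block_jackknife([1.0, 0.0, 3.0], [1.0, 0.0, 1.0])
        assert (est, se) == pytest.approx((2.0, 1.0))

    def test_single_block_raises(self):
        with pytest.raises(ValueError):
            block_jackknife([1.0], [2.0])

    def test_constant_terms_zero_se(self):
        est, se = block_jackknife([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)


class TestF3:
    def test_uncorrected_toy_value(self):
        F = freq_table({
            "X": [0.1, 0.2, 0.3, 0.4],
            "Y": [0.2, 0.1, 0.5, 0.3],
            "O": [0.5, 0.5, 0.5, 0.5],
        })
        r = f3_outgroup(F, "X", "Y", "O", apex_correction=False)
        expected = np.mean([0.4 * 0.3, 0.3 * 0.4, 0.2 * 0.0, 0.1 * 0.2])
        assert r.estimate == pytest.approx(expected)
        assert r.kind == "f3_outgroup" and r.n_snps_used == 4

    def test_apex_correction_subtracts_h_over_n(self):
        F = freq_table({"X": [0.1] * 4, "Y": [0.2] * 4, "O": [0.5] * 4},
                       n_obs=2)
        r0 = f3_outgroup(F, "X", "Y", "O", apex_correction=False)
        r1 = f3_outgroup(F, "X", "Y", "O", apex_correction=True)
        # h_o / n_o with the (n_o - 1) denominator: 0.25 / 1 = 0.25
        assert r0.estimate - r1.estimate == pytest.approx(0.25)

    def test_correction_vanishes_for_large_outgroup(self):
        F = freq_table({"X": [0.1] * 4, "Y": [0.2] * 4, "O": [0.5] * 4},
                       n_obs=10**9)
        r0 = f3_outgroup(F, "X", "Y", "O", apex_correction=False)
        r1 = f3_outgroup(F, "X", "Y", "O", apex_correction=True)
        assert r1.estimate == pytest.approx(r0.estimate, abs=1e-8)

    def test_symmetry_in_x_y(self):
        F = freq_table({"X": [0.1, 0.9, 0.4], "Y": [0.2, 0.3, 0.8],
                        "O": [0.6, 0.1, 0.5]})
        a = f3_outgroup(F, "X", "Y", "O")
        b = f3_outgroup(F, "Y", "X", "O")
        assert a.estimate == pytest.approx(b.estimate)
        assert a.se_jackknife == pytest.approx(b.se_jackknife)

    def test_sites_without_data_excluded(self):
        F = freq_table({"X": [0.1, np.nan, 0.3], "Y": [0.2, 0.2, 0.4],
                        "O": [0.5, 0.5, 0.5]})
        r = f3_outgroup(F, "X", "Y", "O")
        assert r.n_snps_used == 2

    def test_outgroup_singleton_alleles_excluded(self):
        F = freq_table({"X": [0.1, 0.3], "Y": [0.2, 0.4], "O": [0.5, 0.5]},
                       n_obs={"X": 100, "Y": 100, "O": 1})
        with pytest.raises(ValueError):
            f3_outgroup(F, "X", "Y", "O")  # n_O < 2 everywhere

    def test_zero_se_gives_zero_z(self):
        F = freq_table({"X": [0.1] * 4, "Y": [0.2] * 4, "O": [0.5] * 4})
        r = f3_outgroup(F, "X", "Y", "O", apex_correction=False)
        assert r.se_jackknife == pytest.approx(0.0, abs=1e-12)
        assert r.z == 0.0


class TestF4:
    def test_duplicate_population_gives_zero(self):
        F = freq_table({"W": [0.1, 0.8, 0.4], "X": [0.3, 0.2, 0.9],
                        "Y": [0.5, 0.6, 0.1]})
        r = f4(F, "W", "X", "Y", "Y")
        assert r.estimate == 0.0

    def test_antisymmetries(self):
        F = freq_table({"W": [0.1, 0.8, 0.4, 0.2], "X": [0.3, 0.2, 0.9, 0.7],
                        "Y": [0.5, 0.6, 0.1, 0.4], "Z": [0.9, 0.3, 0.2, 0.8]})
        base = f4(F, "W", "X", "Y", "Z")
        assert f4(F, "X", "W", "Y", "Z").estimate == pytest.approx(-base.estimate)
        assert f4(F, "W", "X", "Z", "Y").estimate == pytest.approx(-base.estimate)
        assert f4(F, "Y", "Z", "W", "X").estimate == pytest.approx(base.estimate)
        assert f4(F, "X", "W", "Z", "Y").estimate == pytest.approx(base.estimate)

    def test_toy_value(self):
        F = freq_table({"W": [1.0, 0.0], "X": [0.0, 0.0],
                        "Y": [1.0, 0.5], "Z": [0.0, 0.5]})
        r = f4(F, "W", "X", "Y", "Z")
        assert r.estimate == pytest.approx((1 * 1 + 0 * 0) / 2)


class TestDistanceAndNj:
    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0, 1], [2, 0]]))

    def test_f3_distance_matrix_symmetric(self):
        F = freq_table({"A": [0.1, 0.9, 0.4, 0.6], "B": [0.2, 0.3, 0.8, 0.5],
                        "C": [0.7, 0.1, 0.2, 0.9], "O": [0.5, 0.5, 0.5, 0.5]})
        D = f3_distance_matrix(F, ["A", "B", "C"], "O")
        assert np.allclose(D.d, D.d.T)
        assert np.allclose(np.diag(D.d), 0.0)
        assert D.d[0, 1] == pytest.approx(
            1 - f3_outgroup(F, "A", "B", "O").estimate)

    def test_outgroup_in_pop_list_raises(self):
        F = freq_table({"A": [0.1], "O": [0.5]})
        with pytest.raises(ValueError):
            f3_distance_matrix(F, ["A", "O"], "O")

    def test_four_taxon_additive_recovery(self):
        # distances from the tree ((A:1,B:2):3,(C:4,D:5)) are additive; NJ
        # must recover the split {A,B}|{C,D} and the exact path lengths
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(labels=labels, d=d))
        parts = tree.leaf_bipartitions()
        assert parts in ({frozenset({"A", "B"})}, {frozenset({"C", "D"})})
        # patristic distances reproduce the input exactly
        P = patristic(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert P[(a, b)] == pytest.approx(d[i, j]), (a, b)

    def test_nj_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        for rep in range(5):
            labels = [f"t{i}" for i in range(6)]
            # random additive tree -> random positive distances via points
            pts = rng.uniform(0, 1, size=(6, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            ours = nj_tree(DistanceMatrix(labels=labels, d=d))
            dm = skbio.DistanceMatrix(d, ids=labels)
            theirs = skbio.tree.nj(dm)
            ref = set()
            anchor = min(labels)
            for node in theirs.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < 5:
                    other = frozenset(labels) - below
                    if len(below) != len(other):
                        ref.add(min(below, other, key=len))
                    else:
                        ref.add(below if anchor in below else other)
            assert ours.leaf_bipartitions() == ref, rep

    def test_newick_well_formed(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        nwk = nj_tree(DistanceMatrix(labels=["a", "b", "c"], d=d)).to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")")
        for lbl in ("a", "b", "c"):
            assert lbl in nwk

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["a", "b"],
                                   d=np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_negative_branches_clamped(self):
        # strongly non-additive distances force negative NJ branch estimates
        d = np.array([
            [0, 1, 10, 10, 1],
            [1, 0, 1, 10, 10],
            [10, 1, 0, 1, 10],
            [10, 10, 1, 0, 1],
            [1, 10, 10, 1, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(labels=list("abcde"), d=d))

        def walk(node):
            assert node.branch_length >= 0.0
            for c in node.children:
                walk(c)

        walk(tree)


def patristic(tree: TreeNode) -> dict:
    """Leaf-to-leaf path lengths of an unrooted TreeNode tree."""
    dists = {}

    def down(node, acc, out):
        if not node.children:
            out[node.name] = acc
            return
        for c in node.children:
            down(c, acc + c.branch_length, out)

    # distance between leaves = depth_a + depth_b - 2 * depth(lca) relative
    # to the (arbitrary) root; compute by rooting at the top node
    def collect(node, depth, parent_path):
        path = parent_path + [node]
        if not node.children:
            leaves.append((node.name, depth, path))
        for c in node.children:
            collect(c, depth + c.branch_length, path)

    leaves: list = []
    collect(tree, 0.0, [])
    for a, da, pa in leaves:
        for b, db, pb in leaves:
            shared = 0.0
            sa = set(id(x) for x in pa)
            lca_depth = 0.0
            depth = 0.0
            for node in pb[1:]:
                depth += node.branch_length
                if id(node) in sa:
                    lca_depth = depth
            dists[(a, b)] = da + db - 2 * lca_depth
    return dists
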