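import numpy as np
import pytest

from gmspop import (MISSING, QcConfig, filter_loci, filter_sample_missingness,
                    hwe_exact_test, king_kinship, ld_prune,
                    remove_first_degree, run_qc)
from gmspop.quality_control import _hwe_oracle, _king_matrix, _pairwise_r2

from conftest import make_matrix


class TestSampleMissingness:
    def test_strictly_greater_removed_boundary_kept(self):
        # 4 SNPs; rates 0.0, 0.25, 0.5
        calls = np.array(
            [[0, 1, 2, 0],
             [0, 1, 2, MISSING],
             [MISSING, MISSING, 2, 0]], dtype=np.int8)
        G = make_matrix(calls)
        out, rep = filter_sample_missingness(G, max_rate=0.25)
        assert out.samples.sample_id.tolist() == ["S0", "S1"]
        assert [s for s, _ in rep.samples_removed] == ["S2"]
        rep.check_balance()

    def test_zero_threshold_removes_any_missing(self):
        calls = np.array([[0, 1], [MISSING, 1]], dtype=np.int8)
        out, _ = filter_sample_missingness(make_matrix(calls), max_rate=0.0)
        assert out.n_samples == 1

    def test_invalid_rate_raises(self):
        with pytest.raises(ValueError):
            filter_sample_missingness(make_matrix([[0]]), max_rate=1.5)


class TestHweExact:
    def test_matches_integer_oracle_on_grid(self):
        for n_AA in range(0, 8):
            for n_Aa in range(0, 8):
                for n_aa in range(0, 8):
                    if n_AA + n_Aa + n_aa == 0:
                        continue
                    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        _hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
                    ), (n_AA, n_Aa, n_aa)

    def test_allele_label_symmetry(self):
        assert hwe_exact_test(5, 2, 1) == pytest.approx(hwe_exact_test(1, 2, 5))

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_all_het_with_many_samples_is_small(self):
        # all-heterozygote configurations are extreme under HWE
        assert hwe_exact_test(0, 20, 0) < 1e-4

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_probabilities_is_a_valid_p_value(self, rng):
        # p-values lie in (0, 1] and the observed configuration is included
        for _ in range(50):
            counts = rng.integers(0, 15, size=3)
            if counts.sum() == 0:
                continue
            p = hwe_exact_test(*counts)
            assert 0 < p <= 1


class TestFilterLoci:
    def test_monomorphic_removed(self):
        calls = np.array([[0, 1], [0, 1], [0, 0]], dtype=np.int8)
        G = make_matrix(calls)
        out, rep = filter_loci(G, QcConfig(hwe_min_pop_size=100))
        assert out.snps.snp_id.tolist() == ["rs1"]
        assert rep.snps_removed[0][0] == "rs0"
        assert "maf" in rep.snps_removed[0][1]

    def test_per_population_missingness(self):
        # SNP0 is 50% missing in P2 only; boundary SNP1 at exactly the
        # threshold is kept (strict >)
        calls = np.array(
            [[0, 1], [1, 0], [MISSING, 1], [2, MISSING]], dtype=np.int8)
        G = make_matrix(calls, populations=["P1", "P1", "P2", "P2"])
        cfg = QcConfig(max_locus_missing_per_pop=0.5, hwe_min_pop_size=100)
        out, rep = filter_loci(G, cfg)
        assert out.n_snps == 2  # both exactly 0.5 in P2: kept
        cfg2 = QcConfig(max_locus_missing_per_pop=0.4, hwe_min_pop_size=100)
        out2, rep2 = filter_loci(G, cfg2)
        assert out2.n_snps == 0
        assert all("missing_P2" in r for _, r in rep2.snps_removed)

    def test_hwe_filter_respects_min_pop_size(self):
        # rs0: zero heterozygotes among 6 samples, exact p = 20/924 ~ 0.0216
        # rs1: (1 hom, 4 het, 1 hom) is the modal configuration, p = 1
        calls = np.array(
            [[0, 0], [0, 1], [0, 1], [2, 1], [2, 1], [2, 2]], dtype=np.int8)
        G = make_matrix(calls)
        assert hwe_exact_test(3, 0, 3) == pytest.approx(20 / 924)
        small = QcConfig(hwe_alpha=0.05, hwe_min_pop_size=6, min_maf=0.0)
        out, rep = filter_loci(G, small)
        assert out.snps.snp_id.tolist() == ["rs1"]
        assert "hwe_POP" in rep.snps_removed[0][1]
        # population below hwe_min_pop_size is exempt from the HWE test
        big = QcConfig(hwe_alpha=0.05, hwe_min_pop_size=7, min_maf=0.0)
        out2, _ = filter_loci(G, big)
        assert out2.n_snps == 2


class TestKinship:
    def test_duplicate_is_exactly_half(self, rng):
        g = rng.integers(0, 3, size=200).astype(np.int8)
        g[0] = 1  # ensure at least one heterozygote
        assert king_kinship(g, g) == 0.5

    def test_hand_computed_value(self):
        gi = np.array([1, 1, 0, 2, 1], dtype=np.int8)
        gj = np.array([1, 0, 2, 0, 1], dtype=np.int8)
        # het_het=2, opp_hom=2 (loci 3,4? -> pairs (0,2) and (2,0)), het_i=3, het_j=2
        assert king_kinship(gi, gj) == pytest.approx((2 - 2 * 2) / (3 + 2))

    def test_missing_sites_excluded(self):
        gi = np.array([1, MISSING, 0], dtype=np.int8)
        gj = np.array([1, 2, MISSING], dtype=np.int8)
        assert king_kinship(gi, gj) == pytest.approx(0.5)

    def test_no_overlap_raises(self):
        gi = np.array([MISSING, 0], dtype=np.int8)
        gj = np.array([0, MISSING], dtype=np.int8)
        with pytest.raises(ValueError):
            king_kinship(gi, gj)

    def test_matrix_matches_scalar(self, rng):
        calls = rng.integers(0, 3, size=(6, 300)).astype(np.int8)
        phi = _king_matrix(calls)
        for i in range(6):
            for j in range(i + 1, 6):
                assert phi[i, j] == pytest.approx(
                    king_kinship(calls[i], calls[j]), abs=1e-12)

    def test_remove_first_degree_duplicate_pair(self, rng):
        base = rng.integers(0, 3, size=400).astype(np.int8)
        other = rng.integers(0, 3, size=(3, 400)).astype(np.int8)
        calls = np.vstack([base, base, other])
        G = make_matrix(calls, sample_ids=["kid_a", "kid_b", "u1", "u2", "u3"])
        out, rep = remove_first_degree(G)
        # equal degree and missingness: the lexicographically larger id goes
        assert [s for s, _ in rep.samples_removed] == ["kid_b"]
        assert "kid_a" in out.samples.sample_id.tolist()

    def test_remove_first_degree_prefers_hub(self, rng):
        # c is duplicated against both a and b: removing c resolves all pairs
        base = rng.integers(0, 3, size=400).astype(np.int8)
        calls = np.vstack([base, base, base,
                           rng.integers(0, 3, size=(2, 400)).astype(np.int8)])
        G = make_matrix(calls, sample_ids=["a", "b", "c", "u1", "u2"])
        out, rep = remove_first_degree(G)
        removed = {s for s, _ in rep.samples_removed}
        # a triangle needs two removals; the kept member is the smallest id
        assert removed == {"b", "c"}
        assert "a" in out.samples.sample_id.tolist()

    def test_cross_population_pairs_ignored(self, rng):
        base = rng.integers(0, 3, size=400).astype(np.int8)
        calls = np.vstack([base, base])
        G = make_matrix(calls, populations=["P1", "P2"])
        out, _ = remove_first_degree(G)
        assert out.n_samples == 2


class TestLdPrune:
    def test_r2_pairwise_complete(self):
        calls = np.array(
            [[0, 0], [1, 1], [2, 2], [MISSING, 0], [2, MISSING]], dtype=np.int8)
        G = make_matrix(calls)
        assert _pairwise_r2(G.calls, 0, 1) == pytest.approx(1.0)

    def test_perfect_ld_removes_lower_maf(self):
        # col1 = col0 / 2 is exactly linear in col0 (r^2 = 1), lower MAF
        col0 = np.array([0, 0, 0, 2, 2, 2], dtype=np.int8)
        col1 = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
        col2 = np.array([2, 0, 1, 2, 0, 1], dtype=np.int8)  # uncorrelated-ish
        G = make_matrix(np.column_stack([col0, col1, col2]))
        kept = ld_prune(G, window=3, step=3, r2_max=0.95)
        assert "rs1" not in kept and "rs0" in kept

    def test_tie_removes_later_position(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        G = make_matrix(np.column_stack([col, col]))
        kept = ld_prune(G, window=2, step=2, r2_max=0.4)
        assert kept == ["rs0"]

    def test_windows_do_not_span_chromosomes(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        G = make_matrix(np.column_stack([col, col]), chrom=["1", "2"],
                        pos_bp=[100, 100])
        kept = ld_prune(G, window=2, step=2, r2_max=0.4)
        assert sorted(kept) == ["rs0", "rs1"]

    def test_monomorphic_r2_is_zero(self):
        col0 = np.zeros(6, dtype=np.int8)
        col1 = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        G = make_matrix(np.column_stack([col0, col1]))
        assert _pairwise_r2(G.calls, 0, 1) == 0.0

    def test_prune_is_idempotent(self, small_two_pop):
        G, _ = small_two_pop
        kept = ld_prune(G, window=50, step=10, r2_max=0.4)
        idx = np.nonzero(G.snps.snp_id.isin(kept).to_numpy())[0]
        kept2 = ld_prune(G.subset(snp_idx=idx), window=50, step=10, r2_max=0.4)
        assert kept2 == kept


class TestRunQc:
    def test_chain_counts_and_report_balance(self, small_two_pop):
        G, _ = small_two_pop
        cfg = QcConfig(hwe_min_pop_size=100)  # skip HWE at this sample size
        out, rep = run_qc(G, cfg)
        rep.check_balance()
        assert rep.samples_before == G.n_samples
        assert rep.snps_before == G.n_snps
        assert out.n_samples == rep.samples_after
        assert out.n_snps == rep.snps_after

    def test_report_frame_shape(self, small_two_pop):
        G, _ = small_two_pop
        _, rep = run_qc(G, QcConfig(hwe_min_pop_size=100))
        frame = rep.to_frame()
        assert list(frame.columns) == ["axis", "item_id", "reason"]
        assert len(frame) == len(rep.samples_removed) + len(rep.snps_removed)

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            QcConfig(max_sample_missing=2.0)
        with pytest.raises(ValueError):
            QcConfig(prune_window=10, prune_step=20)
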