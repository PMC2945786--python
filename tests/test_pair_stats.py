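import numpy as np
import pytest
from scipy import stats

from coflank.exon_model import UPDP, UDDD
from coflank.pair_stats import (
    GCGrid,
    adjust_margin,
    build_gc_grid,
    cross_region_pvalues,
    default_alpha,
    evaluate_pairs,
    expected_pair_count,
    expected_position_pair_hits,
    hypergeom_tails,
    index_motif,
    kmer_presence,
    motif_index,
    num_hypotheses,
    pair_pvalue,
    presence_table,
    scan_pairs,
)
from coflank.synthetic_data import CorpusConfig, PlantedPair, generate_corpus

from _reference import naive_scan


class TestKmerPresence:
    def test_presence_is_binary(self):
        """A poly-A region contains 46 AAAAA occurrences but one presence."""
        pres = kmer_presence(["A" * 50], 5)
        assert pres.sum() == 1
        assert pres[0, motif_index("AAAAA")]

    def test_absent_motif(self):
        pres = kmer_presence(["ACGT" * 20], 5)
        assert not pres[0, motif_index("AAAAA")]

    def test_n_blocks_motifs(self):
        pres = kmer_presence(["AANAA"], 2)
        assert pres[0, motif_index("AA")]
        assert pres.sum() == 1  # AN/NA windows contribute nothing

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            kmer_presence(["ACGT"], 0)

    def test_roundtrip_motif_index(self):
        for m in ("AAAAA", "TTTTT", "GCGCG", "ACGTA"):
            assert index_motif(motif_index(m), 5) == m


class TestGCGrid:
    def test_forced_occupancy_40_exons(self, rng):
        corpus, _ = generate_corpus(CorpusConfig(n_exons=40, seed=3))
        grid = build_gc_grid(corpus, UPDP, n_bins=20)
        assert (grid.row_counts == 2).all()
        assert (grid.col_counts == 2).all()
        assert grid.K.sum() == 40

    def test_ties_still_balanced(self):
        """All-identical GC: occupancy stays balanced via exon_id tie-break."""
        from coflank.exon_model import ExonRecord

        corpus = [
            ExonRecord(
                exon_id=f"e{i:03d}", gene_id="g", splice_class="constitutive",
                exon_seq="ATG" * 30, up_flank="ACGT" * 25, down_flank="ACGT" * 25,
            )
            for i in range(40)
        ]
        grid = build_gc_grid(corpus, UPDP, n_bins=10)
        assert (grid.row_counts == 4).all()
        # determinism: same input -> same assignment
        grid2 = build_gc_grid(corpus, UPDP, n_bins=10)
        np.testing.assert_array_equal(grid.row_of, grid2.row_of)

    def test_single_box(self, small_null_corpus):
        grid = build_gc_grid(small_null_corpus, UPDP, n_bins=1)
        assert grid.K.tolist() == [[len(small_null_corpus)]]

    def test_too_few_exons(self, small_null_corpus):
        with pytest.raises(ValueError):
            build_gc_grid(small_null_corpus[:5], UPDP, n_bins=20)


class TestPresenceTable:
    def test_marginals_sum_over_strata(self, small_null_corpus):
        grid = build_gc_grid(small_null_corpus, UPDP, n_bins=5)
        tab = presence_table(small_null_corpus, grid, UPDP.upstream, 3)
        np.testing.assert_array_equal(tab.M.sum(axis=0), tab.n)
        assert ((tab.q >= 0) & (tab.q <= 1)).all()

    def test_two_row_tally(self):
        from coflank.pair_stats import presence_table_from_matrix

        presence = np.array([[1], [1], [0], [0]], dtype=bool)
        strata = np.array([0, 0, 1, 1])
        tab = presence_table_from_matrix(presence, strata, np.array([2, 2]), 1, "upstream")
        assert tab.q[0, 0] == 1.0 and tab.q[1, 0] == 0.0


class TestExpectedPairCount:
    def _grid(self, K):
        K = np.asarray(K)
        n = K.shape[0]
        return GCGrid(
            n_bins=n, row_of=None, col_of=None, K=K,
            row_counts=K.sum(1), col_counts=K.sum(0),
            row_edges=None, col_edges=None, N=int(K.sum()),
        )

    def test_hand_summation(self):
        grid = self._grid([[10, 10], [10, 10]])
        assert expected_pair_count(grid, [0.5, 0.1], [0.2, 0.3]) == pytest.approx(3.0)

    def test_uniform_reduces_to_unstratified(self):
        grid = self._grid([[10, 10], [10, 10]])
        n_u, n_d, N = 8, 12, 40
        k_prime = expected_pair_count(grid, [n_u / N] * 2, [n_d / N] * 2)
        assert k_prime == pytest.approx(n_u * n_d / N)

    def test_zero_q(self):
        grid = self._grid([[5, 5], [5, 5]])
        assert expected_pair_count(grid, [0, 0], [0.4, 0.2]) == 0.0


class TestAdjustMargin:
    def test_unstratified_identity(self):
        N, n_u, n_d = 200, 30, 44
        assert adjust_margin(N, n_u, n_u * n_d / N) == n_d

    def test_rounding(self):
        assert adjust_margin(100, 10, 2.04) == 20

    @pytest.mark.parametrize("kp,expected", [(0.0, 0), (1e9, 100)])
    def test_clamped(self, kp, expected):
        assert adjust_margin(100, 10, kp) == expected

    def test_zero_margin_skips(self):
        assert adjust_margin(100, 0, 5.0) is None


class TestPairPvalue:
    def test_zero_count(self):
        pu, pl = pair_pvalue(50, 5, 10, 0)
        assert pu == pytest.approx(1.0)
        assert pl == pytest.approx(stats.hypergeom.pmf(0, 50, 10, 5))

    def test_exact_tail_example(self):
        """N=20, n_U=5, n'_D=4, k_a=4: p_upper = C(16,1)/C(20,5) = 16/15504."""
        pu, _ = pair_pvalue(20, 5, 4, 4)
        assert pu == pytest.approx(16 / 15504, rel=1e-12)

    def test_degenerate_full_margin(self):
        pu, _ = pair_pvalue(30, 30, 12, 12)
        assert pu == pytest.approx(1.0)

    def test_invalid_margins(self):
        with pytest.raises(ValueError):
            pair_pvalue(10, 12, 5, 3)

    def test_tails_match_scipy_across_regimes(self, rng):
        for _ in range(150):
            N = int(rng.integers(5, 300))
            nU = int(rng.integers(0, N + 1))
            nD = int(rng.integers(0, N + 1))
            kmin, kmax = max(0, nU + nD - N), min(nU, nD)
            ka = int(rng.integers(kmin, kmax + 1))
            pu, pl = hypergeom_tails(np.array([ka]), N, nU, nD)
            assert pu[0] == pytest.approx(stats.hypergeom.sf(ka - 1, N, nD, nU), rel=1e-10, abs=1e-300)
            assert pl[0] == pytest.approx(stats.hypergeom.cdf(ka, N, nD, nU), rel=1e-10, abs=1e-300)


class TestScan:
    def test_hypothesis_space_size(self):
        assert num_hypotheses(5) == 1_048_576
        assert default_alpha(5) == pytest.approx(1 / 4**10)

    def test_power_arithmetic(self):
        """80,000 exons x 46^2 position pairs: ~161 co-hits per pentamer
        pairing but only ~10 per hexamer pairing."""
        assert expected_position_pair_hits(80_000, 46, 6) == pytest.approx(10.09, abs=0.01)
        assert expected_position_pair_hits(80_000, 46, 5) == pytest.approx(161.4, abs=0.1)

    def test_oracle_equivalence_small(self, small_null_corpus):
        """Vectorized scan equals the naive loop implementation bit-for-bit
        on counts and to 1e-12 on p-values (N=150, k=2, 4 strata)."""
        corpus = small_null_corpus
        res = scan_pairs(corpus, UPDP, k=2, n_bins=4, emit_all=True, alpha=1.0)
        ref = naive_scan(corpus, UPDP, 2, 4)
        full = res.full
        for (mu, md), (n_u, n_d, kp, nd_adj, ka, pu, pl) in ref.items():
            i, j = motif_index(mu), motif_index(md)
            assert full["n_U"][i] == n_u
            assert full["n_D"][j] == n_d
            assert full["k_a"][i, j] == ka
            assert full["k_prime"][i, j] == pytest.approx(kp, rel=1e-12)
            if n_u and n_d:
                assert full["nD_adj"][i, j] == nd_adj
            assert full["p_upper"][i, j] == pytest.approx(pu, rel=1e-9, abs=1e-12)
            assert full["p_lower"][i, j] == pytest.approx(pl, rel=1e-9, abs=1e-12)

    def test_single_bin_equals_plain_hypergeometric(self, small_null_corpus):
        """With a 1x1 grid the corrected test collapses exactly onto the
        unstratified hypergeometric with margins (N, n_U, n_D)."""
        res = scan_pairs(small_null_corpus, UPDP, k=2, n_bins=1, emit_all=True, alpha=1.0)
        full = res.full
        n_U, n_D, k_a = full["n_U"], full["n_D"], full["k_a"]
        np.testing.assert_array_equal(full["nD_adj"], np.broadcast_to(n_D, full["nD_adj"].shape))
        i, j = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        ref = stats.hypergeom.sf(k_a - 1, res.N, n_D[j], n_U[i])
        mask = (n_U[i] > 0) & (n_D[j] > 0)
        np.testing.assert_allclose(full["p_upper"][mask], ref[mask], rtol=1e-9)

    def test_planted_pair_is_significant(self, planted_corpus):
        corpus, truth = planted_corpus
        res = scan_pairs(corpus, UPDP, k=5)
        assert ("TCCCT", "GGAGG") in res.significant_pairs()
        top = res.table.iloc[0]
        assert (top["motif_u"], top["motif_d"]) == ("TCCCT", "GGAGG")
        assert top["direction"] == "enriched"

    def test_scan_deterministic(self, small_null_corpus):
        r1 = scan_pairs(small_null_corpus, UPDP, k=2, n_bins=4)
        r2 = scan_pairs(small_null_corpus, UPDP, k=2, n_bins=4)
        assert r1.table.equals(r2.table)

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            scan_pairs([], UPDP, k=2)

    def test_adjust_up_and_both_similar(self, planted_corpus):
        """Adjusting the other margin (or both) gives the same discovery."""
        corpus, _ = planted_corpus
        for adjust in ("up", "both"):
            res = scan_pairs(corpus, UPDP, k=5, adjust=adjust)
            assert ("TCCCT", "GGAGG") in res.significant_pairs()


class TestCrossRegion:
    def test_defining_region_consistency_and_specificity(self):
        cfg = CorpusConfig(
            n_exons=1500, seed=42,
            planted=(PlantedPair("TACGT", "CGTAC", "UpDp", 0.25, 0.02, 0.02),),
        )
        corpus, _ = generate_corpus(cfg)
        res = scan_pairs(corpus, UPDP, k=5, emit_all=True)
        pair = ("TACGT", "CGTAC")
        assert pair in res.significant_pairs()
        df = cross_region_pvalues([pair], corpus, UPDP, [UDDD], n_bins=20)
        here = df[df["region_pair"] == "UpDp"].iloc[0]
        there = df[df["region_pair"] == "UdDd"].iloc[0]
        assert here["p_upper"] == pytest.approx(res.pvalue(*pair), rel=1e-9)
        assert there["p_upper"] > default_alpha(5)
        # comparability flag follows the factor-of-two rule on expected counts
        ratio = there["k_prime"] / here["k_prime"]
        assert bool(there["within_factor_two"]) == (0.5 <= ratio <= 2.0)
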