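import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islescan import ld
from islescan.types import MISSING, make_feature_table

from conftest import tiny_matrix


class TestPairwiseR2:
    def test_self_is_one(self):
        G = tiny_matrix(np.array([[0, 0], [1, 1], [2, 2]]))
        assert ld.pairwise_r2(G, "mk0", "mk0") == pytest.approx(1.0)

    def test_perfect_negative_correlation_squares_to_one(self):
        G = tiny_matrix(np.array([[0, 2], [0, 2], [1, 1], [1, 1], [2, 0], [2, 0]]))
        assert ld.pairwise_r2(G, "mk0", "mk1") == pytest.approx(1.0)

    def test_independent_markers_near_reciprocal_n(self):
        rng = np.random.default_rng(0)
        vals = rng.binomial(2, 0.5, size=(200, 400)).astype(np.int8)
        G = tiny_matrix(vals, pos=list(range(1, 401)))
        r2s = [
            ld.pairwise_r2(G, f"mk{2 * i}", f"mk{2 * i + 1}") for i in range(200)
        ]
        assert np.mean(r2s) < 0.02

    def test_monomorphic_marker_undefined(self):
        G = tiny_matrix(np.array([[0, 1], [0, 2], [0, 0]]))
        assert np.isnan(ld.pairwise_r2(G, "mk0", "mk1"))

    def test_pairwise_complete_ignores_missing(self):
        x = np.array([0, 1, 2, MISSING, 2], dtype=np.int8)
        y = np.array([0, 1, 2, 0, MISSING], dtype=np.int8)
        G = tiny_matrix(np.column_stack([x, y]))
        assert ld.pairwise_r2(G, "mk0", "mk1") == pytest.approx(1.0)


class TestHillRobertson:
    @pytest.mark.parametrize(
        "r2,n,want",
        [(0.01, 100, 0.0), (1.0, 100, 1.0), (0.5, 100, 49 / 99)],
    )
    def test_reference_values(self, r2, n, want):
        assert ld.hill_robertson_correct(r2, n) == pytest.approx(want, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ld.hill_robertson_correct(0.5, 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.integers(2, 10_000))
    def test_correction_never_exceeds_input(self, r2, n):
        assert ld.hill_robertson_correct(r2, n) <= r2 + 1e-12


class TestLDScores:
    def test_isolated_marker_scores_one(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
        G = tiny_matrix(vals, pos=[1, 10_000_000])
        scores = ld.ld_scores(G, 500_000)
        np.testing.assert_allclose(scores["score"], 1.0)

    def test_duplicate_neighbor_scores_two(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        G = tiny_matrix(np.hstack([col, col]), pos=[1000, 2000])
        scores = ld.ld_scores(G, 500_000)
        np.testing.assert_allclose(scores["score"], 2.0)

    def test_triplet_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 3, size=(80, 3)).astype(np.int8)
        G = tiny_matrix(vals, pos=[1, 100_001, 200_001])
        scores = ld.ld_scores(G, 500_000)
        r01 = ld.pairwise_r2(G, "mk0", "mk1")
        r02 = ld.pairwise_r2(G, "mk0", "mk2")
        r12 = ld.pairwise_r2(G, "mk1", "mk2")
        want = [1 + r01 + r02, 1 + r01 + r12, 1 + r02 + r12]
        np.testing.assert_allclose(scores["score"], want, atol=1e-12)

    def test_window_is_centered_half_width_each_side(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        # neighbor at 260 kb: outside a 500 kb centered window (250 kb half)
        G = tiny_matrix(np.hstack([col, col]), pos=[1, 260_001])
        scores = ld.ld_scores(G, 500_000)
        np.testing.assert_allclose(scores["score"], 1.0)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = ld.wilcoxon_rank_sum(a, a)
        assert p == pytest.approx(1.0)

    def test_fully_separated_exact_enumeration(self):
        _, p = ld.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_invariance_to_monotone_shift(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1, size=40)
        s1, p1 = ld.wilcoxon_rank_sum(a, b)
        s2, p2 = ld.wilcoxon_rank_sum(a + 100, b + 100)
        assert (s1, p1) == (s2, p2)


class TestFitLDDecay:
    def _pairs(self, d, y):
        return pd.DataFrame(
            {
                "marker_i": "a", "marker_j": "b", "distance_kb": d,
                "r2": y, "r2_corrected": y, "n_haplotypes": 200,
            }
        )

    def test_noiseless_exact_recovery(self):
        d = np.linspace(10, 2500, 300)
        y = 1 / (1 + 4 * 0.10 * d)
        fit = ld.fit_ld_decay(self._pairs(d, y))
        assert fit.beta == pytest.approx(0.10, abs=1e-8)

    def test_scale_consistency(self):
        d = np.linspace(10, 2000, 200)
        y = 1 / (1 + 4 * 0.25 * d)
        f1 = ld.fit_ld_decay(self._pairs(d, y), max_distance_kb=1e9)
        f2 = ld.fit_ld_decay(self._pairs(d * 2, y), max_distance_kb=1e9)
        assert f2.beta == pytest.approx(f1.beta / 2, rel=1e-6)

    def test_model_value_at_zero_distance_is_one(self):
        assert ld.sved_curve(0.0, 0.7) == pytest.approx(1.0)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            beta = rng.uniform(5e-3, 0.9)
            d = np.sort(rng.uniform(5, 2400, 500))
            y = 1 / (1 + 4 * beta * d)
            fit = ld.fit_ld_decay(self._pairs(d, y))
            grid = np.geomspace(1e-4, 1, 2000)
            for _ in range(4):  # iteratively shrink the bracket
                sse = [np.sum((1 / (1 + 4 * b * d) - y) ** 2) for b in grid]
                i0 = int(np.argmin(sse))
                lo = grid[max(i0 - 1, 0)]
                hi = grid[min(i0 + 1, len(grid) - 1)]
                grid = np.linspace(lo, hi, 200)
            oracle = grid[int(np.argmin([np.sum((1 / (1 + 4 * b * d) - y) ** 2)
                                         for b in grid]))]
            assert fit.beta == pytest.approx(oracle, abs=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ld.fit_ld_decay(self._pairs(np.arange(1, 6), np.full(5, 0.5)))

    def test_nonpositive_corrected_pairs_excluded(self):
        d = np.linspace(10, 2500, 100)
        y = 1 / (1 + 0.4 * d)
        pairs = self._pairs(np.concatenate([d, [50, 60]]),
                            np.concatenate([y, [0.0, -0.2]]))
        fit = ld.fit_ld_decay(pairs)
        assert fit.n_pairs == 100


class TestMedianScoreOrdering:
    def test_median_ld_score_tracks_decay_rate(self):
        """A population simulated with slower LD decay (smaller beta) has the
        larger median LD score."""
        from islescan.sim import SimConfig, simulate_dataset

        medians = {}
        for beta in (0.05, 0.4):
            cfg = SimConfig(
                n_pop1=100, n_pop2=10, n_chromosomes=2,
                markers_per_chromosome=1000, chrom_length_bp=25_000_000,
                fst_background=0.05, selected_loci=[], missing_rate=0.0,
                n_planted_relative_pairs=0, ld_beta=beta, seed=31,
            )
            geno, _, samples, _ = simulate_dataset(cfg)
            sub = geno.take_samples(
                np.flatnonzero(samples["origin"].to_numpy() == "mainland")
            )
            medians[beta] = float(ld.ld_scores(sub, 500_000)["score"].median())
        assert medians[0.05] > medians[0.4]


class TestPairsWithinGenes:
    def _gene_table(self):
        return make_feature_table(
            ["g1", "g2"], ["1", "1"], [100, 10_000], [1_000, 20_000],
            ["gene", "gene"], ["G1", "G2"],
        )

    def test_three_markers_in_gene_give_three_pairs(self):
        rng = np.random.default_rng(7)
        vals = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        G = tiny_matrix(vals, pos=[150, 500, 900, 15_000])
        pairs = ld.pairs_within_genes(G, self._gene_table())
        in_g1 = pairs[pairs["marker_i"].isin(["mk0", "mk1", "mk2"])]
        assert len(in_g1) == 3

    def test_markers_in_different_genes_do_not_pair(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(0, 3, size=(60, 2)).astype(np.int8)
        G = tiny_matrix(vals, pos=[500, 15_000])
        assert len(ld.pairs_within_genes(G, self._gene_table())) == 0

    def test_correction_is_elementwise_hill_robertson(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 3, size=(60, 3)).astype(np.int8)
        G = tiny_matrix(vals, pos=[150, 500, 900])
        pairs = ld.pairs_within_genes(G, self._gene_table())
        for row in pairs.itertuples(index=False):
            want = ld.hill_robertson_correct(row.r2, row.n_haplotypes)
            assert row.r2_corrected == pytest.approx(want, abs=1e-12)
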