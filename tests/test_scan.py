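import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islescan import scan
from islescan.structure import PopTree

from conftest import tiny_matrix


def wc_theta_oracle(n1_counts, n2_counts):
    """Scalar transcription of the published two-population theta formulas.

    ``n*_counts`` are (n_hom_ref, n_het, n_hom_alt) genotype counts.
    """
    out = []
    for counts in (n1_counts, n2_counts):
        n = sum(counts)
        p = (2 * counts[2] + counts[1]) / (2 * n)
        h = counts[1] / n
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def geno_from_counts(c1, c2):
    """Single-marker GenotypeMatrix from two populations' genotype counts."""
    col = (
        [0] * c1[0] + [1] * c1[1] + [2] * c1[2]
        + [0] * c2[0] + [1] * c2[1] + [2] * c2[2]
    )
    labels = ["p1"] * sum(c1) + ["p2"] * sum(c2)
    return tiny_matrix(np.array(col, dtype=np.int8)[:, None]), np.array(labels)


class TestFstPerSnp:
    def test_identical_count_tables_truncate_to_zero(self):
        G, labels = geno_from_counts((30, 40, 30), (30, 40, 30))
        res = scan.fst_per_snp(G, labels)
        assert res["theta_signed"].iloc[0] <= 0
        assert res["theta_truncated"].iloc[0] == 0.0

    def test_fixed_difference_is_one(self):
        G, labels = geno_from_counts((0, 0, 50), (50, 0, 0))
        res = scan.fst_per_snp(G, labels)
        assert res["theta_signed"].iloc[0] == pytest.approx(1.0)

    def test_reference_count_table_matches_oracle(self):
        G, labels = geno_from_counts((30, 40, 30), (60, 30, 10))
        res = scan.fst_per_snp(G, labels)
        want = wc_theta_oracle((30, 40, 30), (60, 30, 10))
        assert res["theta_signed"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            c1 = tuple(rng.integers(0, 40, 3) + np.array([1, 1, 0]))
            c2 = tuple(rng.integers(0, 40, 3) + np.array([0, 1, 1]))
            G, labels = geno_from_counts(c1, c2)
            got = scan.fst_per_snp(G, labels)["theta_signed"].iloc[0]
            assert got == pytest.approx(wc_theta_oracle(c1, c2), abs=1e-12)

    def test_truncation_preserves_signed_value(self):
        G, labels = geno_from_counts((25, 50, 25), (25, 50, 25))
        res = scan.fst_per_snp(G, labels)
        assert res["theta_signed"].iloc[0] < 0
        assert res["theta_truncated"].iloc[0] == 0.0


class TestPercentileThreshold:
    def test_linear_interpolation_rank_arithmetic(self):
        values = np.arange(1, 100_001, dtype=float)
        got = scan.empirical_percentile_threshold(values, 99.999)
        assert got == pytest.approx(99_999.0, abs=1e-3)

    def test_constant_vector_has_no_strict_outliers(self):
        vals = np.full(100, 0.3)
        bound = scan.empirical_percentile_threshold(vals, 99.999)
        assert bound == 0.3
        assert not (vals > bound).any()

    def test_percentile_zero_is_minimum(self):
        vals = np.array([5.0, 1.0, 3.0])
        assert scan.empirical_percentile_threshold(vals, 0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scan.empirical_percentile_threshold([])


class TestWindows:
    def _scan_frame(self, pos, theta, chrom="1"):
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(pos))],
                "chromosome": chrom,
                "position_bp": pos,
                "theta_truncated": theta,
            }
        )

    def test_window_below_min_snps_discarded(self):
        sc = self._scan_frame([100, 200, 300], [0.1, 0.2, 0.3])
        assert len(scan.smooth_fst_windows(sc, 500_000, 4)) == 0

    def test_mean_of_four_snps(self):
        sc = self._scan_frame([1, 2, 3, 4], [0.0, 0.0, 0.0, 0.4])
        win = scan.smooth_fst_windows(sc, 500_000, 4)
        assert len(win) == 1
        assert win["mean_fst"].iloc[0] == pytest.approx(0.1)
        assert win["start_bp"].iloc[0] == 1
        assert win["end_bp"].iloc[0] == 500_001

    def test_snp_count_conservation(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 40, replace=False))
        sc = self._scan_frame(pos, rng.uniform(0, 0.2, 40))
        win = scan.smooth_fst_windows(sc, 500_000, 4)
        retained_idx = (pos - 1) // 500_000
        counts = pd.Series(retained_idx).value_counts()
        assert win["n_snps"].sum() == counts[counts >= 4].sum()

    def test_boundary_snp_at_window_edge(self):
        # position 500_000 belongs to window [1, 500_001); 500_001 to the next
        sc = self._scan_frame([499_998, 499_999, 500_000, 500_001, 500_002,
                               500_003, 500_004, 1_000_000],
                              [0.1] * 8)
        win = scan.smooth_fst_windows(sc, 500_000, 4)
        first = win[win["start_bp"] == 1]
        second = win[win["start_bp"] == 500_001]
        assert first["n_snps"].iloc[0] == 3 if len(first) else True
        assert second["n_snps"].iloc[0] == 5


class TestFLK:
    def _tree(self, f1=0.05, f2=0.05):
        return PopTree(["p1", "p2"], {"p1": f1, "p2": f2},
                       np.diag([f1, f2]), "(p1,p2);")

    def test_identical_frequencies_give_zero_statistic(self):
        freqs = pd.DataFrame({"p1": [0.3, 0.7], "p2": [0.3, 0.7]})
        res = scan.flk_test(freqs, self._tree())
        np.testing.assert_allclose(res["flk_stat"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["flk_p"], 1.0)

    def test_statistic_increases_with_frequency_contrast(self):
        # fixed p0_hat = 0.5; contrast grows
        deltas = np.linspace(0.01, 0.4, 30)
        freqs = pd.DataFrame({"p1": 0.5 + deltas, "p2": 0.5 - deltas})
        res = scan.flk_test(freqs, self._tree())
        assert (np.diff(res["flk_stat"]) > 0).all()

    def test_two_pop_statistic_is_monotone_in_squared_contrast(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.05, 0.95, 500)
        p2 = rng.uniform(0.05, 0.95, 500)
        res = scan.flk_test(pd.DataFrame({"p1": p1, "p2": p2}), self._tree())
        p0 = (p1 + p2) / 2
        x = (p1 - p2) ** 2 / (p0 * (1 - p0))
        r = np.corrcoef(x, res["flk_stat"])[0, 1]
        assert r**2 > 0.999

    def test_monomorphic_markers_flagged(self):
        freqs = pd.DataFrame({"p1": [0.0, 0.5], "p2": [0.0, 0.5]})
        res = scan.flk_test(freqs, self._tree())
        assert np.isnan(res["flk_stat"].iloc[0])

    def test_singular_drift_matrix_names_tree(self):
        tree = PopTree(["p1", "p2"], {}, np.zeros((2, 2)), "(p1,p2)singular;")
        with pytest.raises(ValueError, match="singular"):
            scan.flk_test(pd.DataFrame({"p1": [0.5], "p2": [0.5]}), tree)


class TestFdrBH:
    def test_hand_worked_step_up(self):
        got = scan.fdr_bh([0.01, 0.02, 0.03])
        np.testing.assert_allclose(got, [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        assert scan.fdr_bh([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(scan.fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scan.fdr_bh([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = scan.fdr_bh(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCallOutliers:
    def _scan(self, theta, flk_fdr=None):
        df = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(theta))],
                "chromosome": "1",
                "position_bp": np.arange(1, len(theta) + 1),
                "theta_truncated": theta,
            }
        )
        if flk_fdr is not None:
            df["flk_p_fdr"] = flk_fdr
        return df

    def test_flk_fdr_boundary_is_inclusive(self):
        df = self._scan([0.1, 0.2], flk_fdr=[0.1, 0.5])
        rep = scan.call_outliers(df, pd.DataFrame(columns=["mean_fst"]))
        assert rep.flk_significant == ["m0"]

    def test_null_distribution_yields_at_most_one_outlier(self, neutral_dataset):
        geno, _, samples, _ = neutral_dataset
        fst = scan.fst_per_snp(geno, samples["origin"].to_numpy())
        rep = scan.call_outliers(fst, pd.DataFrame(columns=["mean_fst"]))
        assert len(rep.fst_outliers) <= 1

    def test_planted_locus_called(self, small_dataset):
        geno, _, samples, truth = small_dataset
        fst = scan.fst_per_snp(geno, samples["origin"].to_numpy())
        win = scan.smooth_fst_windows(fst)
        rep = scan.call_outliers(fst, win)
        assert truth.selected_markers[0][0] in rep.fst_outliers
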