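from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islescan import qc
from islescan.types import MISSING

from conftest import tiny_matrix


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration of the conditional HWE test."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    rare = min(na, 2 * n - na)
    if rare == 0:
        return 1.0
    probs = {}
    total = Fraction(0)
    for h in range(rare % 2, rare + 1, 2):
        aa = (na - h) // 2
        bb = n - h - aa
        w = Fraction(2**h) * Fraction(
            comb(n, aa) * comb(n - aa, h)
        )
        probs[h] = w
        total += w
    obs = probs[n_ab]
    acc = sum(w for w in probs.values() if w <= obs)
    return float(Fraction(acc, total))


class TestSampleCallRate:
    def test_boundary_and_vacuous_threshold(self):
        vals = np.zeros((3, 100), dtype=np.int8)
        vals[1, :6] = MISSING   # call rate 0.94 -> excluded at 0.95
        vals[2, :5] = MISSING   # call rate 0.95 -> kept (>= threshold)
        G = tiny_matrix(vals)
        kept, excluded = qc.sample_call_rate_filter(G, 0.95)
        assert excluded == ["s1"]
        assert kept.sample_ids == ["s0", "s2"]
        kept0, excluded0 = qc.sample_call_rate_filter(G, 0.0)
        assert excluded0 == []

    def test_all_removed_is_an_error(self):
        vals = np.full((2, 10), MISSING, dtype=np.int8)
        vals[:, 0] = 1
        with pytest.raises(ValueError, match="threshold"):
            qc.sample_call_rate_filter(tiny_matrix(vals), 0.99)


class TestPihat:
    def test_duplicated_sample_near_one(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, rng.uniform(0.1, 0.9, 5000), size=(4, 5000))
        vals = np.vstack([base, base[0]]).astype(np.int8)
        pihat = qc.estimate_pihat(tiny_matrix(vals))
        assert pihat.iloc[0, 4] >= 0.95

    def test_unrelated_pair_near_zero(self, neutral_dataset):
        geno, _, samples, truth = neutral_dataset
        # two independent samples from the mainland population
        sub = geno.take_samples([0, 1] + list(range(2, 40)))
        pihat = qc.estimate_pihat(sub)
        assert abs(pihat.iloc[0, 1]) < 0.05 + 0.0

    def test_planted_parent_offspring_near_half(self, small_dataset):
        geno, _, _, truth = small_dataset
        pihat = qc.estimate_pihat(geno)
        for a, b in truth.relative_pairs:
            assert abs(pihat.loc[a, b] - 0.5) < 0.1

    def test_monomorphic_only_input_rejected(self):
        vals = np.zeros((3, 10), dtype=np.int8)
        with pytest.raises(ValueError, match="polymorphic"):
            qc.estimate_pihat(tiny_matrix(vals))


class TestPruneRelated:
    def _mat(self, ids, pairs):
        df = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
        np.fill_diagonal(df.values, 1.0)
        for a, b, v in pairs:
            df.loc[a, b] = df.loc[b, a] = v
        return df

    def test_no_offending_pair_keeps_everyone(self):
        m = self._mat(["a", "b", "c"], [("a", "b", 0.2)])
        assert qc.prune_related(m, 0.25) == ["a", "b", "c"]

    def test_tied_pair_removes_exactly_one(self):
        m = self._mat(["a", "b"], [("a", "b", 0.5)])
        kept = qc.prune_related(m, 0.25)
        assert len(kept) == 1

    def test_star_removes_only_hub(self):
        ids = ["hub", "x", "y", "z"]
        m = self._mat(ids, [("hub", p, 0.5) for p in "xyz"])
        assert qc.prune_related(m, 0.25) == ["x", "y", "z"]

    def test_lower_call_rate_removed_first_on_tie(self):
        m = self._mat(["a", "b"], [("a", "b", 0.5)])
        kept = qc.prune_related(m, 0.25, call_rates={"a": 0.99, "b": 0.97})
        assert kept == ["a"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_result_never_contains_offending_pair(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        raw = rng.uniform(0, 0.6, (n, n))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 1.0)
        ids = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(sym, index=ids, columns=ids)
        kept = qc.prune_related(df, 0.25)
        sub = df.loc[kept, kept].to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert (sub <= 0.25).all()


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts,check",
        [
            ((25, 50, 25), lambda p: p >= 0.99),
            ((100, 0, 0), lambda p: p == 1.0),
            ((50, 0, 50), lambda p: p < 1e-5),
        ],
    )
    def test_reference_configurations(self, counts, check):
        assert check(qc.hwe_exact_test(*counts))

    def test_exhaustive_agreement_with_rational_oracle_up_to_n30(self):
        for n in range(1, 31):
            for n_ab in range(n + 1):
                for n_aa in range(n - n_ab + 1):
                    n_bb = n - n_ab - n_aa
                    got = qc.hwe_exact_test(n_aa, n_ab, n_bb)
                    want = hwe_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-12), (n_aa, n_ab, n_bb)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 0, 1)


class TestMarkerQC:
    def test_maf_boundary_is_strict_lower_than(self):
        # 100 samples; marker 0 has MAF 0.049 (excluded), marker 1 has 0.050
        rng = np.random.default_rng(1)
        vals = np.zeros((1000, 2), dtype=np.int8)
        vals[:98, 0] = 1   # freq 98/2000 = 0.049
        vals[:100, 1] = 1  # freq 0.050
        G = tiny_matrix(vals)
        kept, report = qc.marker_qc(G, callrate_min=0.0, maf_min=0.05, hwe_alpha=0.0)
        assert kept.markers["marker_id"].tolist() == ["mk1"]
        assert report.n_markers_excluded_maf == 1

    def test_precedence_counts_marker_once(self):
        vals = np.zeros((100, 1), dtype=np.int8)
        vals[:60, 0] = MISSING  # call rate 0.4 AND maf 0 -> counted under call rate
        vals[60, 0] = 1
        G = tiny_matrix(np.hstack([vals, np.tile([[0], [1]], (50, 1))]))
        kept, report = qc.marker_qc(G, callrate_min=0.95, maf_min=0.05, hwe_alpha=0.0)
        assert report.n_markers_excluded_callrate == 1
        assert report.n_markers_excluded_maf == 0

    def test_nonautosomal_dropped_first_and_conservation(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 3, size=(60, 5)).astype(np.int8)
        G = tiny_matrix(vals, chrom=["1", "X", "2", "26", "27"],
                        pos=[1, 2, 3, 4, 5])
        kept, report = qc.marker_qc(G, callrate_min=0.0, maf_min=0.0, hwe_alpha=0.0)
        assert report.n_markers_excluded_nonautosomal == 2
        assert report.n_markers_in - report.n_markers_excluded == report.n_markers_out
        assert set(kept.markers["chromosome"]) <= {"1", "2", "26"}


class TestLDPrune:
    def test_duplicate_markers_one_survives(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        other = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        G = tiny_matrix(np.hstack([col, col, other]), pos=[10, 20, 30])
        kept = qc.ld_prune(G)
        assert len([k for k in kept if k in ("mk0", "mk1")]) == 1
        assert "mk2" in kept

    def test_uncorrelated_markers_all_kept(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        G = tiny_matrix(vals, pos=list(range(1, 21)))
        assert qc.ld_prune(G) == G.markers["marker_id"].tolist()

    def test_no_surviving_pair_exceeds_bound_brute_force(self, neutral_dataset):
        geno, _, _, _ = neutral_dataset
        block = geno.take_markers(np.arange(60))
        kept = qc.ld_prune(block, window_snps=50, step_snps=5, r2_max=0.5)
        idx = [block.marker_index(k) for k in kept]
        # exhaustive post-check over every surviving intra-window pair
        for wstart in range(0, len(idx), 5):
            window = [j for j in idx if wstart <= idx.index(j) < wstart + 50]
            for x in range(len(window)):
                for y in range(x + 1, len(window)):
                    if abs(idx.index(window[y]) - idx.index(window[x])) < 50:
                        r2 = qc._r2_pair(
                            block.values[:, window[x]], block.values[:, window[y]]
                        )
                        assert not (np.isfinite(r2) and r2 > 0.5)
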