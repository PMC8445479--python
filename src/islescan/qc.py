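"""Sample- and marker-level quality control with an auditable report.

Filter precedence is fixed so the exclusion breakdown is reproducible:
samples by call rate, then relatedness pruning; markers by autosome
membership, then call rate, then MAF, then Hardy-Weinberg, with LD pruning
as a separate final step.  A marker is attributed to the first criterion it
fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import AUTOSOMES, MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Exclusion accounting; ``n_in - n_excluded = n_out`` on both axes."""

    n_samples_in: int = 0
    n_samples_excluded_callrate: int = 0
    n_samples_excluded_ibd: int = 0
    n_markers_in: int = 0
    n_markers_excluded_nonautosomal: int = 0
    n_markers_excluded_callrate: int = 0
    n_markers_excluded_maf: int = 0
    n_markers_excluded_hwe: int = 0
    n_markers_excluded_ldprune: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_samples_out(self) -> int:
        return (
            self.n_samples_in
            - self.n_samples_excluded_callrate
            - self.n_samples_excluded_ibd
        )

    @property
    def n_markers_excluded(self) -> int:
        return (
            self.n_markers_excluded_nonautosomal
            + self.n_markers_excluded_callrate
            + self.n_markers_excluded_maf
            + self.n_markers_excluded_hwe
            + self.n_markers_excluded_ldprune
        )

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - self.n_markers_excluded

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_excluded_callrate", self.n_samples_excluded_callrate),
            ("samples_excluded_ibd", self.n_samples_excluded_ibd),
            ("samples_out", self.n_samples_out),
            ("markers_in", self.n_markers_in),
            ("markers_excluded_nonautosomal", self.n_markers_excluded_nonautosomal),
            ("markers_excluded_callrate", self.n_markers_excluded_callrate),
            ("markers_excluded_maf", self.n_markers_excluded_maf),
            ("markers_excluded_hwe", self.n_markers_excluded_hwe),
            ("markers_excluded_ldprune", self.n_markers_excluded_ldprune),
            ("markers_excluded_total", self.n_markers_excluded),
            ("markers_out", self.n_markers_out),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])


def sample_call_rates(G: GenotypeMatrix) -> np.ndarray:
    return (G.values != MISSING).mean(axis=1)


def sample_call_rate_filter(G: GenotypeMatrix, threshold: float = 0.95):
    """Remove samples whose fraction of non-missing calls is below threshold."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    rates = sample_call_rates(G)
    keep = rates >= threshold
    if not keep.any():
        raise ValueError(
            "sample call-rate filter removed every sample; review the threshold"
        )
    excluded = [s for s, k in zip(G.sample_ids, keep) if not k]
    return G.take_samples(np.flatnonzero(keep)), excluded


def _allele_freqs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker frequency of allele_b and number of genotyped samples."""
    called = values != MISSING
    n = called.sum(axis=0)
    dose = np.where(called, values, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dose / (2 * n), np.nan)
    return p, n


def estimate_pihat(G: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments IBD estimates per sample pair (PLINK --genome style).

    For each pair, loci are classed by identity-by-state (0/1/2 shared
    alleles); expected class totals under IBD states 0/1/2, computed from
    sample allele frequencies, are inverted for P(IBD=k) and
    ``pihat = P(IBD=1)/2 + P(IBD=2)``, clipped to [0, 1].  Returns a
    symmetric matrix as a DataFrame indexed by sample id (diagonal 1).
    """
    X = G.values
    n_s = G.n_samples
    if n_s < 2:
        raise ValueError("need at least 2 samples")
    p, _ = _allele_freqs(X)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no informative (polymorphic) markers")
    X = X[:, poly]
    p = p[poly]
    q = 1 - p

    called = (X != MISSING).astype(np.float64)
    Xf = np.where(X == MISSING, 0, X).astype(np.float64)

    # Expected IBS-class probabilities per locus given IBD state
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd1 = 2 * p * q
    e2_ibd1 = p**2 + q**2

    # Pairwise IBS counts via indicator matmuls (missing excluded).
    ind = [(np.isclose(Xf, d) & (called > 0)).astype(np.float64) for d in (0, 1, 2)]
    both = called @ called.T  # loci called in both
    # IBS0: one hom 0, other hom 2
    ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    # IBS2: same genotype class
    ibs2 = sum(a @ a.T for a in ind)
    ibs1 = both - ibs0 - ibs2

    # Per-pair expectations must be restricted to jointly called loci; with
    # i.i.d. missingness we use the frequency-weighted totals scaled by the
    # jointly-called fraction.
    m_used = p.size
    s0_0, s1_0, s2_0 = e0_ibd0.sum(), e1_ibd0.sum(), e2_ibd0.sum()
    s1_1, s2_1 = e1_ibd1.sum(), e2_ibd1.sum()
    frac = both / m_used

    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = ibs0 / (s0_0 * frac)
        z1 = (ibs1 - z0 * s1_0 * frac) / (s1_1 * frac)
        z2 = (ibs2 - z0 * s2_0 * frac - z1 * s2_1 * frac) / both
    z0, z1, z2 = (np.clip(z, 0, 1) for z in (z0, z1, z2))
    total = z0 + z1 + z2
    total[total == 0] = 1.0
    pihat = np.clip((z1 / 2 + z2) / total, 0, 1)
    np.fill_diagonal(pihat, 1.0)
    pihat = (pihat + pihat.T) / 2
    return pd.DataFrame(pihat, index=G.sample_ids, columns=G.sample_ids)


def prune_related(
    pihat: pd.DataFrame, threshold: float = 0.25, call_rates: dict | None = None
) -> list[str]:
    """Greedy removal of related samples until no pair exceeds threshold.

    Repeatedly removes the sample in the most offending pairs; ties broken
    by lower call rate first, then lexicographic sample id.  Returns the
    kept ids in the input order.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    ids = list(pihat.index)
    cr = call_rates or {}
    mat = pihat.to_numpy().copy()
    np.fill_diagonal(mat, 0.0)
    active = dict.fromkeys(range(len(ids)), True)
    while True:
        act = [i for i, a in active.items() if a]
        sub = mat[np.ix_(act, act)]
        offend = sub > threshold
        deg = offend.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        worst = max(
            range(len(act)),
            key=lambda k: (deg[k], -cr.get(ids[act[k]], 1.0), ids[act[k]]),
        )
        active[act[worst]] = False
    return [ids[i] for i, a in active.items() if a]


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the conditional probabilities that do not exceed the
    observed configuration's.
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("genotype counts must be non-negative with sum >= 1")
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # copies of allele a
    rare = min(na, 2 * n - na)
    if rare == 0:
        return 1.0
    het_values = np.arange(rare % 2, rare + 1, 2)
    # P(n_ab = h | allele counts) ∝ n! / (naa! nab! nbb!) * 2^h
    hom_a = (na - het_values) // 2
    hom_b = n - het_values - hom_a
    logp = (
        het_values * np.log(2)
        - gammaln(hom_a + 1)
        - gammaln(het_values + 1)
        - gammaln(hom_b + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(het_values == n_ab)[0]]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def genotype_counts(values: np.ndarray) -> np.ndarray:
    """(m, 3) counts of dosages 0/1/2 per marker."""
    out = np.empty((values.shape[1], 3), dtype=np.int64)
    for d in (0, 1, 2):
        out[:, d] = (values == d).sum(axis=0)
    return out


def marker_qc(
    G: GenotypeMatrix,
    callrate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-5,
    autosomes: tuple[str, ...] = AUTOSOMES,
) -> tuple[GenotypeMatrix, QCReport]:
    """Marker filters: autosome -> call rate -> MAF -> HWE (fixed precedence)."""
    report = QCReport(
        n_samples_in=G.n_samples,
        n_markers_in=G.n_markers,
        thresholds={
            "marker_callrate_min": callrate_min,
            "maf_min": maf_min,
            "hwe_alpha": hwe_alpha,
        },
    )
    chrom = G.markers["chromosome"].to_numpy()
    autosomal = np.isin(chrom, autosomes)
    report.n_markers_excluded_nonautosomal = int((~autosomal).sum())

    called = (G.values != MISSING).mean(axis=0)
    callrate_ok = called >= callrate_min
    fail_cr = autosomal & ~callrate_ok
    report.n_markers_excluded_callrate = int(fail_cr.sum())

    p, n = _allele_freqs(G.values)
    maf = np.fmin(p, 1 - p)
    maf_ok = maf >= maf_min
    fail_maf = autosomal & callrate_ok & ~maf_ok
    report.n_markers_excluded_maf = int(fail_maf.sum())

    candidates = np.flatnonzero(autosomal & callrate_ok & maf_ok)
    counts = genotype_counts(G.values[:, candidates])
    hwe_ok = np.array(
        [hwe_exact_test(*row) >= hwe_alpha for row in counts], dtype=bool
    )
    report.n_markers_excluded_hwe = int((~hwe_ok).sum())

    keep = candidates[hwe_ok]
    if keep.size == 0:
        raise ValueError("marker QC removed every marker; review the thresholds")
    return G.take_markers(keep), report


def pairwise_r2_matrix(values: np.ndarray) -> np.ndarray:
    """Squared pairwise-complete Pearson correlation of dosage columns.

    Vectorized with masked moment sums; columns with fewer than 2 jointly
    called samples or zero variance give NaN.
    """
    X = values.astype(np.float64)
    C = (values != MISSING).astype(np.float64)
    X[C == 0] = 0.0
    n = C.T @ C
    sx = X.T @ C
    sxx = (X * X).T @ C
    sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_row = n * sxx - sx**2
        denom = var_row * var_row.T
        out = np.where((n >= 2) & (denom > 0), cov * cov / denom, np.nan)
    return out


def _r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(
    G: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.50,
) -> list[str]:
    """PLINK ``--indep-pairwise`` style LD pruning; returns kept marker ids.

    Within each sliding window, while any kept pair has r² above the bound,
    the member with the lower MAF is dropped (ties: the later position).
    """
    chrom = G.markers["chromosome"].to_numpy()
    ids = G.markers["marker_id"].to_numpy()
    p, _ = _allele_freqs(G.values)
    maf = np.fmin(p, 1 - p)
    keep = np.ones(G.n_markers, dtype=bool)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while True:
            win = idx[start : start + window_snps]
            if win.size >= 2:
                _prune_window(G.values, win, keep, maf, r2_max)
            if start + window_snps >= idx.size:
                break
            start += step_snps
    return ids[keep].tolist()


def _prune_window(values, win, keep, maf, r2_max) -> None:
    active = [j for j in win if keep[j]]
    if len(active) < 2:
        return
    # pairwise r2 does not change as markers are removed: compute once
    r2 = pairwise_r2_matrix(values[:, active])
    local = {j: i for i, j in enumerate(active)}
    changed = True
    while changed and len(active) >= 2:
        changed = False
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                r = r2[local[a], local[b]]
                if np.isnan(r) or r <= r2_max:
                    continue
                # drop lower MAF; tie -> later position (b is later)
                drop = b if maf[a] > maf[b] or np.isclose(maf[a], maf[b]) else a
                keep[drop] = False
                active.remove(drop)
                changed = True
                break
            if changed:
                break
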