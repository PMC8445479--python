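"""Per-SNP and windowed F_ST scans with empirical outlier calling, and FLK.

F_ST is the Weir-Cockerham (1984) theta-hat computed per marker from the
two-population genotype counts (variance components a, b, c, with observed
heterozygosity entering b and c).  Negative estimates carry no biological
meaning and are truncated to zero for ranking and window averaging; the
signed estimate is kept for diagnostics.

FLK whitens population allele frequencies by the drift covariance F of the
population tree: with ``p0_hat = (1' F^-1 p) / (1' F^-1 1)``, the statistic
``T = (p - p0_hat 1)' F^-1 (p - p0_hat 1) / (p0_hat (1 - p0_hat))`` is
compared to a chi-square with npop - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .structure import PopTree
from .types import MISSING, GenotypeMatrix


def fst_per_snp(G: GenotypeMatrix, labels) -> pd.DataFrame:
    """Weir-Cockerham theta per marker for a two-population contrast.

    Returns a frame with ``theta_signed`` and ``theta_truncated`` (negative
    values set to 0); markers genotyped in fewer than 2 samples of either
    population get NaN.
    """
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, got {len(pops)}")
    ns, ps, hs = [], [], []
    for pop in pops:
        sub = G.values[labels == pop]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        dose = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, dose / (2 * n), np.nan)
            h = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        ns.append(n)
        ps.append(p)
        hs.append(h)
    theta = _wc_theta_two_pop(ns[0], ps[0], hs[0], ns[1], ps[1], hs[1])
    valid = (ns[0] >= 2) & (ns[1] >= 2)
    theta = np.where(valid, theta, np.nan)
    out = G.markers[["marker_id", "chromosome", "position_bp"]].copy()
    out["theta_signed"] = theta
    out["theta_truncated"] = np.where(np.isnan(theta), np.nan, np.clip(theta, 0, None))
    return out


def fst_overall(G: GenotypeMatrix, labels) -> float:
    """Multilocus Weir-Cockerham theta: ratio of summed variance components.

    This (not the mean of per-SNP ratios, which carries a Jensen-type bias)
    is the consistent genome-wide estimator of the drift parameter under the
    Balding-Nichols model.
    """
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, got {len(pops)}")
    comps = []
    for pop in pops:
        sub = G.values[labels == pop]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    a, b, c = _wc_components_two_pop(n1, p1, h1, n2, p2, h2)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (n1 >= 2) & (n2 >= 2)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def _wc_components_two_pop(n1, p1, h1, n2, p2, h2):
    """Vectorized Weir-Cockerham (1984) a/b/c variance components, r = 2."""
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def _wc_theta_two_pop(n1, p1, h1, n2, p2, h2) -> np.ndarray:
    """Per-marker Weir-Cockerham theta = a / (a + b + c), r = 2."""
    a, b, c = _wc_components_two_pop(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta


def empirical_percentile_threshold(values, percentile: float = 99.999) -> float:
    """Order-statistic percentile with linear interpolation between ranks."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite values")
    return float(np.percentile(arr, percentile, method="linear"))


def smooth_fst_windows(
    scan: pd.DataFrame,
    window_bp: int = 500_000,
    min_snps: int = 4,
) -> pd.DataFrame:
    """Mean truncated F_ST in non-overlapping windows tiled from position 1.

    Windows are half-open ``[k*window_bp + 1, (k+1)*window_bp + 1)`` per
    chromosome; windows holding fewer than ``min_snps`` markers are dropped.
    """
    rows = []
    for chrom, grp in scan.groupby("chromosome", sort=True):
        pos = grp["position_bp"].to_numpy()
        theta = grp["theta_truncated"].to_numpy()
        ok = np.isfinite(theta)
        pos, theta = pos[ok], theta[ok]
        if pos.size == 0:
            continue
        win_idx = (pos - 1) // window_bp
        for k in np.unique(win_idx):
            sel = win_idx == k
            n = int(sel.sum())
            if n < min_snps:
                continue
            rows.append(
                (
                    chrom,
                    int(k * window_bp + 1),
                    int((k + 1) * window_bp + 1),
                    n,
                    float(theta[sel].mean()),
                )
            )
    return pd.DataFrame(
        rows, columns=["chromosome", "start_bp", "end_bp", "n_snps", "mean_fst"]
    )


def flk_test(pop_freqs: pd.DataFrame, tree: PopTree) -> pd.DataFrame:
    """FLK neutrality statistic and chi-square p-value per marker.

    ``pop_freqs`` columns are population labels matching ``tree.leaves``.
    Markers whose estimated ancestral frequency falls outside (0, 1), or
    that are monomorphic across all populations, are flagged (NaN).
    """
    pops = tree.leaves
    P = pop_freqs[pops].to_numpy(dtype=float).T  # npop x m
    F = np.asarray(tree.kinship, dtype=float)
    npop = len(pops)
    if npop < 2:
        raise ValueError("FLK needs at least 2 populations")
    try:
        Finv = np.linalg.inv(F)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"singular drift matrix for tree {tree.newick!r}"
        ) from err
    one = np.ones(npop)
    w = Finv @ one
    denom_p0 = one @ w
    p0 = (w @ P) / denom_p0
    dev = P - p0[None, :]
    T = np.einsum("im,ij,jm->m", dev, Finv, dev)
    het = p0 * (1 - p0)
    valid = np.isfinite(P).all(axis=0) & (p0 > 0) & (p0 < 1)
    mono = np.all(P == P[0:1, :], axis=0) & np.all(np.isin(P, (0.0, 1.0)), axis=0)
    valid &= ~mono
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(valid, T / het, np.nan)
    pval = np.where(valid, stats.chi2.sf(stat, df=npop - 1), np.nan)
    return pd.DataFrame({"flk_stat": stat, "flk_p": pval})


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1).

    NaNs are passed through and do not count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class OutlierReport:
    fst_threshold: float
    window_threshold: float | None
    fst_outliers: list[str]
    window_outliers: pd.DataFrame
    flk_significant: list[str]
    joint_outliers: list[str]  # F_ST-percentile AND FLK-FDR agreement


def call_outliers(
    scan: pd.DataFrame,
    windows: pd.DataFrame,
    fst_percentile: float = 99.999,
    flk_fdr_max: float = 0.1,
) -> OutlierReport:
    """Empirical-percentile F_ST outliers, window outliers and FLK hits.

    Per-SNP outliers are strictly above the percentile bound of the
    truncated F_ST distribution; window outliers use the same percentile on
    window means; FLK significance is ``flk_p_fdr <= flk_fdr_max``
    (boundary inclusive).
    """
    theta = scan["theta_truncated"]
    bound = empirical_percentile_threshold(theta, fst_percentile)
    fst_out = scan.loc[theta > bound, "marker_id"].tolist()

    win_bound = None
    win_out = windows.iloc[0:0]
    if len(windows):
        win_bound = empirical_percentile_threshold(windows["mean_fst"], fst_percentile)
        win_out = windows[windows["mean_fst"] > win_bound].reset_index(drop=True)

    flk_sig: list[str] = []
    if "flk_p_fdr" in scan:
        flk_sig = scan.loc[scan["flk_p_fdr"] <= flk_fdr_max, "marker_id"].tolist()
    joint = sorted(set(fst_out) & set(flk_sig)) if flk_sig else []
    return OutlierReport(
        fst_threshold=bound,
        window_threshold=win_bound,
        fst_outliers=fst_out,
        window_outliers=win_out,
        flk_significant=flk_sig,
        joint_outliers=joint,
    )
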