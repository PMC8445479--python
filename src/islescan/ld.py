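"""Pairwise r², LD scores, Hill-Robertson correction, and LD-decay fitting.

r² for unphased genotypes is the composite (Rogers-Huff style) estimator:
the squared Pearson correlation of dosage vectors over samples non-missing
at both markers.  The Hill-Robertson correction
``r'2 = (r2 - 1/N) / (1 - 1/N)`` removes the sampling inflation, with N the
number of sampled haplotypes (twice the pairwise-complete individuals).

The decay of r'² with inter-marker distance d (kb) is modelled by the
Sved-type curve ``y = 1 / (1 + 4 beta d)``; beta (per kb) absorbs effective
population size, larger beta meaning faster decay.  The fit is nonlinear
least squares (Levenberg-Marquardt) on pairs with positive corrected r² up
to a maximum distance, following the convention of excluding non-positive
corrected values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import MISSING, GenotypeMatrix

PAIR_COLUMNS = ["marker_i", "marker_j", "distance_kb", "r2", "r2_corrected", "n_haplotypes"]


def pairwise_r2(G: GenotypeMatrix, marker_i: str, marker_j: str) -> float:
    """Squared dosage correlation of two markers (NaN when undefined)."""
    i = G.marker_index(marker_i)
    j = G.marker_index(marker_j)
    r2, _ = _r2_complete(G.values[:, i], G.values[:, j])
    return r2


def _r2_complete(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n < 2:
        return np.nan, n
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan, n
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return r * r, n


def hill_robertson_correct(r2: float, n_haplotypes: int) -> float:
    """Remove the 1/N sampling inflation from an r² estimate (may go negative)."""
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    inv = 1.0 / n_haplotypes
    return (r2 - inv) / (1.0 - inv)


def _chrom_blocks(G: GenotypeMatrix):
    chrom = G.markers["chromosome"].to_numpy()
    pos = G.markers["position_bp"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        yield c, idx, pos[idx]


def _banded_pairs(values, idx, pos, max_dist_bp: float):
    """Vectorized pairwise-complete r² for all in-band pairs of one chromosome.

    Iterates over marker-index lags, computing the moment sums with masked
    array products; yields nothing once no pair at a lag is within range.
    Returns (a_local, b_local, r2, n_complete) arrays.
    """
    X = values[:, idx].astype(np.float64)
    C = (values[:, idx] != MISSING).astype(np.float64)
    X[C == 0] = 0.0
    X2 = X * X
    m = idx.size
    out_a, out_b, out_r2, out_n = [], [], [], []
    for k in range(1, m):
        a = np.flatnonzero(pos[k:] - pos[:-k] <= max_dist_bp)
        if a.size == 0:
            if np.min(pos[k:] - pos[:-k]) > max_dist_bp:
                break
            continue
        b = a + k
        ca, cb = C[:, a], C[:, b]
        joint = ca * cb
        n = joint.sum(axis=0)
        sx = (X[:, a] * cb).sum(axis=0)
        sy = (X[:, b] * ca).sum(axis=0)
        sxx = (X2[:, a] * cb).sum(axis=0)
        syy = (X2[:, b] * ca).sum(axis=0)
        sxy = (X[:, a] * X[:, b]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sy
            varx = n * sxx - sx * sx
            vary = n * syy - sy * sy
            r2 = np.where(
                (n >= 2) & (varx > 0) & (vary > 0),
                cov * cov / (varx * vary),
                np.nan,
            )
        out_a.append(a)
        out_b.append(b)
        out_r2.append(r2)
        out_n.append(n.astype(np.int64))
    if not out_a:
        empty = np.array([], dtype=np.int64)
        return empty, empty, np.array([]), empty
    return (
        np.concatenate(out_a),
        np.concatenate(out_b),
        np.concatenate(out_r2),
        np.concatenate(out_n),
    )


def ld_scores(G: GenotypeMatrix, window_bp: int = 500_000) -> pd.DataFrame:
    """Per-marker LD score: 1 + sum of r² with markers within the window.

    The window is centered on the scored marker (half the window size on
    each side), truncated at chromosome edges; the self term contributes
    the leading 1.
    """
    half = window_bp / 2.0
    ids = G.markers["marker_id"].to_numpy()
    scores = np.ones(G.n_markers)
    for _, idx, pos in _chrom_blocks(G):
        a, b, r2, _ = _banded_pairs(G.values, idx, pos, half)
        ok = np.isfinite(r2)
        np.add.at(scores, idx[a[ok]], r2[ok])
        np.add.at(scores, idx[b[ok]], r2[ok])
    return pd.DataFrame(
        {"marker_id": ids, "score": scores, "window_bp": window_bp}
    )


def ld_pairs(G: GenotypeMatrix, max_distance_kb: float = 2500.0) -> pd.DataFrame:
    """All same-chromosome marker pairs within the distance cap, with r'²."""
    ids = G.markers["marker_id"].to_numpy()
    frames = []
    for _, idx, pos in _chrom_blocks(G):
        a, b, r2, n = _banded_pairs(G.values, idx, pos, max_distance_kb * 1000.0)
        ok = np.isfinite(r2) & (n >= 2)
        a, b, r2, n = a[ok], b[ok], r2[ok], n[ok]
        nhap = 2 * n
        frames.append(
            pd.DataFrame(
                {
                    "marker_i": ids[idx[a]],
                    "marker_j": ids[idx[b]],
                    "distance_kb": (pos[b] - pos[a]) / 1000.0,
                    "r2": r2,
                    "r2_corrected": (r2 - 1.0 / nhap) / (1.0 - 1.0 / nhap),
                    "n_haplotypes": nhap,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def pairs_within_genes(
    G: GenotypeMatrix, gene_table: pd.DataFrame, max_distance_kb: float = 2500.0
) -> pd.DataFrame:
    """Marker pairs with both members inside the same gene interval."""
    if len(gene_table) == 0:
        raise ValueError("empty gene table")
    rows = []
    ids = G.markers["marker_id"].to_numpy()
    chrom = G.markers["chromosome"].to_numpy()
    pos = G.markers["position_bp"].to_numpy()
    for gene in gene_table.itertuples(index=False):
        sel = np.flatnonzero(
            (chrom == gene.chromosome)
            & (pos >= gene.start_bp)
            & (pos < gene.end_bp)
        )
        for ai in range(sel.size):
            for bi in range(ai + 1, sel.size):
                a, b = sel[ai], sel[bi]
                d_kb = abs(pos[b] - pos[a]) / 1000.0
                if d_kb > max_distance_kb:
                    continue
                r2, n = _r2_complete(G.values[:, a], G.values[:, b])
                if not np.isfinite(r2):
                    continue
                nhap = 2 * n
                rows.append(
                    (ids[a], ids[b], d_kb, r2, hill_robertson_correct(r2, nhap), nhap)
                )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS).drop_duplicates(
        subset=["marker_i", "marker_j"], ignore_index=True
    )


def wilcoxon_rank_sum(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a location difference.

    Exact null distribution when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with midranks,
    tie correction and continuity correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    exact = a.size + b.size <= 20 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class LDDecayFit:
    beta: float
    se_beta: float
    ci95: tuple[float, float]
    n_pairs: int
    origin: str
    residual_variance: float

    def to_dict(self) -> dict:
        return {
            "origin": self.origin,
            "beta": self.beta,
            "se_beta": self.se_beta,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n_pairs": self.n_pairs,
            "residual_variance": self.residual_variance,
        }


def sved_curve(d_kb, beta: float):
    """Expected r² at distance d under the Sved-type decay model."""
    return 1.0 / (1.0 + 4.0 * beta * np.asarray(d_kb, dtype=float))


def fit_ld_decay(
    pairs: pd.DataFrame,
    max_distance_kb: float = 2500.0,
    origin: str = "",
    use_corrected: bool = True,
    exclude_nonpositive: bool = True,
) -> LDDecayFit:
    """Fit ``y = 1/(1 + 4 beta d)`` to corrected r² by Levenberg-Marquardt.

    Pairs beyond the distance cap are excluded, and by default so are pairs
    with non-positive corrected r² — the convention for sample-size
    corrected empirical r², whose non-positive values are artifacts of the
    correction.  (For data with symmetric additive noise that truncation
    biases the fit; disable it with ``exclude_nonpositive=False``.)
    beta is initialized by closed-form inversion of the model at the
    distance-weighted mean point; the standard error comes from the
    Gauss-Newton approximation, CI95 = beta +/- 1.96 SE.
    """
    ycol = "r2_corrected" if use_corrected else "r2"
    sel = pairs["distance_kb"] <= max_distance_kb
    if exclude_nonpositive:
        sel &= pairs[ycol] > 0
    d = pairs.loc[sel, "distance_kb"].to_numpy(dtype=float)
    y = pairs.loc[sel, ycol].to_numpy(dtype=float)
    if d.size < 10:
        raise ValueError(f"only {d.size} usable pairs; need at least 10")
    # model inversion at the distance-weighted mean point: y = 1/(1+4 b d)
    w = d / d.sum()
    d0 = float(np.sum(w * d))
    y0 = float(np.clip(np.sum(w * y), 1e-6, 1 - 1e-9))
    beta0 = max((1.0 / y0 - 1.0) / (4.0 * d0), 1e-8)

    def residual(b):
        return 1.0 / (1.0 + 4.0 * b[0] * d) - y

    def jac(b):
        return (-4.0 * d / (1.0 + 4.0 * b[0] * d) ** 2)[:, None]

    res = optimize.least_squares(
        residual, x0=[beta0], jac=jac, method="lm", xtol=1e-10, max_nfev=200 * 2
    )
    if not res.success:
        raise RuntimeError(
            f"LD-decay fit did not converge: last beta={res.x[0]:.6g}, "
            f"gradient norm={np.linalg.norm(res.grad):.3g}"
        )
    beta = float(res.x[0])
    dof = max(d.size - 1, 1)
    s2 = float(res.fun @ res.fun) / dof
    JtJ = float((res.jac.T @ res.jac).item())
    se = float(np.sqrt(s2 / JtJ)) if JtJ > 0 else float("nan")
    return LDDecayFit(
        beta=beta,
        se_beta=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        n_pairs=int(d.size),
        origin=origin,
        residual_variance=s2,
    )
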