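"""Genomic relationships, PCA, Reynolds distances, and the population tree.

The genomic relationship matrix (GRM) uses VanRaden method 1: missing
dosages are mean-imputed per marker, dosages are centered at twice the
sample allele frequency, and the cross-product is scaled by the summed
binomial variance ``sum 2 p (1-p)``.  An identity-by-state alternative is
available behind a flag for sensitivity analysis.

The Reynolds coancestry distance ``D = -ln(1 - theta)`` uses the
ratio-of-sums two-population estimator with the finite-sample correction.
The neighbor-joining tree over population distances supplies the drift
covariance (kinship) matrix ``F`` consumed by the FLK test: ``F[i, j]`` is
the branch length shared by the root-to-leaf paths of populations ``i`` and
``j``.  With two populations the root is unidentifiable; the single edge is
split equally between the leaves by default (configurable ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .types import MISSING, GenotypeMatrix


@dataclass
class PCAResult:
    scores: np.ndarray        # n x k, eigenvectors scaled by sqrt(eigenvalue)
    pct_variance: np.ndarray  # k percentages of trace
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class PopTree:
    """Population tree with the drift covariance used by FLK."""

    leaves: list[str]
    branch_lengths: dict
    kinship: np.ndarray  # npop x npop shared-branch-length matrix F
    newick: str


def compute_grm(G: GenotypeMatrix, method: str = "vanraden") -> pd.DataFrame:
    """GRM over samples; ``method`` is 'vanraden' (default) or 'ibs'."""
    X = G.values.astype(np.float64)
    miss = G.values == MISSING
    called = ~miss
    n_called = called.sum(axis=0)
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(miss, 0, X).sum(axis=0) / (2 * n_called), np.nan)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; GRM undefined")
    if method == "vanraden":
        Xp = X[:, poly]
        pp = p[poly]
        Xp = np.where(miss[:, poly], 2 * pp, Xp)  # mean-impute
        Z = Xp - 2 * pp
        denom = float(np.sum(2 * pp * (1 - pp)))
        K = Z @ Z.T / denom
    elif method == "ibs":
        Xp = np.where(miss, np.nan, X)
        # mean IBS-sharing proportion over jointly called markers
        n = G.n_samples
        K = np.empty((n, n))
        for i in range(n):
            diff = np.abs(Xp[i] - Xp)
            K[i] = 1 - np.nanmean(diff, axis=1) / 2
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    K = (K + K.T) / 2
    return pd.DataFrame(K, index=G.sample_ids, columns=G.sample_ids)


def pca_grm(K: pd.DataFrame, k: int) -> PCAResult:
    """Top-k principal components of a relationship matrix.

    Scores are eigenvectors scaled by the square root of their eigenvalues;
    the percent variance of component i is ``100 * lambda_i / trace(K)``.
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    mat = np.asarray(K, dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("GRM contains non-finite entries")
    n = mat.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    evals, evecs = eigh(mat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top_vals = np.clip(evals[:k], 0, None)
    top_vecs = evecs[:, :k]
    for j in range(k):  # deterministic sign
        lead = np.argmax(np.abs(top_vecs[:, j]))
        if top_vecs[lead, j] < 0:
            top_vecs[:, j] = -top_vecs[:, j]
    scores = top_vecs * np.sqrt(top_vals)
    pct = 100.0 * evals[:k] / np.trace(mat)
    return PCAResult(scores, pct, list(K.index))


def population_frequencies(G: GenotypeMatrix, labels) -> tuple[pd.DataFrame, pd.Series]:
    """Per-population allele_b frequencies and genotyped sample counts."""
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    freqs = {}
    counts = {}
    for pop in pops:
        sub = G.values[labels == pop]
        called = sub != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n), np.nan)
        counts[pop] = (labels == pop).sum()
    return pd.DataFrame(freqs), pd.Series(counts)


def reynolds_distance(freqs1, freqs2, n1: int, n2: int) -> float:
    """Reynolds-Weir-Cockerham coancestry distance between two populations.

    Ratio-of-sums estimator over markers of the between/(between + within)
    variance components with the finite-sample correction; returns
    ``-ln(1 - theta)`` (+inf if theta >= 1).
    """
    p1 = np.asarray(freqs1, dtype=float)
    p2 = np.asarray(freqs2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors differ in length")
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 samples per population")
    ok = np.isfinite(p1) & np.isfinite(p2)
    p1, p2 = p1[ok], p2[ok]
    # per-locus sums over the two alleles of a biallelic marker
    sq_diff = (p1 - p2) ** 2 + ((1 - p1) - (1 - p2)) ** 2  # = 2 (p1-p2)^2
    al1 = 1 - (p1**2 + (1 - p1) ** 2)
    al2 = 1 - (p2**2 + (1 - p2) ** 2)
    corr = (n1 + n2) * (n1 * al1 + n2 * al2) / (4.0 * n1 * n2 * (n1 + n2 - 1))
    a = sq_diff / 2.0 - corr
    ab = sq_diff / 2.0 + (4.0 * n1 * n2 - n1 - n2) * (n1 * al1 + n2 * al2) / (
        4.0 * n1 * n2 * (n1 + n2 - 1)
    )
    denom = ab.sum()
    if denom <= 0:
        return 0.0
    theta = a.sum() / denom
    if theta >= 1:
        return float("inf")
    return float(max(0.0, -np.log1p(-theta)))


def reynolds_distance_matrix(G: GenotypeMatrix, labels) -> pd.DataFrame:
    freqs, counts = population_frequencies(G, labels)
    pops = list(freqs.columns)
    D = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            D[i, j] = D[j, i] = reynolds_distance(
                freqs[pops[i]], freqs[pops[j]], counts[pops[i]], counts[pops[j]]
            )
    return pd.DataFrame(D, index=pops, columns=pops)


def nj_tree(D: pd.DataFrame, two_pop_split: float = 0.5) -> PopTree:
    """Neighbor-joining population tree and FLK drift matrix.

    Negative branch lengths are clipped to zero.  With two populations the
    single edge of length D(1,2) is split ``two_pop_split : 1-two_pop_split``
    between the leaves (no outgroup information); with three or more, the
    Saitou-Nei tree is midpoint-rooted before deriving F.
    """
    mat = np.asarray(D, dtype=float)
    pops = list(D.index)
    npop = len(pops)
    if npop < 2:
        raise ValueError("need at least 2 populations")
    if not np.allclose(mat, mat.T) or (mat < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    if npop == 2:
        d = float(mat[0, 1])
        b = {pops[0]: d * two_pop_split, pops[1]: d * (1 - two_pop_split)}
        F = np.diag([b[pops[0]], b[pops[1]]])
        newick = f"({pops[0]}:{b[pops[0]]:.8g},{pops[1]}:{b[pops[1]]:.8g});"
        return PopTree(pops, b, F, newick)
    tree = _skbio_nj(DistanceMatrix(mat, ids=pops))
    tree = tree.root_at_midpoint()
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    # shared root-to-leaf branch length matrix
    paths = {}
    for leaf in tree.tips():
        path = []
        node = leaf
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[leaf.name] = list(reversed(path))  # root-side first
    F = np.zeros((npop, npop))
    branch_lengths = {}
    for i, a in enumerate(pops):
        branch_lengths[a] = sum(n.length or 0.0 for n in paths[a])
        for j, b in enumerate(pops):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is nb:
                    shared += na.length or 0.0
                else:
                    break
            F[i, j] = shared if i != j else branch_lengths[a]
    return PopTree(pops, branch_lengths, F, str(tree).strip())
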