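"""EMMAX-style single-locus mixed-model association scan.

The phenotype here is the binary sampling origin (0: island, 1: mainland),
treated as quantitative.  The null model ``y = mu + u + e`` with
``u ~ (0, sg2 K)`` is fitted once by REML on the spectral decomposition of
the centered relationship matrix; the estimated variance components are
then held fixed while each SNP enters as a fixed covariate, tested by
generalized least squares on the whitened data (the EMMAX approximation).

Diagnostics: per-SNP p-values, BH-FDR, proportion of variance explained
``pve = beta^2 var(g) / var(y)``, and the genomic inflation factor
``lambda = median(chi2_1 quantiles of p) / 0.4549``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scan import fdr_bh
from .types import MISSING, GenotypeMatrix

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


@dataclass
class MixedModelNull:
    variance_genetic: float
    variance_residual: float
    log_likelihood: float
    # spectral decomposition of the phenotype-space covariance (centered)
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    sample_ids: list[str]

    @property
    def delta(self) -> float:
        if self.variance_genetic <= 0:
            return float("inf")
        return self.variance_residual / self.variance_genetic

    @property
    def heritability(self) -> float:
        tot = self.variance_genetic + self.variance_residual
        return self.variance_genetic / tot if tot > 0 else 0.0


def fit_null_mixed_model(y, K: pd.DataFrame, ridge: float = 1e-6) -> MixedModelNull:
    """REML variance components of an intercept-only mixed model.

    Profiles the REML log-likelihood in ``delta = se2/sg2`` over a log grid
    refined by golden-section search on the projected (centered) spectrum.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; no variance to model")
    Kmat = np.asarray(K, dtype=float)
    n = y.size
    if Kmat.shape != (n, n):
        raise ValueError("K and y dimensions disagree")
    evals_k = np.linalg.eigvalsh(Kmat)
    if evals_k.min() < -1e-8:
        Kmat = Kmat + (ridge - evals_k.min()) * np.eye(n)

    # project out the intercept, eigendecompose S K S on its (n-1)-space
    P = np.eye(n) - np.ones((n, n)) / n
    B = P @ Kmat @ P
    evals, evecs = np.linalg.eigh(B)
    keep = np.argsort(evals)[1:]  # drop the null direction of the projection
    xi = np.clip(evals[keep], 0, None)
    W = evecs[:, keep]
    eta = W.T @ y
    nq = n - 1

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = xi + delta
        sg2 = float(np.sum(eta**2 / denom) / nq)
        return 0.5 * (
            nq * np.log(2 * np.pi * sg2) + np.sum(np.log(denom)) + nq
        )

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_reml(g) for g in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        neg_reml, bracket=None, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))
    denom = xi + delta
    sg2 = float(np.sum(eta**2 / denom) / nq)
    se2 = sg2 * delta
    # re-express as full-space decomposition of K for the scan whitening
    evals_f, evecs_f = np.linalg.eigh(Kmat)
    return MixedModelNull(
        variance_genetic=sg2,
        variance_residual=se2,
        log_likelihood=-float(res.fun),
        eigenvalues=np.clip(evals_f, 0, None),
        eigenvectors=evecs_f,
        sample_ids=list(K.index) if hasattr(K, "index") else [str(i) for i in range(n)],
    )


@dataclass
class AssocResult:
    table: pd.DataFrame  # marker_id, beta_hat, se, p_value, p_fdr, pve, significant
    lambda_gc: float
    qq: pd.DataFrame     # expected vs observed -log10 p


def genomic_lambda(p_values) -> float:
    """Median observed chi-square quantile over its null median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def emmax_scan(
    G: GenotypeMatrix,
    y,
    null: MixedModelNull,
    fdr_alpha: float = 0.05,
) -> AssocResult:
    """Per-SNP GLS scan with variance components fixed at the null fit.

    Missing dosages are mean-imputed; monomorphic SNPs are skipped (NaN).
    Wald tests use a t distribution with n - 2 degrees of freedom.
    Significance: FDR-adjusted p below ``fdr_alpha``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if G.n_samples != n:
        raise ValueError("genotypes and phenotype disagree on sample count")
    sg2, se2 = null.variance_genetic, null.variance_residual
    var_diag = np.clip(sg2 * null.eigenvalues + se2, 1e-12, None)
    # whitening transform M = V^(-1/2)
    M = null.eigenvectors / np.sqrt(var_diag)
    yt = M.T @ y
    ones_t = M.T @ np.ones(n)

    X = G.values.astype(np.float64)
    miss = G.values == MISSING
    called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dose = np.where(called > 0, np.where(miss, 0, X).sum(axis=0) / called, 0.0)
    X = np.where(miss, mean_dose, X)
    var_dose = X.var(axis=0)
    poly = var_dose > 0

    Gt = M.T @ X  # n x m rotated dosages

    # per-marker 2x2 normal equations with covariates (1, g)
    a11 = float(ones_t @ ones_t)
    a12 = ones_t @ Gt
    a22 = np.einsum("ij,ij->j", Gt, Gt)
    b1 = float(ones_t @ yt)
    b2 = yt @ Gt
    det = a11 * a22 - a12**2
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        alpha = (b1 - a12 * beta) / a11
        yty = float(yt @ yt)
        rss = yty - alpha * b1 - beta * b2
        dof = n - 2
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * a11 / det)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    beta = np.where(poly, beta, np.nan)
    se = np.where(poly, se, np.nan)
    pvals = np.where(poly, pvals, np.nan)
    var_y = float(y.var())
    pve = np.where(poly, beta**2 * var_dose / var_y, np.nan)
    p_fdr = fdr_bh(pvals)

    lam = genomic_lambda(pvals)
    obs = np.sort(pvals[np.isfinite(pvals)])
    mcount = obs.size
    expected = (np.arange(1, mcount + 1) - 0.5) / mcount
    qq = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.clip(obs, 1e-300, None)),
        }
    )
    table = G.markers[["marker_id", "chromosome", "position_bp"]].copy()
    table["beta_hat"] = beta
    table["se"] = se
    table["p_value"] = pvals
    table["p_fdr"] = p_fdr
    table["pve"] = pve
    table["significant"] = table["p_fdr"] < fdr_alpha
    return AssocResult(table=table, lambda_gc=lam, qq=qq)
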