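"""Spatial point-pattern statistics for genetic structure.

Values (typically PC1 of the relationship matrix) observed at sampling
coordinates are tested for spatial autocorrelation with global Moran's I
under row-standardized inverse-distance or k-nearest-neighbour weights;
the null expectation is ``-1/(n-1)`` and the Z score uses the
randomization-variance formula, optionally checked by permutation.
A Gaussian-kernel intensity surface and nearest-neighbour distances
describe the point pattern itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist


@dataclass
class SpatialResult:
    moran_i: float
    expected_i: float
    z_score: float
    p_value: float
    weight_scheme: str
    permutation_p: float | None = None


def _weights(coords: np.ndarray, scheme: str, k: int = 8, jitter: float = 0.0,
             rng=None) -> np.ndarray:
    n = coords.shape[0]
    pts = coords.astype(float).copy()
    d = cdist(pts, pts)
    if scheme == "inverse_distance":
        off = d[~np.eye(n, dtype=bool)]
        if (off == 0).any():
            if jitter > 0:
                rng = rng or np.random.default_rng(0)
                pts += rng.normal(0, jitter, pts.shape)
                d = cdist(pts, pts)
            else:
                raise ValueError(
                    "duplicate coordinates under inverse_distance; use jitter"
                )
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif scheme == "knn":
        w = np.zeros((n, n))
        order = np.argsort(d + np.diag(np.full(n, np.inf)), axis=1)
        for i in range(n):
            w[i, order[i, :k]] = 1.0
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return w / rs


def moran_i(
    values,
    coords,
    scheme: str = "inverse_distance",
    k: int = 8,
    jitter: float = 0.0,
    n_permutations: int = 0,
    seed: int = 0,
) -> SpatialResult:
    """Global Moran's I with analytic randomization Z and optional permutations."""
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant values; Moran's I undefined")
    w = _weights(coords, scheme, k=k, jitter=jitter)
    z = x - x.mean()
    W = w.sum()
    num = z @ w @ z
    den = float(z @ z)
    I = (n / W) * num / den
    EI = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    b2 = n * np.sum(z**4) / (np.sum(z**2) ** 2)
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * W**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * W**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * W**2) - EI**2
    zscore = (I - EI) / np.sqrt(var)
    pval = 2.0 * stats.norm.sf(abs(zscore))
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            zp = rng.permutation(z)
            Ip = (n / W) * (zp @ w @ zp) / den
            if abs(Ip - EI) >= abs(I - EI):
                count += 1
        perm_p = (count + 1) / (n_permutations + 1)
    return SpatialResult(
        moran_i=float(I),
        expected_i=EI,
        z_score=float(zscore),
        p_value=float(pval),
        weight_scheme=scheme,
        permutation_p=perm_p,
    )


def nearest_neighbor_distances(coords) -> np.ndarray:
    """Euclidean distance from each point to its nearest other point."""
    pts = np.asarray(coords, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def kernel_intensity(
    coords,
    values=None,
    bandwidth: float | None = None,
    grid_size: int = 64,
):
    """Gaussian-kernel intensity and Nadaraya-Watson value surface.

    Returns ``(grid_x, grid_y, intensity, smoothed_values)`` on a regular
    grid covering the bounding box with a 10% margin; ``smoothed_values``
    is None when no values are given.  The intensity integrates to
    approximately the number of points.  Default bandwidth: Silverman's
    rule on the coordinates.
    """
    pts = np.asarray(coords, dtype=float)
    n = pts.shape[0]
    if bandwidth is None:
        sd = pts.std(axis=0, ddof=1).mean() if n > 1 else 1.0
        bandwidth = max(1.06 * sd * n ** (-1 / 5), 1e-6)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    mins, maxs = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(maxs - mins, 1e-9)
    lo = mins - 0.1 * span
    hi = maxs + 0.1 * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    GX, GY = np.meshgrid(gx, gy)
    grid_pts = np.column_stack([GX.ravel(), GY.ravel()])
    d2 = cdist(grid_pts, pts, "sqeuclidean")
    kern = np.exp(-d2 / (2 * bandwidth**2)) / (2 * np.pi * bandwidth**2)
    intensity = kern.sum(axis=1).reshape(grid_size, grid_size)
    smoothed = None
    if values is not None:
        v = np.asarray(values, dtype=float)
        wsum = kern.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = (kern @ v) / wsum
        smoothed = smoothed.reshape(grid_size, grid_size)
    return gx, gy, intensity, smoothed
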