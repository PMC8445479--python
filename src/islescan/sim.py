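"""Synthetic two-population SNP-array genotypes.

The generator emulates the statistical structure a mainland-vs-island genome
scan assumes, at 50k-array scale:

* Per-marker ancestral frequencies ``p0 ~ Uniform(0.05, 0.95)``; population
  frequencies follow the Balding–Nichols model,
  ``p_i ~ Beta(p0(1-c)/c, (1-p0)(1-c)/c)`` with ``c`` the drift parameter
  (equal to the expected per-locus F_ST against the ancestor).
* Within-chromosome LD from a first-order Markov copying process: each
  haplotype carries a latent uniform per marker that is either copied from
  the previous marker or redrawn; the per-interval retention probability is
  calibrated (least squares, see :func:`calibrate_switch_rate`) so that the
  expected r² between markers at distance ``d`` kb approximates the Sved
  curve ``1/(1 + 4*beta*d)``.  A multiplicative survival process is
  necessarily exponential in distance, and unlinked allele frequencies bound
  the attainable correlation (Fréchet bound), so the match is approximate by
  construction; downstream recovery tests budget for that.
* Planted "adapted" loci: Balding–Nichols draws at the selected drift value,
  rejection-sampled until the realized Nei F_ST of the locus is within 0.05
  of the requested value, so a planted locus is reliably differentiated.
* Planted close relatives: one haplotype of a sample is replaced by a copy
  from another sample of the same population (parent-offspring-like,
  expected pi-hat about 0.5).
* Missing genotypes i.i.d. at ``missing_rate``; sampling coordinates at two
  Gaussian-jittered cluster centers (lon/lat roughly matching northwestern
  mainland Greece and the northern Aegean).

Defaults mirror the study design this package targets: 90 mainland vs 147
island samples, 26 autosomes, ~39k markers, background differentiation 0.05,
one strongly differentiated locus on chromosome 4.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import io as iio
from .types import MISSING, GenotypeMatrix, make_marker_map, make_sample_table


class SimConfigError(ValueError):
    """Raised for unsatisfiable simulation configurations."""


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the package's reference scenario."""

    n_pop1: int = 90           # mainland
    n_pop2: int = 147          # island
    n_chromosomes: int = 26
    markers_per_chromosome: int = 1500
    chrom_length_bp: int = 100_000_000
    fst_background: float = 0.05
    selected_loci: list = field(
        default_factory=lambda: [("4", 72_769_785, 0.40)]
    )
    ld_beta: float = 0.11      # per kb; island ~0.117, mainland ~0.106 scale
    missing_rate: float = 0.01
    n_planted_relative_pairs: int = 3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_pop1, self.n_pop2) < 2:
            raise SimConfigError("need at least 2 samples per population")
        if not (0 <= self.fst_background < 1):
            raise SimConfigError("fst_background must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise SimConfigError("missing_rate must be in [0, 1)")
        if self.ld_beta <= 0:
            raise SimConfigError("ld_beta must be > 0")
        chroms = {str(i + 1) for i in range(self.n_chromosomes)}
        for chrom, pos, fsel in self.selected_loci:
            if str(chrom) not in chroms:
                raise SimConfigError(f"selected locus on unknown chromosome {chrom!r}")
            if not (1 <= pos <= self.chrom_length_bp):
                raise SimConfigError(
                    f"selected locus position {pos} outside chromosome (1..{self.chrom_length_bp})"
                )
            if fsel < self.fst_background:
                raise SimConfigError("fst_selected must be >= fst_background")
        if self.n_planted_relative_pairs * 2 > self.n_pop1 + self.n_pop2:
            raise SimConfigError("too many planted relative pairs")


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset."""

    selected_markers: list          # [(marker_id, chromosome, position, fst_selected)]
    relative_pairs: list            # [(sample_id_a, sample_id_b)]
    p_pop1: np.ndarray
    p_pop2: np.ndarray
    p_ancestral: np.ndarray
    switch_rate_per_kb: float

    def to_json(self) -> str:
        d = {
            "selected_markers": [list(t) for t in self.selected_markers],
            "relative_pairs": [list(t) for t in self.relative_pairs],
            "p_pop1": np.round(self.p_pop1, 6).tolist(),
            "p_pop2": np.round(self.p_pop2, 6).tolist(),
            "p_ancestral": np.round(self.p_ancestral, 6).tolist(),
            "switch_rate_per_kb": self.switch_rate_per_kb,
        }
        return json.dumps(d, sort_keys=True)


@lru_cache(maxsize=1)
def _mean_squared_comonotone_corr() -> float:
    """E[A²] for A = corr of two comonotone Bernoulli indicators.

    A(p, p') = (min(p,p') - p p') / sqrt(p(1-p) p'(1-p')) is the Fréchet
    upper bound on the correlation of indicators with marginals p, p'.
    Averaged over p, p' ~ Uniform(0.05, 0.95) on a deterministic grid; this
    is the attenuation factor the LD calibration has to absorb.
    """
    grid = np.linspace(0.05, 0.95, 181)
    p, q = np.meshgrid(grid, grid)
    a = (np.minimum(p, q) - p * q) / np.sqrt(p * (1 - p) * q * (1 - q))
    return float(np.mean(a**2))


def calibrate_switch_rate(ld_beta: float, pair_distances_kb, max_d_kb: float = 2500.0) -> float:
    """Gamma scale of the per-haplotype copying rate matching the Sved curve.

    Each haplotype copies its latent uniform along the chromosome, switching
    at a haplotype-specific rate ``s ~ Gamma(1/2, theta)`` per kb.  The
    shared-segment survival is then ``E[exp(-s d)] = (1 + theta d)^(-1/2)``
    and the expected r² curve ``A2bar / (1 + theta d)`` — the same shape as
    the Sved target ``1/(1 + 4 beta d)`` but attenuated by the
    frequency-mismatch bound ``A2bar`` (markers with unequal frequencies
    cannot be perfectly correlated, which caps r² at short range).

    ``theta`` is chosen so that the least-squares Sved fit applied to the
    implied expected curve, evaluated over the map's own pair-distance
    distribution, returns ``ld_beta`` — i.e. the calibration targets
    unbiased recovery of the decay rate rather than pointwise curve
    equality, which the attenuation ceiling makes unattainable at very
    short distances.  ``pair_distances_kb`` is either the array of pair
    distances of the realized map or a scalar spacing for an even grid.
    """
    a2 = _mean_squared_comonotone_corr()
    if np.ndim(pair_distances_kb) == 0:
        step = float(pair_distances_kb)
        d = np.arange(step, max_d_kb + step, step)
        w = np.linspace(1.0, 0.05, d.size)  # pair density falls off with lag
    else:
        d = np.asarray(pair_distances_kb, dtype=float)
        d = d[(d > 0) & (d <= max_d_kb)]
        if d.size > 5000:  # deterministic thinning for speed
            d = np.sort(d)[:: d.size // 5000 + 1]
        w = np.ones(d.size)

    def beta_hat(theta: float) -> float:
        y = a2 / (1.0 + theta * d)

        def loss(b: float) -> float:
            return float(np.sum(w * (1.0 / (1.0 + 4.0 * b * d) - y) ** 2))

        grid = np.geomspace(1e-5, 10.0 * ld_beta + 1.0, 120)
        vals = np.array([loss(g) for g in grid])
        i0 = int(np.argmin(vals))
        res = minimize_scalar(
            loss,
            bounds=(grid[max(i0 - 1, 0)], grid[min(i0 + 1, grid.size - 1)]),
            method="bounded", options={"xatol": 1e-12},
        )
        return float(res.x)

    theta0 = 4.0 * ld_beta * a2  # tail-exact starting point
    lo, hi = theta0 / 100.0, theta0 * 10.0
    if beta_hat(lo) > ld_beta or beta_hat(hi) < ld_beta:
        return theta0
    for _ in range(40):  # beta_hat is increasing in theta
        mid = 0.5 * (lo + hi)
        if beta_hat(mid) < ld_beta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _nei_fst(p1: float, p2: float) -> float:
    pbar = 0.5 * (p1 + p2)
    ht = 2 * pbar * (1 - pbar)
    hs = p1 * (1 - p1) + p2 * (1 - p2)
    if ht <= 0:
        return 0.0
    return 1.0 - hs / ht


def _draw_bn_pair(rng, p0: float, c: float) -> tuple[float, float]:
    if c <= 0:
        return p0, p0
    a = p0 * (1 - c) / c
    b = (1 - p0) * (1 - c) / c
    for _ in range(1000):
        p1, p2 = rng.beta(a, b, size=2)
        if 1e-6 < p1 < 1 - 1e-6 and 1e-6 < p2 < 1 - 1e-6:
            return float(p1), float(p2)
    raise SimConfigError(f"degenerate Balding-Nichols draw at p0={p0}, c={c}")


def _draw_positions(rng, length_bp: int, n: int, exclude=()) -> np.ndarray:
    """Draw ``n`` distinct 1-based positions, avoiding ``exclude``."""
    if n > length_bp - len(exclude):
        raise SimConfigError("chromosome too short for requested marker count")
    taken = set(int(x) for x in exclude)
    out: list[int] = []
    while len(out) < n:
        cand = rng.integers(1, length_bp + 1, size=2 * (n - len(out)) + 16)
        for c in cand:
            c = int(c)
            if c not in taken:
                taken.add(c)
                out.append(c)
                if len(out) == n:
                    break
    return np.asarray(out, dtype=np.int64)


def _haplotypes(rng, p: np.ndarray, pos_bp: np.ndarray, n_hap: int, theta: float) -> np.ndarray:
    """Markov-copying haplotypes for one chromosome of one population.

    Each haplotype switches its latent uniform at its own per-kb rate drawn
    from Gamma(1/2, theta); see :func:`calibrate_switch_rate`.
    """
    m = p.size
    u = np.empty((n_hap, m))
    u[:, 0] = rng.random(n_hap)
    d_kb = np.diff(pos_bp) / 1000.0
    rate = rng.gamma(0.5, theta, size=n_hap)
    retain = np.exp(-np.outer(rate, d_kb))
    fresh = rng.random((n_hap, m))
    copy = rng.random((n_hap, m - 1)) < retain
    for k in range(1, m):
        u[:, k] = np.where(copy[:, k - 1], u[:, k - 1], fresh[:, k])
    return (u < p[None, :]).astype(np.int8)


def simulate_dataset(config: SimConfig):
    """Simulate genotypes; returns (GenotypeMatrix, MarkerMap, SampleTable, TruthRecord)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_map, rng_freq, rng_hap, rng_rel, rng_miss, rng_coord = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    mpc = config.markers_per_chromosome
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]
    selected_by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, fsel in config.selected_loci:
        selected_by_chrom.setdefault(str(chrom), []).append((int(pos), float(fsel)))

    # --- marker map ------------------------------------------------------
    chrom_col, pos_col, id_col, c_col, sel_col = [], [], [], [], []
    for chrom in chroms:
        planted = selected_by_chrom.get(chrom, [])
        n_free = mpc - len(planted)
        if n_free < 0:
            raise SimConfigError(f"more planted loci than markers on chromosome {chrom}")
        pos = _draw_positions(
            rng_map, config.chrom_length_bp, n_free, exclude=[p for p, _ in planted]
        )
        pos = np.concatenate([pos, [p for p, _ in planted]]).astype(np.int64)
        cvec = np.concatenate(
            [np.full(n_free, config.fst_background), [f for _, f in planted]]
        )
        svec = np.concatenate([np.zeros(n_free, bool), np.ones(len(planted), bool)])
        order = np.argsort(pos, kind="stable")
        chrom_col.extend([chrom] * mpc)
        pos_col.extend(pos[order].tolist())
        c_col.extend(cvec[order].tolist())
        sel_col.extend(svec[order].tolist())
        id_col.extend(f"snp_{chrom}_{k + 1}" for k in range(mpc))
    markers = make_marker_map(id_col, chrom_col, pos_col, allele_a="A", allele_b="B")
    m_total = len(markers)
    c_arr = np.asarray(c_col)
    is_selected = np.asarray(sel_col, dtype=bool)

    # --- allele frequencies ---------------------------------------------
    p0 = rng_freq.uniform(0.05, 0.95, size=m_total)
    p1 = np.empty(m_total)
    p2 = np.empty(m_total)
    bg = ~is_selected
    if config.fst_background <= 0:
        p1[bg] = p0[bg]
        p2[bg] = p0[bg]
    else:
        c = config.fst_background
        a = p0[bg] * (1 - c) / c
        b = (1 - p0[bg]) * (1 - c) / c
        q1 = rng_freq.beta(a, b)
        q2 = rng_freq.beta(a, b)
        for _ in range(100):  # redraw loci with degenerate draws
            bad = (
                (q1 < 1e-6) | (q1 > 1 - 1e-6) | (q2 < 1e-6) | (q2 > 1 - 1e-6)
            )
            if not bad.any():
                break
            q1[bad] = rng_freq.beta(a[bad], b[bad])
            q2[bad] = rng_freq.beta(a[bad], b[bad])
        p1[bg], p2[bg] = q1, q2
    for j in np.flatnonzero(is_selected):
        target = c_arr[j]
        for _ in range(10_000):
            a_, b_ = _draw_bn_pair(rng_freq, p0[j], target)
            if abs(_nei_fst(a_, b_) - target) < 0.05:
                p1[j], p2[j] = a_, b_
                break
        else:
            raise SimConfigError(
                f"could not realize planted F_ST {target} at marker {j}"
            )

    # --- haplotypes and genotypes ---------------------------------------
    chrom_arr0 = markers["chromosome"].to_numpy()
    pos_arr0 = markers["position_bp"].to_numpy()
    dists = []
    for chrom in chroms:
        cpos = pos_arr0[chrom_arr0 == chrom]
        for k in range(1, cpos.size):
            gaps = (cpos[k:] - cpos[:-k]) / 1000.0
            gaps = gaps[gaps <= 2500.0]
            if gaps.size == 0:
                break
            dists.append(gaps)
    lam = calibrate_switch_rate(
        config.ld_beta, np.concatenate(dists) if dists else 1.0
    )
    n1, n2 = config.n_pop1, config.n_pop2
    hapA = np.empty((2 * n1, m_total), dtype=np.int8)
    hapB = np.empty((2 * n2, m_total), dtype=np.int8)
    chrom_arr = markers["chromosome"].to_numpy()
    pos_arr = markers["position_bp"].to_numpy()
    for chrom in chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        hapA[:, idx] = _haplotypes(rng_hap, p1[idx], pos_arr[idx], 2 * n1, lam)
        hapB[:, idx] = _haplotypes(rng_hap, p2[idx], pos_arr[idx], 2 * n2, lam)

    sample_ids = [f"m{i + 1:03d}" for i in range(n1)] + [f"i{i + 1:03d}" for i in range(n2)]
    origins = ["mainland"] * n1 + ["island"] * n2

    # --- planted relatives (perturb after frequency draws) ---------------
    rel_pairs: list[tuple[str, str]] = []
    pool = rng_rel.permutation(n1 + n2)
    taken = 0
    hap_of = lambda s: (hapA, 2 * s) if s < n1 else (hapB, 2 * (s - n1))
    pop_of = lambda s: 0 if s < n1 else 1
    i = 0
    while taken < config.n_planted_relative_pairs and i + 1 < pool.size:
        a = int(pool[i])
        # find a partner from the same population
        j = i + 1
        while j < pool.size and pop_of(int(pool[j])) != pop_of(a):
            j += 1
        if j >= pool.size:
            break
        b = int(pool[j])
        pool = np.delete(pool, [i, j])
        arr_a, ra = hap_of(a)
        arr_b, rb = hap_of(b)
        arr_b[rb] = arr_a[ra]  # b's first haplotype copies a's first haplotype
        rel_pairs.append((sample_ids[a], sample_ids[b]))
        taken += 1
    if taken < config.n_planted_relative_pairs:
        raise SimConfigError("could not place all planted relative pairs")

    values = np.empty((n1 + n2, m_total), dtype=np.int8)
    values[:n1] = hapA[0::2] + hapA[1::2]
    values[n1:] = hapB[0::2] + hapB[1::2]

    # --- missingness ------------------------------------------------------
    if config.missing_rate > 0:
        mask = rng_miss.random(values.shape) < config.missing_rate
        values[mask] = MISSING

    # --- coordinates ------------------------------------------------------
    centers = {"mainland": (20.8, 39.6), "island": (25.9, 39.2)}
    jitter = rng_coord.normal(0.0, 0.35, size=(n1 + n2, 2))
    coord_x = np.array([centers[o][0] for o in origins]) + jitter[:, 0]
    coord_y = np.array([centers[o][1] for o in origins]) + jitter[:, 1]

    geno = GenotypeMatrix(values, sample_ids, markers)
    samples = make_sample_table(
        sample_ids, origins,
        region=origins, herd=["h1"] * (n1 + n2),
        coord_x=coord_x, coord_y=coord_y,
    )
    sel_records = []
    mid_arr = markers["marker_id"].to_numpy()
    for j in np.flatnonzero(is_selected):
        sel_records.append((mid_arr[j], chrom_arr[j], int(pos_arr[j]), float(c_arr[j])))
    truth = TruthRecord(
        selected_markers=sel_records,
        relative_pairs=rel_pairs,
        p_pop1=p1, p_pop2=p2, p_ancestral=p0,
        switch_rate_per_kb=lam,
    )
    return geno, markers, samples, truth


def impose_sweep(
    geno: GenotypeMatrix,
    labels,
    focal_marker: str,
    halfwidth_bp: int = 200_000,
    peak_p1: float = 0.98,
    valley_p2: float = 0.25,
    seed: int = 0,
) -> None:
    """Overwrite genotypes around a marker with a hitchhiking-style pattern.

    Emulates the footprint of long-term local adaptation: in population 1
    the swept allele approaches fixation at the focal marker (frequency
    ``peak_p1``) and relaxes linearly toward each marker's original
    frequency over ``halfwidth_bp``; population 2 is pulled toward the
    intermediate ``valley_p2`` the same way.  This produces the joint
    differentiation peak, avHo dip and dHo peak that the selective-process
    classifier looks for.  ``valley_p2`` defaults below 0.5 because an
    exactly intermediate frequency maximizes population 2's heterozygosity
    and would cancel the avHo dip that population 1's near-fixation creates.  Genotypes in the window are redrawn
    binomially (in place); LD within the window is not preserved.
    """
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    rng = np.random.default_rng(seed)
    j = geno.marker_index(focal_marker)
    chrom = geno.markers["chromosome"].iloc[j]
    pos0 = int(geno.markers["position_bp"].iloc[j])
    chrom_arr = geno.markers["chromosome"].to_numpy()
    pos_arr = geno.markers["position_bp"].to_numpy()
    sel = np.flatnonzero(
        (chrom_arr == chrom) & (np.abs(pos_arr - pos0) <= halfwidth_bp)
    )
    weight = 1.0 - np.abs(pos_arr[sel] - pos0) / halfwidth_bp
    for pop, target in ((pops[0], peak_p1), (pops[1], valley_p2)):
        rows = np.flatnonzero(labels == pop)
        sub = geno.values[np.ix_(rows, sel)]
        called = sub != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_orig = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n), 0.5)
        p_new = (1 - weight) * p_orig + weight * target
        draws = rng.binomial(2, p_new[None, :], size=sub.shape).astype(np.int8)
        draws[~called] = MISSING
        geno.values[np.ix_(rows, sel)] = draws


def write_fixture(config: SimConfig, out_dir) -> dict:
    """Simulate and persist a dataset (PED/MAP, BED/BIM/FAM, samples, truth).

    Byte-identical outputs for identical configs (all randomness flows from
    ``config.seed``).  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno, markers, samples, truth = simulate_dataset(config)
    paths = {
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "bed": out / "genotypes.bed",
        "bim": out / "genotypes.bim",
        "fam": out / "genotypes.fam",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    iio.write_plink_text(geno, paths["ped"], paths["map"], samples)
    iio.write_plink_binary(geno, paths["bed"], paths["bim"], paths["fam"], samples)
    iio.write_sample_table(samples, paths["samples"])
    paths["truth"].write_text(truth.to_json())
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    )
    return {k: str(v) for k, v in paths.items()}
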