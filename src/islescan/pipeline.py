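"""End-to-end orchestration: simulate/load -> QC -> structure -> scans -> report.

All stage thresholds default to the package's reference analysis settings
(sample call rate 0.95, pi-hat 0.25, marker call rate 0.95, MAF 0.05, HWE
1e-5, LD prune r2 0.5 in 50-SNP windows stepping 5, F_ST percentile 99.999,
500-kb windows with >= 4 SNPs, FLK FDR 0.1, GWAS FDR 0.05, LD-score windows
500/1000 kb, pair distance cap 2500 kb, annotation flank 500 kb, diagnostic
flank 1 Mb, loess span 0.21).  Every run is reproducible: all randomness
flows from one seed through named per-stage substreams, and the summary
JSON is byte-identical for identical config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import assoc, diagnostics, io as iio, ld as ld_mod, qc, scan as scan_mod
from . import sim, spatial, structure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds plus data paths; serializes to/from YAML."""

    # data source
    simulate: bool = True
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    ped_path: str = ""
    map_path: str = ""
    sample_table_path: str = ""
    gene_bed_path: str = ""
    qtl_bed_path: str = ""
    # sample QC
    sample_callrate_min: float = 0.95
    pihat_max: float = 0.25
    # marker QC
    marker_callrate_min: float = 0.95
    maf_min: float = 0.05
    hwe_alpha: float = 1e-5
    ld_prune_r2: float = 0.50
    ld_prune_window: int = 50
    ld_prune_step: int = 5
    # scans
    fst_percentile: float = 99.999
    fst_window_bp: int = 500_000
    fst_window_min_snps: int = 4
    flk_fdr_max: float = 0.1
    gwas_fdr_max: float = 0.05
    # LD analysis
    ld_score_windows_bp: tuple = (500_000, 1_000_000)
    ld_max_pair_distance_kb: float = 2500.0
    # spatial / diagnostics / annotation
    moran_scheme: str = "inverse_distance"
    diagnostic_flank_bp: int = 1_000_000
    loess_span: float = 0.21
    annotation_flank_bp: int = 500_000
    colocation_bp: int = 100_000
    n_pca: int = 10
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["ld_score_windows_bp"] = list(self.ld_score_windows_bp)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"]["selected_loci"] = [tuple(t) for t in d["sim"].get("selected_loci", [])]
            d["sim"] = sim.SimConfig(**d["sim"])
        if "ld_score_windows_bp" in d:
            d["ld_score_windows_bp"] = tuple(d["ld_score_windows_bp"])
        return cls(**d)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def _round(x, nd=10):
    if x is None:
        return None
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return round(x, nd) if np.isfinite(x) else None
    if isinstance(x, (np.integer, int)):
        return int(x)
    return x


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute the full scan pipeline; returns the summary dictionary.

    Writes every stage table as TSV under ``out_dir`` plus
    ``summary.json``.  Identical config and seed give identical bytes.
    Any stage failure aborts with :class:`StageError` naming the stage.
    """
    tracker = {"stage": "load"}
    t0 = time.perf_counter()
    try:
        summary = _run_all(config, out_dir, tracker)
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage {tracker['stage']!r} failed: {err}") from err
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return summary


def _run_all(config: PipelineConfig, out_dir, tracker: dict) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- load or simulate -------------------------------------------------
    truth = None
    if config.simulate:
        simcfg = dataclasses.replace(config.sim, seed=config.sim.seed or config.seed)
        geno, markers, samples, truth = sim.simulate_dataset(simcfg)
    else:
        geno, markers, samples = iio.read_plink_text(config.ped_path, config.map_path)
        samples = iio.read_sample_table(config.sample_table_path)
        samples = samples[samples["sample_id"].isin(geno.sample_ids)].reset_index(drop=True)
    n_called_in = geno.n_called()
    summary["input"] = {
        "n_samples": geno.n_samples,
        "n_markers": geno.n_markers,
        "n_called_genotypes": n_called_in,
    }

    tracker["stage"] = "qc"
    # --- QC ---------------------------------------------------------------
    report = qc.QCReport(
        n_samples_in=geno.n_samples, n_markers_in=geno.n_markers
    )
    call_rates_all = dict(zip(geno.sample_ids, qc.sample_call_rates(geno)))
    geno_s, excl_cr = qc.sample_call_rate_filter(geno, config.sample_callrate_min)
    report.n_samples_excluded_callrate = len(excl_cr)
    pihat = qc.estimate_pihat(geno_s)
    kept_ids = qc.prune_related(pihat, config.pihat_max, call_rates=call_rates_all)
    report.n_samples_excluded_ibd = geno_s.n_samples - len(kept_ids)
    geno_s = geno_s.subset_sample_ids(kept_ids)
    geno_m, mreport = qc.marker_qc(
        geno_s, config.marker_callrate_min, config.maf_min, config.hwe_alpha
    )
    for f in (
        "n_markers_excluded_nonautosomal",
        "n_markers_excluded_callrate",
        "n_markers_excluded_maf",
        "n_markers_excluded_hwe",
    ):
        setattr(report, f, getattr(mreport, f))
    kept_markers = qc.ld_prune(
        geno_m, config.ld_prune_window, config.ld_prune_step, config.ld_prune_r2
    )
    report.n_markers_excluded_ldprune = geno_m.n_markers - len(kept_markers)
    keep_idx = np.flatnonzero(geno_m.markers["marker_id"].isin(kept_markers).to_numpy())
    geno_q = geno_m.take_markers(keep_idx)
    report.thresholds = {
        "sample_callrate_min": config.sample_callrate_min,
        "pihat_max": config.pihat_max,
        "marker_callrate_min": config.marker_callrate_min,
        "maf_min": config.maf_min,
        "hwe_alpha": config.hwe_alpha,
        "ld_prune_r2": config.ld_prune_r2,
    }
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    samples_q = samples.set_index("sample_id").loc[geno_q.sample_ids].reset_index()
    labels = samples_q["origin"].to_numpy()
    summary["qc"] = {
        "samples_in": report.n_samples_in,
        "samples_excluded_callrate": report.n_samples_excluded_callrate,
        "samples_excluded_ibd": report.n_samples_excluded_ibd,
        "samples_out": report.n_samples_out,
        "markers_in": report.n_markers_in,
        "markers_excluded": report.n_markers_excluded,
        "markers_out": report.n_markers_out,
        "markers_excluded_breakdown": {
            "nonautosomal": report.n_markers_excluded_nonautosomal,
            "callrate": report.n_markers_excluded_callrate,
            "maf": report.n_markers_excluded_maf,
            "hwe": report.n_markers_excluded_hwe,
            "ld_prune": report.n_markers_excluded_ldprune,
        },
    }

    tracker["stage"] = "structure"
    # --- structure --------------------------------------------------------
    K = structure.compute_grm(geno_q)
    pca = structure.pca_grm(K, k=min(config.n_pca, geno_q.n_samples))
    pca.to_frame().to_csv(out / "pca_scores.tsv", sep="\t", index=False,
                          float_format="%.6g")
    D_origin = structure.reynolds_distance_matrix(geno_q, labels)
    D_origin.to_csv(out / "reynolds_origin.tsv", sep="\t", float_format="%.6g")
    tree = structure.nj_tree(D_origin)
    (out / "population_tree.nwk").write_text(tree.newick + "\n")
    region_labels = samples_q["region"].to_numpy()
    if len(pd.unique(region_labels)) >= 2:
        D_region = structure.reynolds_distance_matrix(geno_q, region_labels)
        D_region.to_csv(out / "reynolds_region.tsv", sep="\t", float_format="%.6g")
    summary["structure"] = {
        "pc1_pct_variance": _round(pca.pct_variance[0], 4),
        "pc2_pct_variance": _round(pca.pct_variance[1], 4)
        if len(pca.pct_variance) > 1 else None,
        "reynolds_origin_distance": _round(D_origin.iloc[0, 1], 6),
    }

    tracker["stage"] = "scan"
    # --- selection scan ---------------------------------------------------
    fst = scan_mod.fst_per_snp(geno_q, labels)
    windows = scan_mod.smooth_fst_windows(
        fst, config.fst_window_bp, config.fst_window_min_snps
    )
    pop_freqs, _ = structure.population_frequencies(geno_q, labels)
    flk = scan_mod.flk_test(pop_freqs, tree)
    scan_table = pd.concat([fst.reset_index(drop=True), flk], axis=1)
    scan_table["flk_p_fdr"] = scan_mod.fdr_bh(scan_table["flk_p"])
    outliers = scan_mod.call_outliers(
        scan_table, windows, config.fst_percentile, config.flk_fdr_max
    )
    iio.write_scan_table(scan_table, out / "selection_scan.tsv")
    windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False, float_format="%.6g")
    summary["selection"] = {
        "fst_mean": _round(scan_table["theta_truncated"].mean(), 6),
        "fst_percentile_bound": _round(outliers.fst_threshold, 6),
        "window_percentile_bound": _round(outliers.window_threshold, 6),
        "n_fst_outliers": len(outliers.fst_outliers),
        "fst_outliers": outliers.fst_outliers,
        "n_window_outliers": len(outliers.window_outliers),
        "n_flk_significant": len(outliers.flk_significant),
        "joint_outliers": outliers.joint_outliers,
        "n_windows": len(windows),
    }

    tracker["stage"] = "ld"
    # --- LD ---------------------------------------------------------------
    ld_summary = {}
    score_medians = {}
    for origin in ("mainland", "island"):
        sub = geno_q.take_samples(np.flatnonzero(labels == origin))
        for win in config.ld_score_windows_bp:
            scores = ld_mod.ld_scores(sub, win)
            scores.to_csv(
                out / f"ld_scores_{origin}_{win // 1000}kb.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
            score_medians[(origin, win)] = float(scores["score"].median())
        pairs = ld_mod.ld_pairs(sub, config.ld_max_pair_distance_kb)
        fit = ld_mod.fit_ld_decay(
            pairs, config.ld_max_pair_distance_kb, origin=origin
        )
        ld_summary[origin] = fit.to_dict()
    for win in config.ld_score_windows_bp:
        a = pd.read_csv(out / f"ld_scores_mainland_{win // 1000}kb.tsv", sep="\t")
        b = pd.read_csv(out / f"ld_scores_island_{win // 1000}kb.tsv", sep="\t")
        stat, p = ld_mod.wilcoxon_rank_sum(a["score"], b["score"])
        ld_summary[f"wilcoxon_{win // 1000}kb"] = {
            "statistic": _round(stat, 4),
            "p_value": _round(p, 8),
            "median_mainland": _round(score_medians[("mainland", win)], 6),
            "median_island": _round(score_medians[("island", win)], 6),
        }
    summary["ld"] = {
        k: ({kk: _round(vv, 8) for kk, vv in v.items()} if isinstance(v, dict) else v)
        for k, v in ld_summary.items()
    }

    tracker["stage"] = "gwas"
    # --- GWAS -------------------------------------------------------------
    y = (labels == "mainland").astype(float)  # 0: island, 1: mainland
    null = assoc.fit_null_mixed_model(y, K)
    res = assoc.emmax_scan(geno_q, y, null, fdr_alpha=config.gwas_fdr_max)
    iio.write_scan_table(res.table, out / "gwas.tsv")
    res.qq.to_csv(out / "gwas_qq.tsv", sep="\t", index=False, float_format="%.6g")
    sig = res.table[res.table["significant"]]
    summary["gwas"] = {
        "lambda": _round(res.lambda_gc, 6),
        "h2_null": _round(null.heritability, 6),
        "n_significant": int(len(sig)),
        "significant_markers": sig["marker_id"].tolist(),
        "top_marker": (
            res.table.loc[res.table["p_value"].idxmin(), "marker_id"]
            if res.table["p_value"].notna().any() else None
        ),
        "top_p": _round(res.table["p_value"].min(), 12),
        "top_pve": _round(
            res.table.loc[res.table["p_value"].idxmin(), "pve"]
            if res.table["p_value"].notna().any() else None, 8
        ),
    }

    tracker["stage"] = "spatial"
    # --- spatial ----------------------------------------------------------
    coords = samples_q[["coord_x", "coord_y"]].to_numpy()
    sp = None
    if np.isfinite(coords).all():
        sp = spatial.moran_i(
            pca.scores[:, 0], coords, scheme=config.moran_scheme,
            jitter=1e-6, seed=config.seed,
        )
        nnd = spatial.nearest_neighbor_distances(coords)
        pd.DataFrame(
            {"sample_id": geno_q.sample_ids, "nn_distance": nnd}
        ).to_csv(out / "nearest_neighbor.tsv", sep="\t", index=False,
                 float_format="%.6g")
    summary["spatial"] = (
        {
            "moran_i": _round(sp.moran_i, 6),
            "expected_i": _round(sp.expected_i, 6),
            "z_score": _round(sp.z_score, 4),
            "p_value": _round(sp.p_value, 10),
            "weight_scheme": sp.weight_scheme,
        }
        if sp is not None else None
    )

    tracker["stage"] = "diagnose"
    # --- diagnostics around outliers -------------------------------------
    diag_labels = {}
    for mid in outliers.fst_outliers[:10]:
        try:
            profile = diagnostics.local_diagnostic_stats(
                geno_q, labels, mid, config.diagnostic_flank_bp, config.loess_span
            ).smooth()
        except ValueError:
            diag_labels[mid] = "inconclusive"
            continue
        cls = diagnostics.classify_selective_process(profile, config.colocation_bp)
        diag_labels[mid] = cls.label
        profile.table.to_csv(
            out / f"diagnostic_{mid}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    summary["diagnostics"] = diag_labels

    tracker["stage"] = "annotate"
    # --- annotation -------------------------------------------------------
    hits_n = None
    if config.gene_bed_path:
        genes = iio.read_features_bed(config.gene_bed_path, kind="gene")
        hits = annotate_mod.annotate_markers(
            geno_q, outliers.fst_outliers, genes, config.annotation_flank_bp
        )
        hits.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
        hits_n = int(len(hits))
    summary["annotation"] = {"n_gene_hits": hits_n}

    # --- truth (simulation only) ------------------------------------------
    if truth is not None:
        planted = [t[0] for t in truth.selected_markers]
        summary["truth"] = {
            "planted_markers": planted,
            "planted_recovered_fst": sorted(
                set(planted) & set(outliers.fst_outliers)
            ),
            "n_relative_pairs": len(truth.relative_pairs),
        }

    text = json.dumps(summary, sort_keys=True, indent=1)
    (out / "summary.json").write_text(text + "\n")
    return summary
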