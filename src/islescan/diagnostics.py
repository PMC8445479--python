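"""Loess profiles of F_ST and heterozygosity around outlier markers.

Around a focal (outlier) marker, three per-marker summaries are profiled in
a flanking window: truncated F_ST, the average observed heterozygosity of
the two populations (avHo), and their difference (dHo).  Each is smoothed
by local linear regression (tricube weights, no robustness iterations) and
the joint shape is classified:

* ``local_adaptation`` — the smoothed F_ST peak and the smoothed \\|dHo\\|
  peak both sit within a co-location margin of the focal marker, and
  smoothed avHo at the focal position is below the window median: the
  classic signature of a locally adapted allele (one population near
  fixation, the other still variable).
* ``not_local_adaptation`` — any of the three conditions fails.
* ``inconclusive`` — a curve is undefined (too few informative markers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import fst_per_snp
from .types import MISSING, GenotypeMatrix


def loess_smooth(x, y, span: float = 0.21) -> np.ndarray:
    """Degree-1 loess with tricube weights, evaluated at each input x.

    The neighbourhood of each point is its ``ceil(span * n)`` nearest x
    values (at least 2); no robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values")
    k = max(int(math.ceil(span * n)), 2)
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nearest = np.argsort(d, kind="stable")[:k]
        h = d[nearest].max()
        if h == 0:
            out[i] = y[nearest].mean()
            continue
        w = (1 - (d[nearest] / h) ** 3) ** 3
        w = np.clip(w, 0, None)
        if w.sum() == 0 or np.count_nonzero(w) < 2:
            out[i] = y[nearest].mean()
            continue
        xs, ys = x[nearest], y[nearest]
        sw = w.sum()
        xm = np.sum(w * xs) / sw
        ym = np.sum(w * ys) / sw
        sxx = np.sum(w * (xs - xm) ** 2)
        if sxx <= 0:
            out[i] = ym
            continue
        slope = np.sum(w * (xs - xm) * (ys - ym)) / sxx
        out[i] = ym + slope * (x[i] - xm)
    return out


@dataclass
class DiagnosticProfile:
    focal_marker: str
    focal_position: int
    chromosome: str
    table: pd.DataFrame  # marker_id, position_bp, fst, av_ho, d_ho (+ smoothed)
    span: float = 0.21
    excluded_markers: list = field(default_factory=list)

    def smooth(self) -> "DiagnosticProfile":
        t = self.table
        x = t["position_bp"].to_numpy(dtype=float)
        for col in ("fst", "av_ho", "d_ho"):
            t[f"{col}_smooth"] = loess_smooth(x, t[col].to_numpy(), self.span)
        return self


def local_diagnostic_stats(
    G: GenotypeMatrix,
    labels,
    focal_marker: str,
    flank_bp: int = 1_000_000,
    span: float = 0.21,
) -> DiagnosticProfile:
    """Raw F_ST / avHo / dHo profile in ``[pos - flank, pos + flank]``.

    Markers with no genotypes in one of the populations are excluded from
    the profile and listed in ``excluded_markers``.
    """
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    if len(pops) != 2:
        raise ValueError("diagnostic profile needs exactly 2 populations")
    j = G.marker_index(focal_marker)
    chrom = G.markers["chromosome"].iloc[j]
    pos0 = int(G.markers["position_bp"].iloc[j])
    in_win = (
        (G.markers["chromosome"] == chrom)
        & (G.markers["position_bp"] >= pos0 - flank_bp)
        & (G.markers["position_bp"] <= pos0 + flank_bp)
    ).to_numpy()
    idx = np.flatnonzero(in_win)
    if idx.size < 3:
        raise ValueError("fewer than 3 markers in the diagnostic window")
    sub = G.take_markers(idx)
    fst = fst_per_snp(sub, labels)

    ho = {}
    for pop in pops:
        vals = sub.values[labels == pop]
        called = (vals != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho[pop] = np.where(called > 0, (vals == 1).sum(axis=0) / called, np.nan)
    av_ho = (ho[pops[0]] + ho[pops[1]]) / 2.0
    d_ho = ho[pops[0]] - ho[pops[1]]

    table = pd.DataFrame(
        {
            "marker_id": sub.markers["marker_id"],
            "position_bp": sub.markers["position_bp"],
            "fst": fst["theta_truncated"].to_numpy(),
            "av_ho": av_ho,
            "d_ho": d_ho,
        }
    )
    bad = table[["fst", "av_ho", "d_ho"]].isna().any(axis=1)
    excluded = table.loc[bad, "marker_id"].tolist()
    table = table[~bad].reset_index(drop=True)
    return DiagnosticProfile(
        focal_marker=focal_marker,
        focal_position=pos0,
        chromosome=str(chrom),
        table=table,
        span=span,
        excluded_markers=excluded,
    )


@dataclass
class Classification:
    label: str  # local_adaptation | not_local_adaptation | inconclusive
    fst_peak_offset_bp: float
    dho_peak_offset_bp: float
    avho_focal_minus_median: float


def classify_selective_process(
    profile: DiagnosticProfile,
    colocation_bp: int = 100_000,
) -> Classification:
    """Operationalized reading of the local-adaptation loess pattern.

    ``local_adaptation`` requires (a) the smoothed F_ST maximum within
    ``colocation_bp`` of the focal marker, (b) the smoothed \\|dHo\\| maximum
    within the same margin, and (c) smoothed avHo at the focal position
    below the window median of smoothed avHo.
    """
    t = profile.table
    needed = {"fst_smooth", "av_ho_smooth", "d_ho_smooth"}
    if not needed.issubset(t.columns):
        profile.smooth()
        t = profile.table
    nan = float("nan")
    if len(t) == 0 or t[list(needed)].isna().any().any():
        return Classification("inconclusive", nan, nan, nan)
    pos = t["position_bp"].to_numpy(dtype=float)
    focal = profile.focal_position
    fst_peak = pos[int(np.argmax(t["fst_smooth"].to_numpy()))]
    dho_peak = pos[int(np.argmax(np.abs(t["d_ho_smooth"].to_numpy())))]
    i_focal = int(np.argmin(np.abs(pos - focal)))
    av = t["av_ho_smooth"].to_numpy()
    av_margin = float(av[i_focal] - np.median(av))
    off_fst = float(fst_peak - focal)
    off_dho = float(dho_peak - focal)
    ok = (
        abs(off_fst) <= colocation_bp
        and abs(off_dho) <= colocation_bp
        and av_margin < 0
    )
    return Classification(
        "local_adaptation" if ok else "not_local_adaptation",
        off_fst,
        off_dho,
        av_margin,
    )
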