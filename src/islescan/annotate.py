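"""Positional candidate-gene and QTL lookup around significant markers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GenotypeMatrix


def features_near_marker(
    chromosome: str,
    position_bp: int,
    features: pd.DataFrame,
    flank_bp: int = 500_000,
    marker_id: str = "",
) -> pd.DataFrame:
    """Features within ``flank_bp`` of a marker position, sorted by distance.

    Distance is 0 when the marker lies inside the (half-open, 1-based)
    feature interval, otherwise the gap to the nearest feature edge; the
    flank bound is inclusive.  Returns an empty frame when the chromosome
    has no features.
    """
    sel = features[features["chromosome"].astype(str) == str(chromosome)].copy()
    if len(sel) == 0:
        return _empty_hits()
    start = sel["start_bp"].to_numpy()
    end_incl = sel["end_bp"].to_numpy() - 1  # half-open -> last included bp
    inside = (position_bp >= start) & (position_bp <= end_incl)
    gap = np.minimum(np.abs(position_bp - start), np.abs(position_bp - end_incl))
    dist = np.where(inside, 0, gap)
    sel["distance_bp"] = dist.astype(np.int64)
    sel["marker_id"] = marker_id
    sel = sel[sel["distance_bp"] <= flank_bp]
    return (
        sel.sort_values(["distance_bp", "start_bp"], kind="stable")
        .reset_index(drop=True)[
            ["marker_id", "feature_id", "name", "kind", "chromosome",
             "start_bp", "end_bp", "distance_bp"]
        ]
    )


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "marker_id", "feature_id", "name", "kind", "chromosome",
            "start_bp", "end_bp", "distance_bp",
        ]
    )


def annotate_markers(
    G: GenotypeMatrix,
    marker_ids,
    features: pd.DataFrame,
    flank_bp: int = 500_000,
) -> pd.DataFrame:
    """Feature lookup for a set of marker ids from a genotype matrix's map."""
    frames = []
    mk = G.markers.set_index("marker_id")
    for mid in marker_ids:
        row = mk.loc[mid]
        frames.append(
            features_near_marker(
                row["chromosome"], int(row["position_bp"]), features,
                flank_bp=flank_bp, marker_id=mid,
            )
        )
    if not frames:
        return _empty_hits()
    return pd.concat(frames, ignore_index=True)
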