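"""Core data containers shared by every pipeline stage.

Conventions used throughout the package:

* Genotypes are stored as integer dosages of ``allele_b`` (the *counted*
  allele, i.e. the second allele column of a MAP/BIM record), with ``-1``
  marking a missing call.
* Marker positions are 1-based inclusive at I/O boundaries; every internal
  window computation uses half-open ``[start, end)`` intervals in bp.
* Chromosome labels are strings; only labels in the configured autosome set
  ("1".."26" by default, the Ovis aries autosomes) are retained by QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Default autosome labels (sheep have 26 autosome pairs).
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 27))

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
FEATURE_COLUMNS = ["feature_id", "chromosome", "start_bp", "end_bp", "kind", "name"]


def make_marker_map(
    marker_id, chromosome, position_bp, allele_a="A", allele_b="B"
) -> pd.DataFrame:
    """Assemble a marker map frame, sorted by (chromosome, position)."""
    df = pd.DataFrame(
        {
            "marker_id": np.asarray(marker_id, dtype=object),
            "chromosome": np.asarray(chromosome, dtype=object).astype(str),
            "position_bp": np.asarray(position_bp, dtype=np.int64),
        }
    )
    df["allele_a"] = allele_a
    df["allele_b"] = allele_b
    validate_marker_map(df)
    return df


def validate_marker_map(markers: pd.DataFrame) -> None:
    if list(markers.columns[:3]) != MARKER_COLUMNS[:3]:
        raise ValueError(f"marker map must start with columns {MARKER_COLUMNS[:3]}")
    if markers["marker_id"].duplicated().any():
        dup = markers.loc[markers["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker id: {dup!r}")
    if (markers["position_bp"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based)")


def sort_markers(markers: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sort by (chromosome, position); return (sorted frame, take-order)."""
    order = np.lexsort(
        (markers["position_bp"].to_numpy(), markers["chromosome"].to_numpy())
    )
    return markers.iloc[order].reset_index(drop=True), order


@dataclass
class GenotypeMatrix:
    """``n_samples x n_markers`` dosage matrix with its marker map.

    ``values[i, j]`` is the number of copies of ``allele_b`` of marker ``j``
    carried by sample ``i`` (0, 1 or 2), or :data:`MISSING`.
    """

    values: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x markers)")
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} genotype rows but {len(self.sample_ids)} sample ids"
            )
        if m != len(self.markers):
            raise ValueError(
                f"{m} genotype columns but {len(self.markers)} map records"
            )
        valid = np.isin(self.values, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = self.values[~valid].ravel()[0]
            raise ValueError(f"invalid dosage value {bad!r}")
        validate_marker_map(self.markers)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def n_called(self) -> int:
        """Number of non-missing genotype calls (conservation audits)."""
        return int((self.values != MISSING).sum())

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[index],
            [self.sample_ids[i] for i in index],
            self.markers,
        )

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[:, index],
            self.sample_ids,
            self.markers.iloc[index].reset_index(drop=True),
        )

    def subset_sample_ids(self, keep_ids) -> "GenotypeMatrix":
        keep = set(keep_ids)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return self.take_samples(idx)

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.markers["marker_id"] == marker_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"marker {marker_id!r} not found")
        return int(hits[0])


def make_sample_table(
    sample_id, origin, region=None, herd=None, coord_x=None, coord_y=None
) -> pd.DataFrame:
    """Assemble a sample table (origin must be 'mainland' or 'island')."""
    sample_id = list(sample_id)
    n = len(sample_id)
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "origin": list(origin),
            "region": list(region) if region is not None else [""] * n,
            "herd": list(herd) if herd is not None else [""] * n,
            "coord_x": np.full(n, np.nan) if coord_x is None else np.asarray(coord_x, float),
            "coord_y": np.full(n, np.nan) if coord_y is None else np.asarray(coord_y, float),
        }
    )
    validate_sample_table(df)
    return df


def validate_sample_table(samples: pd.DataFrame) -> None:
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    bad = ~samples["origin"].isin(["mainland", "island"])
    if bad.any():
        raise ValueError(
            f"origin must be 'mainland' or 'island', got {samples.loc[bad, 'origin'].iloc[0]!r}"
        )


def make_feature_table(feature_id, chromosome, start_bp, end_bp, kind, name) -> pd.DataFrame:
    """Assemble a feature table; intervals are half-open [start_bp, end_bp) 1-based."""
    df = pd.DataFrame(
        {
            "feature_id": list(feature_id),
            "chromosome": np.asarray(chromosome, dtype=object).astype(str),
            "start_bp": np.asarray(start_bp, dtype=np.int64),
            "end_bp": np.asarray(end_bp, dtype=np.int64),
            "kind": list(kind),
            "name": list(name),
        }
    )
    if (df["start_bp"] > df["end_bp"]).any():
        raise ValueError("feature start_bp must be <= end_bp")
    return df
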