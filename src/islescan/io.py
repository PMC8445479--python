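"""PLINK text/binary genotype I/O, feature tables, and tabular outputs.

Allele bookkeeping
------------------
``allele_b`` — the counted allele — is the second allele column of a BIM
record.  PED/MAP carries no allele columns, so the text reader infers the
two alleles per marker from the data and assigns the lexicographically
greater one to ``allele_b`` (a marker where only one allele is observed gets
``allele_a = "0"``).  MAF, F_ST and r² are invariant to this choice;
association effect signs are not.

Positions are 1-based inclusive in all PLINK/BED/GFF3 files and converted to
the package convention at the boundary (see :mod:`islescan.types`).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges

from .types import (
    MISSING,
    GenotypeMatrix,
    make_feature_table,
    make_marker_map,
    make_sample_table,
    sort_markers,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"


class PlinkFormatError(ValueError):
    """Raised when a PLINK file does not follow the expected layout."""


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) == 3:  # chrom, id, bp (no cM column)
                chrom, mid, bp = tok
            elif len(tok) == 4:
                chrom, mid, _cm, bp = tok
            else:
                raise PlinkFormatError(f"{map_path}:{lineno}: expected 3 or 4 fields")
            rows.append((mid, chrom, int(bp)))
    ids, chroms, pos = zip(*rows) if rows else ((), (), ())
    return make_marker_map(list(ids), list(chroms), list(pos))


def read_plink_text(ped_path, map_path):
    """Read a PED/MAP pair.

    Returns ``(GenotypeMatrix, MarkerMap, SampleTable)`` with markers sorted
    by (chromosome, position).  ``0 0`` genotypes become missing; more than
    two observed alleles at a marker is a format error naming the marker.
    The sample table carries family id as ``herd`` and an empty origin
    placeholder resolved by the caller (PED has no origin column).
    """
    markers = _read_map(map_path)
    m = len(markers)
    sample_ids, herds = [], []
    with open(ped_path) as fh:
        raw = [line.split() for line in fh if line.strip()]
    if not raw:
        raise PlinkFormatError(f"{ped_path}: empty PED file")
    a1 = np.empty((len(raw), m), dtype="U16")
    a2 = np.empty((len(raw), m), dtype="U16")
    for i, tok in enumerate(raw):
        if len(tok) != 6 + 2 * m:
            raise PlinkFormatError(
                f"{ped_path}:{i + 1}: expected {6 + 2 * m} fields, got {len(tok)}"
            )
        fid, iid = tok[0], tok[1]
        sample_ids.append(iid)
        herds.append(fid)
        a1[i] = tok[6::2]
        a2[i] = tok[7::2]
    values = np.full((len(raw), m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        c1, c2 = a1[:, j], a2[:, j]
        called = (c1 != "0") & (c2 != "0")
        alleles = sorted(set(c1[called]) | set(c2[called]))
        if len(alleles) > 2:
            raise PlinkFormatError(
                f"marker {markers['marker_id'].iloc[j]!r}: more than two alleles "
                f"({', '.join(alleles)})"
            )
        if len(alleles) == 0:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        if len(alleles) == 1:
            allele_a[j], allele_b[j] = "0", alleles[0]
        else:
            allele_a[j], allele_b[j] = alleles
        values[called, j] = (c1[called] == allele_b[j]).astype(np.int8) + (
            c2[called] == allele_b[j]
        ).astype(np.int8)
    markers["allele_a"] = allele_a
    markers["allele_b"] = allele_b
    markers, order = sort_markers(markers)
    values = values[:, order]
    geno = GenotypeMatrix(values, sample_ids, markers)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "origin": "",
            "region": "",
            "herd": herds,
            "coord_x": np.nan,
            "coord_y": np.nan,
        }
    )
    logger.info(
        "read %d samples x %d markers from %s (%d called genotypes)",
        geno.n_samples, geno.n_markers, ped_path, geno.n_called(),
    )
    return geno, markers, samples


def write_plink_text(geno: GenotypeMatrix, ped_path, map_path, samples=None) -> None:
    """Write a PED/MAP pair (inverse of :func:`read_plink_text`)."""
    mk = geno.markers
    with open(map_path, "w") as fh:
        for row in mk.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")
    herd = {}
    if samples is not None:
        herd = dict(zip(samples["sample_id"], samples["herd"]))
    aa = mk["allele_a"].to_numpy()
    ab = mk["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.sample_ids):
            fid = herd.get(sid, "0") or "0"
            row = [str(fid), sid, "0", "0", "0", "-9"]
            v = geno.values[i]
            for j, d in enumerate(v):
                if d == MISSING:
                    row += ["0", "0"]
                elif d == 0:
                    row += [aa[j], aa[j]]
                elif d == 1:
                    row += [aa[j], ab[j]]
                else:
                    row += [ab[j], ab[j]]
            fh.write(" ".join(row) + "\n")


# 2-bit PLINK .bed codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# allele_a = BIM column 5 (A1), allele_b = BIM column 6 (A2, counted).
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink_binary(bed_path, bim_path, fam_path):
    """Read a BED/BIM/FAM triple (SNP-major mode only)."""
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele_a", "allele_b"],
        dtype={"chromosome": str, "marker_id": str, "allele_a": str, "allele_b": str},
    )
    markers = make_marker_map(
        bim["marker_id"], bim["chromosome"], bim["position_bp"],
        bim["allele_a"].to_numpy(), bim["allele_b"].to_numpy(),
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    sample_ids = fam["iid"].tolist()
    n, m = len(sample_ids), len(markers)
    data = Path(bed_path).read_bytes()
    if data[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {data[:2]!r}")
    if data[2:3] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: not SNP-major mode")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes, got {body.size}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, least-significant pair first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    values = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    markers_sorted, order = sort_markers(markers)
    geno = GenotypeMatrix(values[:, order], sample_ids, markers_sorted)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "origin": "",
            "region": "",
            "herd": fam["fid"].tolist(),
            "coord_x": np.nan,
            "coord_y": np.nan,
        }
    )
    return geno, markers_sorted, samples


def write_plink_binary(geno: GenotypeMatrix, bed_path, bim_path, fam_path, samples=None) -> None:
    """Write a BED/BIM/FAM triple in SNP-major mode."""
    mk = geno.markers
    with open(bim_path, "w") as fh:
        for row in mk.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}"
                f"\t{row.allele_a}\t{row.allele_b}\n"
            )
    herd = {}
    if samples is not None:
        herd = dict(zip(samples["sample_id"], samples["herd"]))
    with open(fam_path, "w") as fh:
        for sid in geno.sample_ids:
            fid = herd.get(sid, "0") or "0"
            fh.write(f"{fid} {sid} 0 0 0 -9\n")
    n, m = geno.n_samples, geno.n_markers
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b00, dtype=np.uint8)
    code_lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        code_lut[dosage % 4] = code  # MISSING=-1 maps to index 3
    padded[:, :n] = code_lut[geno.values.T % 4]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())


def read_sample_table(path) -> pd.DataFrame:
    """Read a TSV sample table (sample_id, origin, region, herd, coord_x, coord_y)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "herd": str, "region": str})
    return make_sample_table(
        df["sample_id"], df["origin"],
        df.get("region"), df.get("herd"), df.get("coord_x"), df.get("coord_y"),
    )


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_scan_table(table: pd.DataFrame, path) -> None:
    """Write a per-marker scan table as TSV, deterministic float formatting."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty scan table")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_scan_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})


def read_features_bed(path, kind: str = "gene") -> pd.DataFrame:
    """Read feature intervals from BED (0-based half-open on disk)."""
    df = pyranges.read_bed(str(path)).df
    name = df["Name"] if "Name" in df else df["Chromosome"].astype(str)
    return make_feature_table(
        feature_id=[f"{kind}{i}" for i in range(len(df))],
        chromosome=df["Chromosome"].astype(str),
        start_bp=df["Start"] + 1,  # -> 1-based half-open
        end_bp=df["End"] + 1,
        kind=[kind] * len(df),
        name=name,
    )


def read_features_gff3(path, kind: str = "gene", feature_types=("gene",)) -> pd.DataFrame:
    """Read feature intervals from GFF3 (1-based inclusive on disk)."""
    df = pyranges.read_gff3(str(path)).df
    df = df[df["Feature"].isin(feature_types)].reset_index(drop=True)
    if "Name" in df:
        name = df["Name"].fillna("")
    elif "ID" in df:
        name = df["ID"].fillna("")
    else:
        name = pd.Series([""] * len(df))
    # pyranges already converted to 0-based half-open
    return make_feature_table(
        feature_id=[f"{kind}{i}" for i in range(len(df))],
        chromosome=df["Chromosome"].astype(str),
        start_bp=df["Start"] + 1,
        end_bp=df["End"] + 1,
        kind=[kind] * len(df),
        name=name,
    )
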