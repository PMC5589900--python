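"""Readers/writers for the tabular formats the pipeline touches, plus probe QC.

Formats
-------
* beta matrix: TSV/CSV, first column ``probe_id``, one column per sample,
  values in [0, 1] or empty (missing).
* segment table: SEG-like TSV with columns ``sample, chrom, start, end,
  total_cn, minor_cn``; coordinates 1-based inclusive on disk, converted to
  0-based half-open on read.
* region BED: 3+ columns extended with ``region_id, klass, methylated_parent``.
* RRBS site table: TSV ``chrom, pos, meth_count, total_count``.
* anatomy table: TSV ``chrom, length, centromere_start, centromere_end``.

All readers are gzip-transparent (any path ending in ``.gz``).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MANIFEST_COLUMNS,
    REGION_COLUMNS,
    SEGMENT_COLUMNS,
    BetaMatrix,
    ChromosomeAnatomy,
    validate_regions,
)

log = logging.getLogger(__name__)

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# -- beta matrix -------------------------------------------------------------

def read_beta_matrix(path, dialect: str = "tsv") -> BetaMatrix:
    """Read a probe x sample methylation matrix.

    Empty cells become NaN (missing), never zero.  A non-numeric or
    out-of-range cell raises :class:`ValueError` naming the probe and sample.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    raw = pd.read_csv(
        _open_text(path), sep=sep, dtype=str, index_col=0, keep_default_na=False
    )
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate probe_id {dup!r} in {path}")
    beta = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip().replace("", np.nan)
        num = pd.to_numeric(cells, errors="coerce")
        bad = cells.notna() & num.isna()
        if bad.any():
            probe = cells.index[bad][0]
            raise ValueError(
                f"non-numeric beta value {cells[bad].iloc[0]!r} at probe "
                f"{probe!r}, sample {col!r} in {path}"
            )
        beta[col] = num
    beta.index.name = "probe_id"
    return BetaMatrix(beta)


def write_beta_matrix(bm: BetaMatrix, path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    with _open_text(path, "wt") as fh:
        bm.beta.to_csv(fh, sep=sep, index_label="probe_id", float_format="%.17g")


# -- probe manifest ----------------------------------------------------------

def read_probe_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV; SNP columns may be empty (absent)."""
    df = pd.read_csv(_open_text(path), sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df = df[MANIFEST_COLUMNS].copy()
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r} in manifest")
    if (df["pos"] < 0).any():
        raise ValueError("manifest probe positions must be >= 0")
    maf = df["nearest_snp_maf"]
    if ((maf < 0) | (maf > 1)).any():
        raise ValueError("nearest_snp_maf must lie in [0, 1]")
    return df


def write_probe_manifest(manifest: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        manifest[MANIFEST_COLUMNS].to_csv(fh, sep="\t", index=False)


# -- allele-specific segments ------------------------------------------------

def read_segments(path) -> pd.DataFrame:
    """Read a SEG-like allele-specific copy-number table.

    On-disk coordinates are 1-based inclusive; the returned DataFrame
    (:data:`~imprintcna.core.SEGMENT_COLUMNS`) is 0-based half-open.
    Validation: ``minor_cn`` must be the smaller allele count, and segments
    within one sample/chromosome must not overlap (abutting is fine).
    """
    df = pd.read_csv(_open_text(path), sep="\t", dtype={"sample": str, "chrom": str})
    required = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    df = df.rename(columns={"sample": "sample_id"})
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    return validate_segments(df[SEGMENT_COLUMNS])


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    df = df[SEGMENT_COLUMNS].copy()
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"segment with start >= end for sample {bad.sample_id!r} on {bad.chrom}"
        )
    bad_minor = df["minor_cn"] > df["total_cn"] - df["minor_cn"]
    if bad_minor.any():
        bad = df[bad_minor].iloc[0]
        raise ValueError(
            f"minor_cn {bad.minor_cn} exceeds the major allele count for "
            f"total_cn {bad.total_cn} (sample {bad.sample_id!r}, {bad.chrom})"
        )
    if (df["minor_cn"] < 0).any():
        raise ValueError("negative minor_cn")
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if overlap.any():
            raise ValueError(
                f"overlapping segments for sample {sample!r} on {chrom}"
            )
    return df.reset_index(drop=True)


def write_segments(df: pd.DataFrame, path) -> None:
    """Write segments back to the 1-based inclusive SEG-like dialect."""
    out = df[SEGMENT_COLUMNS].copy()
    out["start"] = out["start"] + 1
    out = out.rename(columns={"sample_id": "sample"})
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


# -- region BED --------------------------------------------------------------

def read_regions_bed(path) -> pd.DataFrame:
    """Read an extended BED (chrom, start, end, region_id, klass, parent)."""
    df = pd.read_csv(
        _open_text(path),
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "region_id", "klass", "methylated_parent"],
        dtype={"chrom": str, "region_id": str},
        comment="#",
    )
    return validate_regions(df[REGION_COLUMNS])


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "region_id", "klass", "methylated_parent"]
    with _open_text(path, "wt") as fh:
        regions[cols].to_csv(fh, sep="\t", index=False, header=False)


# -- chromosome anatomy ------------------------------------------------------

def read_anatomy(path) -> dict[str, ChromosomeAnatomy]:
    df = pd.read_csv(_open_text(path), sep="\t", dtype={"chrom": str})
    required = ["chrom", "length", "centromere_start", "centromere_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"anatomy table missing columns: {missing}")
    return {
        row.chrom: ChromosomeAnatomy(
            row.chrom, int(row.length), int(row.centromere_start), int(row.centromere_end)
        )
        for row in df.itertuples()
    }


def write_anatomy(anatomy: dict[str, ChromosomeAnatomy], path) -> None:
    rows = [
        (a.chrom, a.length_bp, a.centromere_start, a.centromere_end)
        for a in anatomy.values()
    ]
    df = pd.DataFrame(rows, columns=["chrom", "length", "centromere_start", "centromere_end"])
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


# -- RRBS sites --------------------------------------------------------------

def read_rrbs_sites(path) -> pd.DataFrame:
    df = pd.read_csv(_open_text(path), sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "meth_count", "total_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"RRBS site table missing columns: {missing}")
    df = df[required].copy()
    if (df["meth_count"] > df["total_count"]).any():
        raise ValueError("RRBS site with meth_count > total_count")
    if (df["total_count"] < 1).any():
        raise ValueError("RRBS site with non-positive total_count")
    return df


def write_rrbs_sites(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        df[["chrom", "pos", "meth_count", "total_count"]].to_csv(fh, sep="\t", index=False)


# -- probe QC ----------------------------------------------------------------

def filter_probes(
    bm: BetaMatrix,
    manifest: pd.DataFrame,
    *,
    detection_p_max: float = 0.01,
    detection_sample_frac: float = 0.10,
    snp_flank_bp: int = 5,
    snp_maf_min: float = 0.01,
    drop_sex_chroms: bool = True,
) -> tuple[BetaMatrix, dict[str, int]]:
    """Apply the array QC cascade and return (filtered matrix, removal counts).

    Rules, applied in sequence to the probes still standing:

    1. detection p-value > ``detection_p_max`` in strictly more than
       ``detection_sample_frac`` of samples (skipped when no detection matrix);
    2. any missing beta value in the remaining samples;
    3. a common SNP (MAF >= ``snp_maf_min``) within ``snp_flank_bp`` of the
       interrogated CpG;
    4. probes on chrX/chrY.

    The counts dictionary reconciles: removals across rules plus ``retained``
    equals the input probe count.
    """
    man = manifest.set_index("probe_id")
    unknown = [p for p in bm.probes if p not in man.index]
    if unknown:
        raise ValueError(f"{len(unknown)} probes absent from manifest, e.g. {unknown[0]!r}")

    counts: dict[str, int] = {"input": len(bm.probes)}
    current = bm

    if current.detection_p is not None:
        n_samples = len(current.samples)
        frac_failed = (current.detection_p > detection_p_max).sum(axis=1) / n_samples
        keep = frac_failed <= detection_sample_frac  # "more than 10%" is strict
        counts["detection_p"] = int((~keep).sum())
        current = current.subset_probes(current.beta.index[keep])
    else:
        counts["detection_p"] = 0

    has_missing = current.beta.isna().any(axis=1)
    counts["missing_values"] = int(has_missing.sum())
    current = current.subset_probes(current.beta.index[~has_missing])

    sub = man.loc[current.beta.index]
    dist = sub["nearest_snp_distance_bp"]
    maf = sub["nearest_snp_maf"]
    snp_hit = dist.notna() & maf.notna() & (dist <= snp_flank_bp) & (maf >= snp_maf_min)
    counts["snp_proximal"] = int(snp_hit.sum())
    current = current.subset_probes(current.beta.index[~snp_hit.to_numpy()])

    if drop_sex_chroms:
        on_sex = man.loc[current.beta.index, "chrom"].isin(_SEX_CHROMS)
        counts["sex_chrom"] = int(on_sex.sum())
        current = current.subset_probes(current.beta.index[~on_sex.to_numpy()])
    else:
        counts["sex_chrom"] = 0

    counts["retained"] = len(current.probes)
    if counts["retained"] == 0:
        log.warning("probe QC removed every probe")
    return current, counts


# -- RRBS aggregation --------------------------------------------------------

def aggregate_rrbs_regions(
    sites: pd.DataFrame, regions: pd.DataFrame, min_coverage: int = 10
) -> pd.Series:
    """Per-region mean methylation from RRBS site counts.

    Site methylation is ``meth_count / total_count``; sites with coverage below
    ``min_coverage`` are excluded; the region value is the unweighted mean of
    surviving sites (NaN when none survive).  A site belongs to a region when
    ``start <= pos < end``.
    """
    regions = validate_regions(regions)
    ok = sites[sites["total_count"] >= min_coverage]
    frac = ok["meth_count"] / ok["total_count"]
    out = pd.Series(np.nan, index=regions["region_id"], name="methylation", dtype=float)
    for chrom, grp in ok.assign(frac=frac).groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        vals = grp["frac"].to_numpy()
        for row in regions[regions["chrom"] == chrom].itertuples():
            mask = (pos >= row.start) & (pos < row.end)
            if mask.any():
                out[row.region_id] = float(vals[mask].mean())
    return out
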