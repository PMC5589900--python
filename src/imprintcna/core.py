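"""Shared domain types and vocabulary for the copy-number-aware imprint analysis.

Tabular data (region sets, segment tables, manifests, truth tables) travels as
plain :class:`pandas.DataFrame` objects with documented column contracts, in
the style of pyranges / scanpy ``.obs`` tables; small record-like values are
frozen dataclasses.  All genomic intervals are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# -- controlled vocabularies -------------------------------------------------

KLASSES = ("imprinted_dmr", "cimp", "bivalent", "dmv")
PARENTS = ("maternal", "paternal", "none")
ABERRATIONS = ("normal", "amplification", "deletion", "cnnloh")
BOUNDEDNESS = ("internal", "telomere_bound", "centromere_bound", "not_applicable")
METH_STATES = (
    "normal",
    "hypermethylated",
    "hypomethylated",
    "intermediate_gain",
    "intermediate_loss",
)
SEVERITIES = ("unaffected", "lowly", "mildly", "highly")
EPIMUTATION_KINDS = ("none", "hyper", "hypo", "intermediate")

#: columns of a region-set DataFrame
REGION_COLUMNS = ["region_id", "chrom", "start", "end", "klass", "methylated_parent"]

#: columns of an allele-specific segment DataFrame (0-based half-open)
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "total_cn", "minor_cn"]

#: columns of a probe manifest DataFrame
MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "nearest_snp_distance_bp",
    "nearest_snp_maf",
    "region_id",
]


@dataclass(frozen=True)
class CopyNumberSegment:
    """One allele-specific copy-number interval for one sample.

    ``minor_cn`` is the copy count of the less-abundant parental allele, so
    ``minor_cn <= total_cn - minor_cn`` always holds.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy counts must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds the major allele count for "
                f"total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChromosomeAnatomy:
    """Chromosome length and centromere interval (0-based half-open)."""

    chrom: str
    length_bp: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end < self.length_bp):
            raise ValueError(
                f"invalid anatomy for {self.chrom}: centromere "
                f"[{self.centromere_start}, {self.centromere_end}) must lie "
                f"strictly inside (0, {self.length_bp})"
            )


@dataclass
class BetaMatrix:
    """Probe-level methylation fractions (probes x samples).

    ``beta`` holds values in [0, 1] with missing entries as NaN; ``detection_p``
    is an optional matrix of detection p-values with identical shape and axes.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value {vals[i, j]} out of [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        if self.beta.index.has_duplicates:
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id {dup!r}")
        if self.beta.columns.has_duplicates:
            dup = self.beta.columns[self.beta.columns.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if self.detection_p is not None:
            if not (
                self.detection_p.index.equals(self.beta.index)
                and self.detection_p.columns.equals(self.beta.columns)
            ):
                raise ValueError("detection_p axes do not match beta axes")

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        keep = self.beta.index.isin(set(probe_ids))
        det = self.detection_p.loc[keep] if self.detection_p is not None else None
        return BetaMatrix(self.beta.loc[keep], det)


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Validate a region-set DataFrame and return it (column order normalised)."""
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ValueError(f"region table missing columns: {missing}")
    df = regions[REGION_COLUMNS].copy()
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValueError(f"duplicate region_id {dup!r}")
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "region_id"].iloc[0]
        raise ValueError(f"region {bad!r} has start >= end")
    unknown = set(df["klass"]) - set(KLASSES)
    if unknown:
        raise ValueError(f"unknown region klass values: {sorted(unknown)}")
    imp = df["klass"] == "imprinted_dmr"
    if (df.loc[imp, "methylated_parent"] == "none").any():
        bad = df.loc[imp & (df["methylated_parent"] == "none"), "region_id"].iloc[0]
        raise ValueError(f"imprinted DMR {bad!r} lacks a germline-methylated parent")
    if (df.loc[~imp, "methylated_parent"] != "none").any():
        bad = df.loc[~imp & (df["methylated_parent"] != "none"), "region_id"].iloc[0]
        raise ValueError(f"non-imprinted region {bad!r} carries a parent annotation")
    return df


def other_parent(parent: str) -> str:
    if parent == "maternal":
        return "paternal"
    if parent == "paternal":
        return "maternal"
    raise ValueError(f"no opposite parent for {parent!r}")
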