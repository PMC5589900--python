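"""Allele-specific copy-number states at imprinted loci.

Assigns every (sample, region) pair a copy state from segmented
allele-specific copy-number calls, classifies the aberration (deletion,
amplification, copy-neutral LOH) and whether the underlying segment is focal
("internal") or anchored at a telomere/centromere, and estimates a per-sample
baseline ploidy so gains and losses can also be read relative to a hyperploid
genome.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    ChromosomeAnatomy,
    CopyNumberSegment,
    validate_regions,
)

#: columns of the locus copy-state table produced by :func:`overlap_locus_state`
STATE_COLUMNS = [
    "sample_id",
    "region_id",
    "total_cn",
    "minor_cn",
    "assumed",
    "ploidy_ratio",
    "cnnloh",
    "aberration",
    "boundedness",
    "seg_start",
    "seg_end",
    "seg_length",
]

INTERNAL_DISTANCE_BP = 1_000_000  # strict: exactly 1 Mb away is still bound


def is_cnnloh(total_cn: int, minor_cn: int) -> bool:
    """Copy-neutral LOH: one parental allele lost, the other in >= 2 copies."""
    return minor_cn == 0 and total_cn >= 2


def classify_aberration(total_cn: int, minor_cn: int) -> str:
    """Aberration class relative to the diploid 2:1 state.

    cnnLOH takes precedence; otherwise total copies above/below 2 are
    amplification/deletion.  The only normal state is exactly 2:1.
    """
    if is_cnnloh(total_cn, minor_cn):
        return "cnnloh"
    if total_cn > 2:
        return "amplification"
    if total_cn < 2:
        return "deletion"
    return "normal"


def estimate_baseline_ploidy(segments: pd.DataFrame | list[CopyNumberSegment]) -> int:
    """Length-weighted median total copy number, rounded half-up (minimum 1).

    The median is robust to focal high-copy amplifications, so a genome that is
    mostly 4:2 reports baseline 4 even with a few 14-copy segments.
    """
    if isinstance(segments, list):
        if not segments:
            raise ValueError("cannot estimate ploidy from zero segments")
        totals = np.array([s.total_cn for s in segments], dtype=float)
        weights = np.array([s.length for s in segments], dtype=float)
    else:
        if len(segments) == 0:
            raise ValueError("cannot estimate ploidy from zero segments")
        totals = segments["total_cn"].to_numpy(dtype=float)
        weights = (segments["end"] - segments["start"]).to_numpy(dtype=float)

    order = np.argsort(totals, kind="stable")
    totals, weights = totals[order], weights[order]
    cum = np.cumsum(weights)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="left"))
    if math.isclose(cum[i], half) and i + 1 < len(totals):
        median = (totals[i] + totals[i + 1]) / 2.0
    else:
        median = totals[i]
    return max(1, math.floor(median + 0.5))


def classify_boundedness(
    segment: CopyNumberSegment,
    anatomy: ChromosomeAnatomy,
    internal_distance_bp: int = INTERNAL_DISTANCE_BP,
) -> str:
    """Internal vs telomere-/centromere-bound classification of a segment.

    A segment is internal when its nearest anchor (either telomere or the
    centromere interval) is strictly more than 1 Mb away; otherwise it takes
    the class of the nearer anchor, ties going to the telomere.
    """
    d_tel = min(segment.start, anatomy.length_bp - segment.end)
    if segment.end <= anatomy.centromere_start:
        d_cen = anatomy.centromere_start - segment.end
    elif segment.start >= anatomy.centromere_end:
        d_cen = segment.start - anatomy.centromere_end
    else:
        d_cen = 0
    if min(d_tel, d_cen) > internal_distance_bp:
        return "internal"
    return "telomere_bound" if d_tel <= d_cen else "centromere_bound"


def overlap_locus_state(
    segments: pd.DataFrame,
    regions: pd.DataFrame,
    anatomy: dict[str, ChromosomeAnatomy],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Assign a copy state to every (sample, region) pair.

    A segment is eligible if it overlaps the region by at least 1 bp.  When
    several segments overlap, the one covering the most of the region wins,
    ties broken toward the higher total copy number.  Regions with no covering
    segment default to the diploid 2:1 state with ``assumed=True``.

    ``samples`` extends the output to samples absent from the segment table
    (they receive assumed-diploid states everywhere); output has exactly one
    row per (sample, region).
    """
    regions = validate_regions(regions)
    bad = set(regions["chrom"]) - set(anatomy)
    if bad:
        raise ValueError(f"regions on chromosomes absent from anatomy: {sorted(bad)}")

    if samples is None:
        samples = list(pd.unique(segments["sample_id"]))
    else:
        samples = list(samples)
        extra = set(pd.unique(segments["sample_id"])) - set(samples)
        if extra:
            raise ValueError(f"segment table has samples not in sample list: {sorted(extra)}")

    by_sample_chrom = {
        key: grp.sort_values("start")
        for key, grp in segments.groupby(["sample_id", "chrom"], sort=False)
    }
    baselines = {}
    for sample in samples:
        segs = segments[segments["sample_id"] == sample]
        baselines[sample] = estimate_baseline_ploidy(segs) if len(segs) else 2

    rows = []
    for sample in samples:
        baseline = baselines[sample]
        for reg in regions.itertuples():
            grp = by_sample_chrom.get((sample, reg.chrom))
            winner = None
            if grp is not None:
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                overlap = np.minimum(ends, reg.end) - np.maximum(starts, reg.start)
                eligible = overlap >= 1
                if eligible.any():
                    cand = grp[eligible].assign(_overlap=overlap[eligible])
                    cand = cand.sort_values(
                        ["_overlap", "total_cn"], ascending=False, kind="stable"
                    )
                    winner = cand.iloc[0]
            if winner is None:
                total, minor, assumed = 2, 1, True
                seg_start = seg_end = seg_len = np.nan
                bound = "not_applicable"
            else:
                total, minor = int(winner.total_cn), int(winner.minor_cn)
                assumed = False
                seg_start, seg_end = int(winner.start), int(winner.end)
                seg_len = seg_end - seg_start
                aberr = classify_aberration(total, minor)
                if aberr == "normal":
                    bound = "not_applicable"
                else:
                    seg = CopyNumberSegment(
                        sample, reg.chrom, seg_start, seg_end, total, minor
                    )
                    bound = classify_boundedness(seg, anatomy[reg.chrom])
            rows.append(
                (
                    sample,
                    reg.region_id,
                    total,
                    minor,
                    assumed,
                    total / baseline,
                    is_cnnloh(total, minor),
                    classify_aberration(total, minor),
                    bound,
                    seg_start,
                    seg_end,
                    seg_len,
                )
            )
    return pd.DataFrame(rows, columns=STATE_COLUMNS)


def cna_size_summary(states: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Summarise aberrant segments by region and boundedness class.

    Returns a table of (region_id, boundedness, n, mean_length_bp,
    mean_total_cn) over aberrant, non-assumed states — averaged over segments —
    plus the fraction of regions (among those with both classes) whose mean
    internal segment is shorter than its mean telomere/centromere-bound
    segment.
    """
    ab = states[(~states["assumed"]) & (states["aberration"] != "normal")]
    if len(ab) == 0:
        raise ValueError("no aberrant states to summarise")
    table = (
        ab.groupby(["region_id", "boundedness"], sort=True)
        .agg(
            n=("seg_length", "size"),
            mean_length_bp=("seg_length", "mean"),
            mean_total_cn=("total_cn", "mean"),
        )
        .reset_index()
    )
    wide = table.pivot(index="region_id", columns="boundedness", values="mean_length_bp")
    bound_cols = [c for c in ("telomere_bound", "centromere_bound") if c in wide.columns]
    if "internal" in wide.columns and bound_cols:
        bound_mean = wide[bound_cols].mean(axis=1)
        both = wide["internal"].notna() & bound_mean.notna()
        frac_smaller = (
            float((wide.loc[both, "internal"] < bound_mean[both]).mean())
            if both.any()
            else float("nan")
        )
    else:
        frac_smaller = float("nan")
    return table, frac_smaller
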