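"""Genome-context hypermethylation scoring.

Tumors accumulate hypermethylation at characteristic region classes — CIMP
promoter CpG islands, bivalent (H3K4me2/3 + H3K27me3) domains and DNA
methylation valleys (DMVs).  This module scores per-sample hypermethylation
burden over such regions, ranks samples by burden, and correlates burdens
across region classes (and against imprinted-DMR defect counts) choosing
Pearson or Spearman according to the data distribution.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import validate_regions

MILD_BETA = 0.5
HIGH_BETA = 0.75
LOW_DELTA = 0.2  # above control mean; >= by convention
UNMETHYLATED_CONTROL_MAX = 0.2  # region eligibility: uniformly unmethylated controls

DEFAULT_SEVERITY_WEIGHTS = {"lowly": 1, "mildly": 2, "highly": 3}


def select_analysis_regions(
    ctrl: pd.DataFrame,
    regions: pd.DataFrame,
    klass: str | None = None,
    max_control_mean: float = UNMETHYLATED_CONTROL_MAX,
) -> pd.DataFrame:
    """Keep regions uniformly unmethylated in controls (mean beta < 0.2)."""
    regions = validate_regions(regions)
    if klass is not None:
        regions = regions[regions["klass"] == klass]
    means = ctrl["mean"].reindex(regions["region_id"])
    keep = (means < max_control_mean).to_numpy()
    return regions[keep].reset_index(drop=True)


def severity_class(
    value: float,
    ctrl_mean: float,
    mild: float = MILD_BETA,
    high: float = HIGH_BETA,
    low_delta: float = LOW_DELTA,
) -> str:
    """Severity of a methylation gain at one region in one sample.

    highly (> 0.75 absolute beta) beats mildly (> 0.5) beats lowly (at least
    control mean + 0.2) beats unaffected.
    """
    if np.isnan(value):
        raise ValueError("cannot classify a missing value")
    if value > high:
        return "highly"
    if value > mild:
        return "mildly"
    if value >= ctrl_mean + low_delta:
        return "lowly"
    return "unaffected"


def severity_calls(
    region_means: pd.DataFrame,
    ctrl: pd.DataFrame,
    regions: pd.DataFrame,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Severity class per (sample, region) for the given region set."""
    regions = validate_regions(regions)
    if samples is None:
        samples = list(region_means.columns)
    rows = []
    for reg in regions.itertuples():
        if reg.region_id not in region_means.index or reg.region_id not in ctrl.index:
            continue
        c_mean = ctrl.loc[reg.region_id, "mean"]
        for sample in samples:
            value = region_means.loc[reg.region_id, sample]
            rows.append(
                (sample, reg.region_id, reg.klass, severity_class(value, c_mean))
            )
    return pd.DataFrame(rows, columns=["sample_id", "region_id", "klass", "severity"])


def burden_profile(
    calls: pd.DataFrame,
    klass: str | None = None,
    weights: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-sample burden counts, weighted score and cohort rank.

    The score is ``3·highly + 2·mildly + 1·lowly`` by default (a convention:
    severity-weighted count of affected loci).  Ranking is descending by
    score, ties broken by the number of highly methylated loci, then by
    sample id for determinism.
    """
    if weights is None:
        weights = DEFAULT_SEVERITY_WEIGHTS
    sub = calls if klass is None else calls[calls["klass"] == klass]
    counts = (
        sub.pivot_table(
            index="sample_id", columns="severity", aggfunc="size", fill_value=0
        )
        .reindex(columns=["unaffected", "lowly", "mildly", "highly"], fill_value=0)
    )
    counts["score"] = sum(counts[sev] * w for sev, w in weights.items())
    counts = counts.sort_values(
        ["score", "highly", "sample_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    counts["rank"] = np.arange(1, len(counts) + 1)
    return counts.reset_index()


class BurdenCorrelation(NamedTuple):
    coefficient: float
    method: str  # "pearson" | "spearman" | "undefined"
    p_value: float


def correlate_burdens(x, y, alpha: float = 0.05) -> BurdenCorrelation:
    """Correlate two per-sample burden vectors, Pearson or Spearman by fit.

    Shapiro-Wilk tests both vectors at ``alpha``; if either rejects
    normality, Spearman's rank correlation is used, otherwise Pearson's.
    A zero-variance vector makes the coefficient undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("burden vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise ValueError(f"need >= 5 paired samples, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return BurdenCorrelation(float("nan"), "undefined", float("nan"))
    normal = (
        stats.shapiro(x).pvalue > alpha and stats.shapiro(y).pvalue > alpha
    )
    if normal:
        r = stats.pearsonr(x, y)
        return BurdenCorrelation(float(r.statistic), "pearson", float(r.pvalue))
    r = stats.spearmanr(x, y)
    return BurdenCorrelation(float(r.statistic), "spearman", float(r.pvalue))


def burden_correlation_matrix(
    scores: dict[str, pd.Series], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise burden correlations between named score vectors.

    Returns (coefficient matrix, method-label matrix); vectors are aligned on
    their sample index.
    """
    names = list(scores)
    coef = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    meth = pd.DataFrame("", index=names, columns=names, dtype=object)
    for a in names:
        coef.loc[a, a] = 1.0
        meth.loc[a, a] = "identity"
        for b in names:
            if names.index(b) <= names.index(a):
                continue
            xa, xb = scores[a].align(scores[b], join="inner")
            res = correlate_burdens(xa.to_numpy(), xb.to_numpy(), alpha=alpha)
            coef.loc[a, b] = coef.loc[b, a] = res.coefficient
            meth.loc[a, b] = meth.loc[b, a] = res.method
    return coef, meth
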