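"""Core imprinted-DMR methylation analysis.

An imprinted DMR carries one germline-methylated and one unmethylated parental
allele, so a diploid cell reads out ~0.5 average beta.  Somatic copy-number
change moves that value deterministically: with total copies ``t`` and minor
allele count ``m``, the only methylation fractions consistent with the copy
state are ``m/t`` and ``1 - m/t`` (whichever parental allele is the methylated
one).  This module computes that copy-number-predicted methylation, calls a
locus CNA-independent (an epimutation candidate) when the observed DMR average
deviates from the prediction by more than three control standard deviations,
classifies absolute methylation states, infers which parental allele survived
a copy-neutral LOH event, and quantifies how much methylation variance copy
number alone explains.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, other_parent, validate_regions

log = logging.getLogger(__name__)

HYPER_BETA = 0.8  #: absolute beta above which a DMR is hypermethylated
HYPO_BETA = 0.2  #: absolute beta below which a DMR is hypomethylated
INTERMEDIATE_DELTA = 0.2  #: beta shift vs controls for intermediate defects
SD_BAND = 3.0  #: control s.d. multiple defining the CNA-dependent band

#: columns of the per-(sample, region) methylation-call table
CALL_COLUMNS = [
    "sample_id",
    "region_id",
    "observed",
    "predicted",
    "evaluable",
    "cna_independent",
    "state",
    "retained_parent",
]


# -- region averaging --------------------------------------------------------

def region_average(
    bm: BetaMatrix,
    regions: pd.DataFrame,
    manifest: pd.DataFrame,
    min_probes: int = 1,
) -> pd.DataFrame:
    """Mean beta per region per sample (regions x samples).

    Probe-to-region assignment comes from the manifest's ``region_id`` column.
    The mean skips missing probe values; a (region, sample) cell is NaN when
    every probe is missing.  Regions with fewer than ``min_probes`` mapped
    probes are dropped (with a warning).
    """
    regions = validate_regions(regions)
    mapping = manifest.set_index("probe_id")["region_id"]
    probe_region = mapping.reindex(bm.beta.index)
    in_regions = probe_region.isin(set(regions["region_id"]))
    sub = bm.beta.loc[in_regions.to_numpy()]
    grouped = sub.groupby(probe_region[in_regions.to_numpy()].to_numpy())
    means = grouped.mean()
    n_probes = grouped.size()
    too_few = [r for r in means.index if n_probes[r] < min_probes]
    absent = [r for r in regions["region_id"] if r not in means.index]
    for r in too_few + (absent if min_probes > 0 else []):
        warnings.warn(
            f"region {r!r} has fewer than {min_probes} surviving probes; excluded",
            stacklevel=2,
        )
    keep = [r for r in regions["region_id"] if r in means.index and n_probes[r] >= min_probes]
    out = means.loc[keep]
    out.index.name = "region_id"
    return out


def dmr_average(
    bm: BetaMatrix, regions: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample average beta over each imprinted DMR's probes.

    Single-probe DMRs are excluded: one probe cannot distinguish a regional
    methylation profile from probe-level noise.
    """
    imp = regions[regions["klass"] == "imprinted_dmr"]
    return region_average(bm, imp, manifest, min_probes=2)


# -- control statistics ------------------------------------------------------

def compute_control_stats(
    region_means: pd.DataFrame, control_samples: list[str]
) -> pd.DataFrame:
    """Per-region mean and sample s.d. (ddof=1) across normal controls.

    Raises when fewer than two controls are available — a standard deviation
    from one sample is undefined.
    """
    missing = [s for s in control_samples if s not in region_means.columns]
    if missing:
        raise ValueError(f"control samples absent from matrix: {missing}")
    if len(control_samples) < 2:
        raise ValueError(
            f"need >= 2 control samples for a usable s.d., got {len(control_samples)}"
        )
    ctrl = region_means[list(control_samples)]
    out = pd.DataFrame(
        {
            "n_controls": ctrl.notna().sum(axis=1),
            "mean": ctrl.mean(axis=1),
            "sd": ctrl.std(axis=1, ddof=1),
        }
    )
    out.index.name = "region_id"
    return out


# -- the copy-number-predicted methylation model -----------------------------

def predicted_methylation(total_cn: int, minor_cn: int, observed: float) -> float:
    """Methylation fraction implied by the allele-specific copy state.

    The minor methylation value is ``m = minor_cn / total_cn``.  If the
    observed beta is below 0.5 the methylated allele is taken to be the minor
    one and ``m`` is returned; above 0.5 the methylated allele is the major
    one and ``1 - m`` is returned.  An observed beta of exactly 0.5 is a tie
    and resolves to the ``1 - m`` branch (logged), except when ``m = 0.5``
    where both branches coincide.

    Returns NaN for homozygous deletions (``total_cn == 0``): no DNA, no
    prediction — callers flag such loci not-evaluable.
    """
    if total_cn == 0:
        return float("nan")
    if minor_cn > total_cn - minor_cn:
        raise ValueError(
            f"minor_cn {minor_cn} exceeds the major allele count for total_cn {total_cn}"
        )
    m = minor_cn / total_cn
    if np.isnan(observed):
        return float("nan")
    if observed < 0.5:
        return m
    if observed > 0.5:
        return 1.0 - m
    if m != 0.5:
        log.debug(
            "observed beta exactly 0.5 with asymmetric copy state %d:%d; "
            "tie broken toward the major-methylated branch",
            total_cn,
            minor_cn,
        )
    return 1.0 - m


def call_cna_independent(
    observed: float,
    predicted: float,
    sd: float,
    n_sd: float = SD_BAND,
    atol: float = 1e-9,
) -> bool | float:
    """True when the observed value falls outside predicted +/- 3 control s.d.

    The inequality is strict: a deviation of exactly three standard deviations
    is still CNA-consistent.  With a zero control s.d., any nonzero deviation
    is independent — up to ``atol``, a numerical guard that keeps accumulated
    floating-point rounding (averaging, 1 - m complements) from registering as
    deviation.  Missing inputs yield NaN (no call).
    """
    if np.isnan(observed) or np.isnan(predicted) or np.isnan(sd):
        return float("nan")
    return abs(observed - predicted) > max(n_sd * sd, atol)


def classify_state(
    observed: float,
    ctrl_mean: float,
    hyper: float = HYPER_BETA,
    hypo: float = HYPO_BETA,
    delta: float = INTERMEDIATE_DELTA,
) -> str:
    """Absolute/relative methylation state of one DMR in one sample.

    Absolute cutoffs first (beta > 0.8 hyper, < 0.2 hypo, both strict), then
    intermediate defects at +/- 0.2 beta relative to the control mean, else
    normal.
    """
    if np.isnan(observed):
        raise ValueError("cannot classify a missing observed value")
    if observed > hyper:
        return "hypermethylated"
    if observed < hypo:
        return "hypomethylated"
    if observed >= ctrl_mean + delta:
        return "intermediate_gain"
    if observed <= ctrl_mean - delta:
        return "intermediate_loss"
    return "normal"


def infer_cnnloh_parent(
    observed: float,
    methylated_parent: str,
    hyper: float = HYPER_BETA,
    hypo: float = HYPO_BETA,
) -> str:
    """Which parental allele survived a copy-neutral LOH event.

    All copies share one parent, so the DMR reads out near 0 or near 1.  A
    value above 0.8 means the retained allele carries the germline methylation
    (the annotated methylated parent); below 0.2 means the other parent;
    anything between is ambiguous.
    """
    if methylated_parent not in ("maternal", "paternal"):
        raise ValueError(
            f"cnnLOH parent inference needs a germline-methylated parent, got "
            f"{methylated_parent!r}"
        )
    if observed > hyper:
        return methylated_parent
    if observed < hypo:
        return other_parent(methylated_parent)
    return "ambiguous"


class VarianceExplained(NamedTuple):
    r2: float
    degenerate: bool  # constant predictor: R^2 reported as 0


def variance_explained(observed, predicted) -> VarianceExplained:
    """Coefficient of determination from regressing observed on predicted.

    Ordinary least squares with intercept over paired non-missing values
    (>= 3 required).  A constant predictor has no explanatory power: R^2 is
    reported as 0 with the degeneracy flag set.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[ok], pred[ok]
    if len(obs) < 3:
        raise ValueError(f"need >= 3 paired values, got {len(obs)}")
    if np.ptp(pred) == 0:
        return VarianceExplained(0.0, True)
    if np.ptp(obs) == 0:
        # perfect (degenerate) fit: residuals are zero for the flat line
        return VarianceExplained(1.0, True)
    fit = stats.linregress(pred, obs)
    return VarianceExplained(float(fit.rvalue**2), False)


# -- per-cohort assembly -----------------------------------------------------

def call_epimutations(
    region_means: pd.DataFrame,
    states: pd.DataFrame,
    ctrl: pd.DataFrame,
    regions: pd.DataFrame,
    tumor_samples: list[str] | None = None,
    *,
    hyper: float = HYPER_BETA,
    hypo: float = HYPO_BETA,
    delta: float = INTERMEDIATE_DELTA,
    n_sd: float = SD_BAND,
) -> pd.DataFrame:
    """Assemble the per-(sample, region) methylation-call table.

    Joins DMR averages with locus copy states and control statistics, then
    applies the predicted-methylation model, the +/- 3 s.d. CNA-independence
    rule, absolute state classification, and cnnLOH parent-of-origin
    inference.  Homozygous deletions (total 0) and missing observations are
    marked non-evaluable.
    """
    regions = validate_regions(regions)
    parent_of = regions.set_index("region_id")["methylated_parent"]
    if tumor_samples is None:
        tumor_samples = list(region_means.columns)
    state_idx = states.set_index(["sample_id", "region_id"])

    rows = []
    for region_id in region_means.index:
        if region_id not in ctrl.index:
            continue
        c_mean = ctrl.loc[region_id, "mean"]
        c_sd = ctrl.loc[region_id, "sd"]
        for sample in tumor_samples:
            observed = region_means.loc[region_id, sample]
            try:
                st = state_idx.loc[(sample, region_id)]
            except KeyError as exc:
                raise ValueError(
                    f"no copy state for sample {sample!r}, region {region_id!r}"
                ) from exc
            total, minor = int(st["total_cn"]), int(st["minor_cn"])
            predicted = predicted_methylation(total, minor, observed)
            evaluable = not (np.isnan(observed) or total == 0)
            independent = (
                call_cna_independent(observed, predicted, c_sd, n_sd=n_sd)
                if evaluable
                else float("nan")
            )
            state = (
                classify_state(observed, c_mean, hyper=hyper, hypo=hypo, delta=delta)
                if not np.isnan(observed)
                else "missing"
            )
            retained = ""
            if bool(st["cnnloh"]) and not np.isnan(observed):
                retained = infer_cnnloh_parent(
                    observed, parent_of[region_id], hyper=hyper, hypo=hypo
                )
            rows.append(
                (sample, region_id, observed, predicted, evaluable, independent, state, retained)
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def epimutation_frequency(calls: pd.DataFrame) -> dict[str, float]:
    """Cohort-level epimutation summaries from a methylation-call table.

    ``pair_frequency`` counts CNA-independent calls over evaluable
    (sample, DMR) pairs; ``mean_dmrs_affected_per_sample`` averages the number
    of affected DMRs per sample.  Both readings are emitted because cohort
    percentages can be expressed either way.
    """
    ev = calls[calls["evaluable"].astype(bool)]
    n_pairs = len(ev)
    n_independent = int(ev["cna_independent"].astype(float).fillna(0).sum())
    per_sample = ev.groupby("sample_id")["cna_independent"].apply(
        lambda s: s.astype(float).fillna(0).sum()
    )
    return {
        "n_evaluable_pairs": n_pairs,
        "n_independent": n_independent,
        "pair_frequency": n_independent / n_pairs if n_pairs else float("nan"),
        "mean_dmrs_affected_per_sample": float(per_sample.mean()) if len(per_sample) else float("nan"),
    }


def variance_explained_by_region(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-region R^2 of observed on copy-number-predicted methylation."""
    rows = []
    for region_id, grp in calls.groupby("region_id", sort=True):
        ev = grp[grp["evaluable"].astype(bool)]
        if len(ev) < 3:
            rows.append((region_id, float("nan"), True, len(ev)))
            continue
        res = variance_explained(ev["observed"], ev["predicted"])
        rows.append((region_id, res.r2, res.degenerate, len(ev)))
    return pd.DataFrame(rows, columns=["region_id", "r2", "degenerate", "n"])
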