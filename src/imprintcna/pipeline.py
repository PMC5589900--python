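"""End-to-end orchestration: QC -> copy states -> imprint calls -> context burdens.

:func:`analyse_cohort` runs the whole analysis on in-memory objects and is the
programmatic entry point; :func:`run_analysis` wraps it with file reading,
output writing and a structured run report, and backs the ``analyse`` CLI
subcommand.  Reruns with identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cna, context, imprint, io_formats
from .core import BetaMatrix, ChromosomeAnatomy, validate_regions

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """All decision thresholds of the analysis, with their standard defaults."""

    hyper_beta: float = 0.8
    hypo_beta: float = 0.2
    intermediate_delta: float = 0.2
    sd_band: float = 3.0
    severity_mild: float = 0.5
    severity_high: float = 0.75
    severity_low_delta: float = 0.2
    unmethylated_control_max: float = 0.2
    internal_distance_bp: int = 1_000_000
    rrbs_min_coverage: int = 10
    detection_p_max: float = 0.01
    detection_sample_frac: float = 0.10
    snp_flank_bp: int = 5
    snp_maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name}={v} must be positive")


@dataclass
class RunConfig:
    """File-based run configuration (see ``analyse --config``)."""

    beta_path: str
    manifest_path: str
    regions_path: str
    segments_path: str
    anatomy_path: str
    control_samples: list[str]
    out_dir: str
    tissue: str = "unspecified"
    dialect: str = "tsv"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        thr = data.pop("thresholds", None)
        cfg = cls(**data)
        if thr:
            cfg.thresholds = Thresholds(**thr)
        return cfg


@dataclass
class AnalysisResult:
    """All tables produced by one analysis run."""

    qc_counts: dict
    region_means: pd.DataFrame  # imprinted DMR averages, regions x samples
    control_stats: pd.DataFrame
    states: pd.DataFrame
    calls: pd.DataFrame
    r2: pd.DataFrame
    cohort: dict
    severity: pd.DataFrame
    burdens: dict[str, pd.DataFrame]
    burden_scores: dict[str, pd.Series]
    correlations: pd.DataFrame
    correlation_methods: pd.DataFrame
    report: dict


def _stage(name: str):
    log.info("stage: %s", name)
    return name


def analyse_cohort(
    bm: BetaMatrix,
    manifest: pd.DataFrame,
    regions: pd.DataFrame,
    segments: pd.DataFrame,
    anatomy: dict[str, ChromosomeAnatomy],
    control_samples: list[str],
    thresholds: Thresholds | None = None,
) -> AnalysisResult:
    """Run the full copy-number-aware imprint analysis on in-memory inputs.

    Stages: probe QC -> DMR averaging -> control statistics -> locus copy
    states -> predicted methylation / CNA-independence / state classification /
    cnnLOH parent inference -> per-region variance explained -> genome-context
    severity, burden and correlation scoring.
    """
    thr = thresholds or Thresholds()
    regions = validate_regions(regions)
    stage = _stage("filter_probes")
    try:
        bm_qc, qc_counts = io_formats.filter_probes(
            bm,
            manifest,
            detection_p_max=thr.detection_p_max,
            detection_sample_frac=thr.detection_sample_frac,
            snp_flank_bp=thr.snp_flank_bp,
            snp_maf_min=thr.snp_maf_min,
        )

        stage = _stage("dmr_average")
        dmr_means = imprint.dmr_average(bm_qc, regions, manifest)
        tumor_samples = [s for s in bm.samples if s not in set(control_samples)]

        stage = _stage("compute_control_stats")
        ctrl = imprint.compute_control_stats(dmr_means, control_samples)

        stage = _stage("overlap_locus_state")
        imprinted = regions[regions["klass"] == "imprinted_dmr"]
        states = cna.overlap_locus_state(
            segments, imprinted, anatomy, samples=list(bm.samples)
        )

        stage = _stage("call_epimutations")
        calls = imprint.call_epimutations(
            dmr_means,
            states,
            ctrl,
            regions,
            tumor_samples=tumor_samples,
            hyper=thr.hyper_beta,
            hypo=thr.hypo_beta,
            delta=thr.intermediate_delta,
            n_sd=thr.sd_band,
        )
        cohort = imprint.epimutation_frequency(calls)

        stage = _stage("variance_explained")
        r2 = imprint.variance_explained_by_region(calls)

        stage = _stage("genome_context")
        ctx_regions = regions[regions["klass"] != "imprinted_dmr"]
        severity = pd.DataFrame(
            columns=["sample_id", "region_id", "klass", "severity"]
        )
        burdens: dict[str, pd.DataFrame] = {}
        scores: dict[str, pd.Series] = {}
        if len(ctx_regions) and tumor_samples:
            ctx_means = imprint.region_average(bm_qc, ctx_regions, manifest, min_probes=1)
            ctx_ctrl = imprint.compute_control_stats(ctx_means, control_samples)
            eligible = context.select_analysis_regions(
                ctx_ctrl, ctx_regions, max_control_mean=thr.unmethylated_control_max
            )
            if len(eligible):
                severity = context.severity_calls(
                    ctx_means, ctx_ctrl, eligible, samples=tumor_samples
                )
                for klass in sorted(eligible["klass"].unique()):
                    prof = context.burden_profile(severity, klass=klass)
                    burdens[klass] = prof
                    scores[klass] = prof.set_index("sample_id")["score"]
        # imprinted defect burden: number of non-normal DMR states per sample
        if tumor_samples and len(calls):
            ok = calls[calls["state"] != "missing"]
            imp_score = (
                (ok["state"] != "normal")
                .groupby(ok["sample_id"])
                .sum()
                .reindex(tumor_samples, fill_value=0)
                .astype(float)
            )
            scores["imprinted"] = imp_score
        if len(scores) >= 2 and all(len(s) >= 5 for s in scores.values()):
            corr, corr_methods = context.burden_correlation_matrix(scores)
        else:
            corr = pd.DataFrame()
            corr_methods = pd.DataFrame()
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc

    report = {
        "software_version": __version__,
        "n_samples": len(bm.samples),
        "n_controls": len(control_samples),
        "n_tumors": len(bm.samples) - len(control_samples),
        "probe_qc": qc_counts,
        "n_regions": int(len(regions)),
        "n_imprinted_dmrs_analysed": int(len(dmr_means)),
        "n_states": int(len(states)),
        "n_calls": int(len(calls)),
        "cohort": cohort,
        "thresholds": dataclasses.asdict(thr),
    }
    return AnalysisResult(
        qc_counts=qc_counts,
        region_means=dmr_means,
        control_stats=ctrl,
        states=states,
        calls=calls,
        r2=r2,
        cohort=cohort,
        severity=severity,
        burdens=burdens,
        burden_scores=scores,
        correlations=corr,
        correlation_methods=corr_methods,
        report=report,
    )


def _write_atomic(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", **kwargs)
    tmp.replace(path)


def run_analysis(cfg: RunConfig) -> AnalysisResult:
    """File-based end-to-end run; writes all output tables plus a report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bm = io_formats.read_beta_matrix(cfg.beta_path, dialect=cfg.dialect)
    manifest = io_formats.read_probe_manifest(cfg.manifest_path)
    regions = io_formats.read_regions_bed(cfg.regions_path)
    segments = io_formats.read_segments(cfg.segments_path)
    anatomy = io_formats.read_anatomy(cfg.anatomy_path)

    result = analyse_cohort(
        bm, manifest, regions, segments, anatomy, cfg.control_samples, cfg.thresholds
    )

    _write_atomic(result.calls, out / "methylation_calls.tsv", index=False)
    _write_atomic(result.states, out / "locus_copy_states.tsv", index=False)
    _write_atomic(result.control_stats, out / "control_stats.tsv")
    _write_atomic(result.r2, out / "variance_explained.tsv", index=False)
    _write_atomic(result.severity, out / "context_severity.tsv", index=False)
    for klass, prof in result.burdens.items():
        _write_atomic(prof, out / f"burden_{klass}.tsv", index=False)
    if len(result.correlations):
        _write_atomic(result.correlations, out / "burden_correlations.tsv")
        _write_atomic(result.correlation_methods, out / "burden_correlation_methods.tsv")
    # observed-vs-expected scatter export (x = predicted, y = observed)
    scatter = result.calls[["sample_id", "region_id", "predicted", "observed"]].copy()
    sd = result.control_stats["sd"]
    scatter["band_halfwidth"] = (
        scatter["region_id"].map(sd) * cfg.thresholds.sd_band
    )
    _write_atomic(scatter, out / "observed_vs_expected.tsv", index=False)

    report = dict(result.report)
    report["config"] = {
        **{
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k != "thresholds"
        },
    }
    tmp = out / "run_report.json.tmp"
    tmp.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    tmp.replace(out / "run_report.json")
    return result
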