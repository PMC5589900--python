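"""Synthetic allele-resolved tumor methylome cohorts with known ground truth.

The generator emulates a cell-line-style cohort measured on a beta-value
methylation array together with allele-specific copy-number segment calls:

* normal diploid samples read out ~0.5 beta at every imprinted DMR (one
  methylated, one unmethylated parental allele) and ~0.05 at CIMP/bivalent/DMV
  regions (uniformly unmethylated in normal tissue);
* tumors draw per-locus allele-specific copy states (deletions,
  amplifications up to 14 total copies, copy-neutral LOH), each copy carrying
  the methylation state of its parental allele, so the noise-free DMR beta is
  exactly (methylated copies) / (total copies);
* epimutations are injected on top at a configurable rate (hyper: all copies
  methylated; hypo: all unmethylated; intermediate: exactly one copy flipped),
  always as events that actually change the locus — an "epimutation" that
  reproduces the copy-number-expected profile is not an event;
* genome-context hypermethylation is driven by one per-tumor latent factor,
  while imprinted epimutations are drawn independently of it;
* tumor purity below 1 linearly dilutes every beta toward the matched normal
  profile; RRBS-style binomial read counts can be emitted for any sample.

Randomness uses one ``numpy`` Generator stream per (seed, role, sample,
region), so adding samples or regions never perturbs the values already
generated for existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BetaMatrix, ChromosomeAnatomy, other_parent, validate_regions
from . import io_formats

# stream roles (second word of the RNG seed key)
_ROLE_SAMPLE = 1  # per-sample draws: latent factor, purity
_ROLE_TRUTH = 2  # per-(tumor, DMR) copy state and segment flanks
_ROLE_EPI = 3  # epimutation injection
_ROLE_BETA = 4  # imprinted probe noise
_ROLE_CONTEXT = 5  # context-region level + probe noise
_ROLE_RRBS = 6  # per-sample read-count emission

_TUMOR_IDX_BASE = 1_000_000  # keeps tumor streams disjoint from normal streams

#: imprinted DMR names used by the default synthetic region set (coordinates
#: are synthetic; the germline-methylated parent is paternal for H19, the
#: MEG3/DLK1 IG-DMR and ZDBF2, maternal otherwise, as in the human imprintome)
DEFAULT_DMR_NAMES = [
    "PPIEL", "DIRAS3", "ZDBF2", "NAP1L5", "FAM50B", "PLAGL1", "IGF2R",
    "GRB10", "SGCE_PEG10", "MEST", "HTR5A", "KCNK9", "PEG13", "H19",
    "KCNQ1OT1", "IGF2_DMR0", "INPP5F", "RB1", "MEG3", "SNRPN", "MKRN3",
    "MAGEL2", "IGF2R_AIR", "IGF1R", "ZNF597", "ZNF331_DMR1", "ZNF331_DMR2",
    "PEG3", "MCTS2_HM13", "NNAT", "L3MBTL1", "GNAS_AB", "GNAS_XL",
    "GNAS_NESP", "NHP2L1", "WRB", "DGCR6",
]
PATERNALLY_METHYLATED = {"H19", "MEG3", "ZDBF2"}


def default_anatomy(
    n_chrom: int = 22,
    length_bp: int = 120_000_000,
    centromere_start: int = 55_000_000,
    centromere_end: int = 65_000_000,
) -> dict[str, ChromosomeAnatomy]:
    """A synthetic karyotype: equal-length chromosomes with mid centromeres."""
    return {
        f"chr{i}": ChromosomeAnatomy(f"chr{i}", length_bp, centromere_start, centromere_end)
        for i in range(1, n_chrom + 1)
    }


def default_region_set(
    n_dmr: int = 37,
    n_cimp: int = 30,
    n_bivalent: int = 442,
    n_dmv: int = 166,
    anatomy: dict[str, ChromosomeAnatomy] | None = None,
    region_length: int = 4_000,
    spacing: int = 2_500_000,
) -> pd.DataFrame:
    """Deterministic synthetic region set laid out across the karyotype.

    Imprinted DMRs come first (named after known imprinted loci, synthetic
    coordinates), then CIMP, bivalent and DMV regions.  Regions are spread
    round-robin over chromosomes with fixed spacing, skipping the
    pericentromere so most loci are internal.
    """
    if anatomy is None:
        anatomy = default_anatomy()
    chroms = list(anatomy)
    names: list[tuple[str, str, str]] = []
    for i in range(n_dmr):
        nm = DEFAULT_DMR_NAMES[i] if i < len(DEFAULT_DMR_NAMES) else f"DMR_{i:03d}"
        parent = "paternal" if nm in PATERNALLY_METHYLATED else "maternal"
        names.append((nm, "imprinted_dmr", parent))
    names += [(f"cimp_{i:03d}", "cimp", "none") for i in range(n_cimp)]
    names += [(f"biv_{i:03d}", "bivalent", "none") for i in range(n_bivalent)]
    names += [(f"dmv_{i:03d}", "dmv", "none") for i in range(n_dmv)]

    # candidate start positions per chromosome, avoiding the pericentromere
    slots_by_chrom: dict[str, list[int]] = {}
    for chrom in chroms:
        a = anatomy[chrom]
        lo, hi = a.centromere_start - 2_000_000, a.centromere_end + 2_000_000
        slots = [
            p
            for p in range(5_000_000, a.length_bp - 5_000_000, spacing)
            if not (lo <= p < hi)
        ]
        slots_by_chrom[chrom] = slots

    rows = []
    for i, (region_id, klass, parent) in enumerate(names):
        chrom = chroms[i % len(chroms)]
        slot = i // len(chroms)
        slots = slots_by_chrom[chrom]
        if slot >= len(slots):
            raise ValueError("too many regions for the synthetic karyotype")
        start = slots[slot]
        rows.append((region_id, chrom, start, start + region_length, klass, parent))
    return validate_regions(
        pd.DataFrame(
            rows,
            columns=["region_id", "chrom", "start", "end", "klass", "methylated_parent"],
        )
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a breast-cancer cell-line cohort: 51 tumor lines against
    19 normal-tissue controls, 37 imprinted DMRs, context-region counts of
    30 CIMP / 442 bivalent / 166 DMV, amplification up to 14 total copies,
    an imprinted epimutation rate of 0.176, and purity 1 (cell lines are pure;
    primary-tumor dilution is simulated by lowering ``purity_mean``).
    """

    n_tumors: int = 51
    n_normals: int = 19
    n_dmr: int = 37
    n_cimp: int = 30
    n_bivalent: int = 442
    n_dmv: int = 166
    regions: pd.DataFrame | None = None  # overrides the n_* counts when given
    anatomy: dict[str, ChromosomeAnatomy] | None = None
    probes_per_region: int = 18
    context_probes_per_region: int = 4
    cna_rate: float = 0.40
    cnnloh_rate: float = 0.08
    max_total_cn: int = 14
    epimutation_rate: float = 0.176
    epimutation_weights: dict[str, float] = field(
        default_factory=lambda: {"hyper": 0.5, "hypo": 0.3, "intermediate": 0.2}
    )
    noise_sd: float = 0.02
    purity_mean: float = 1.0
    purity_sd: float = 0.0
    rrbs_mean_coverage: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cna_rate", "cnnloh_rate", "epimutation_rate", "noise_sd",
                     "purity_mean", "purity_sd"):
            v = getattr(self, name)
            if v < 0 or (name.endswith("rate") and v > 1):
                raise ValueError(f"{name}={v} out of range")
        if self.cna_rate + self.cnnloh_rate > 1:
            raise ValueError("cna_rate + cnnloh_rate must not exceed 1")
        if self.max_total_cn < 2:
            raise ValueError("max_total_cn must be >= 2")
        if self.probes_per_region < 2:
            raise ValueError("probes_per_region must be >= 2")
        if not (0 <= self.purity_mean <= 1):
            raise ValueError("purity_mean must lie in [0, 1]")
        if any(w < 0 for w in self.epimutation_weights.values()) or (
            sum(self.epimutation_weights.values()) <= 0
        ):
            raise ValueError("epimutation weights must be non-negative and not all zero")
        if self.rrbs_mean_coverage <= 0:
            raise ValueError("rrbs_mean_coverage must be positive")

    def resolved_regions(self) -> pd.DataFrame:
        if self.regions is not None:
            return validate_regions(self.regions)
        return default_region_set(
            self.n_dmr, self.n_cimp, self.n_bivalent, self.n_dmv,
            anatomy=self.resolved_anatomy(),
        )

    def resolved_anatomy(self) -> dict[str, ChromosomeAnatomy]:
        return self.anatomy if self.anatomy is not None else default_anatomy()

    def to_yaml(self, path) -> None:
        scalars = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in ("regions", "anatomy")
        }
        with open(path, "w") as fh:
            yaml.safe_dump(scalars, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SimulatedCohort:
    """In-memory result of :func:`simulate_cohort` (files via :func:`write_cohort`)."""

    config: SimulationConfig
    regions: pd.DataFrame
    anatomy: dict[str, ChromosomeAnatomy]
    manifest: pd.DataFrame
    beta: BetaMatrix
    segments: pd.DataFrame
    truth: pd.DataFrame
    context_levels: pd.DataFrame
    samples: pd.DataFrame  # sample_id, group, purity, latent_factor

    @property
    def normal_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == "normal", "sample_id"])

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == "tumor", "sample_id"])


def _total_cn_weights(max_total_cn: int) -> np.ndarray:
    """Prior over total copy number for CNA draws: mass at 1-4, decaying tail."""
    w = np.zeros(max_total_cn + 1)
    head = {0: 0.03, 1: 0.22, 2: 0.10, 3: 0.30, 4: 0.17}
    for k, v in head.items():
        if k <= max_total_cn:
            w[k] = v
    tail = np.array([0.55**i for i in range(1, max_total_cn - 4 + 1)])
    if len(tail):
        w[5:] = tail / tail.sum() * (1.0 - w.sum())
    return w / w.sum()


def _noisy_probes(
    rng: np.random.Generator, mean_beta: float, n: int, noise_sd: float
) -> np.ndarray:
    """Probe betas around a locus mean with beta-value-like heteroscedastic noise.

    Measured beta variance peaks at intermediate methylation and vanishes at
    the fully (un)methylated extremes; the probe s.d. is scaled by
    ``2 * sqrt(beta * (1 - beta))`` so ``noise_sd`` is the s.d. at beta 0.5.
    This also keeps probe values unbiased at the boundaries, where additive
    homoscedastic noise would be clipped asymmetrically.
    """
    if noise_sd == 0:
        return np.full(n, mean_beta)
    sd = noise_sd * 2.0 * np.sqrt(mean_beta * (1.0 - mean_beta))
    return np.clip(mean_beta + rng.normal(0.0, sd, n), 0.0, 1.0)


def mix_purity(beta_tumor: float, beta_normal: float, purity: float):
    """Linear purity dilution: ``purity * tumor + (1 - purity) * normal``."""
    return purity * beta_tumor + (1.0 - purity) * beta_normal


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _draw_truth(cfg: SimulationConfig, samples: pd.DataFrame,
                imprinted: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, DMR) copy states and parental phase, before epimutations."""
    cn_weights = _total_cn_weights(cfg.max_total_cn)
    cnnloh_totals = np.arange(2, min(4, cfg.max_total_cn) + 1)
    rows = []
    for s in samples.itertuples():
        for r_idx, reg in enumerate(imprinted.itertuples()):
            if s.group == "normal":
                total, minor, minor_parent = 2, 1, "maternal"
                u_left = u_right = 0.0
            else:
                rng = _rng(cfg.seed, _ROLE_TRUTH, s.sample_idx, r_idx)
                u = rng.random()
                if u < cfg.cnnloh_rate:
                    total = int(rng.choice(cnnloh_totals))
                    minor = 0
                elif u < cfg.cnnloh_rate + cfg.cna_rate:
                    total = int(rng.choice(len(cn_weights), p=cn_weights))
                    minor = int(rng.integers(0, total // 2 + 1)) if total else 0
                else:
                    total, minor = 2, 1
                minor_parent = "maternal" if rng.random() < 0.5 else "paternal"
                u_left, u_right = float(rng.random()), float(rng.random())
            major_parent = other_parent(minor_parent)
            meth_parent = reg.methylated_parent
            if total == 0:
                meth_base = 0
            elif minor_parent == meth_parent:
                meth_base = minor
            else:
                meth_base = total - minor
            rows.append(
                (
                    s.sample_id, reg.region_id, s.sample_idx, r_idx,
                    s.group == "tumor", total, minor, minor_parent, major_parent,
                    meth_parent, meth_base, s.purity, u_left, u_right,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "region_id", "sample_idx", "region_idx", "is_tumor",
            "total_cn", "minor_cn", "minor_parent", "major_parent",
            "methylated_parent", "meth_copies_base", "purity",
            "flank_u_left", "flank_u_right",
        ],
    )


def inject_epimutations(truth: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Inject per-locus epimutations into a truth table.

    Each (tumor, region) pair with at least one copy is hit with probability
    ``epimutation_rate``.  The kind is drawn from ``epimutation_weights``
    restricted to kinds that change the per-copy methylation pattern (a
    "hyper" event at an already fully methylated locus would be unobservable
    and is not an event): hyper methylates every copy, hypo demethylates every
    copy, intermediate flips exactly one copy chosen uniformly.
    """
    truth = truth.copy()
    kinds = ["hyper", "hypo", "intermediate"]
    base_w = np.array([cfg.epimutation_weights.get(k, 0.0) for k in kinds])
    labels = []
    meth_after = []
    for row in truth.itertuples():
        total, base = row.total_cn, row.meth_copies_base
        if not row.is_tumor or total == 0 or cfg.epimutation_rate == 0:
            labels.append("none")
            meth_after.append(base)
            continue
        rng = _rng(cfg.seed, _ROLE_EPI, row.sample_idx, row.region_idx)
        if rng.random() >= cfg.epimutation_rate:
            labels.append("none")
            meth_after.append(base)
            continue
        feasible = np.array([base < total, base > 0, True])
        w = base_w * feasible
        if w.sum() == 0:
            labels.append("none")
            meth_after.append(base)
            continue
        kind = kinds[int(rng.choice(3, p=w / w.sum()))]
        if kind == "hyper":
            new = total
        elif kind == "hypo":
            new = 0
        else:  # flip one copy, uniform over copies
            new = base - 1 if rng.random() < base / total else base + 1
        labels.append(kind)
        meth_after.append(new)
    truth["epimutation"] = labels
    truth["meth_copies"] = meth_after
    total = truth["total_cn"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tumor_beta = np.where(total > 0, truth["meth_copies"] / total, np.nan)
    truth["tumor_beta"] = tumor_beta
    # measured fraction after purity dilution; homozygous deletions read out
    # the contaminating-normal signal (0.5) regardless of purity
    mixed = mix_purity(np.where(np.isnan(tumor_beta), 0.5, tumor_beta), 0.5,
                       truth["purity"].to_numpy())
    truth["mixed_beta"] = mixed
    return truth


def _segment_bounds(imprinted: pd.DataFrame, anatomy) -> dict[str, tuple[int, int]]:
    """Max left/right flank per DMR so per-sample segments never overlap."""
    bounds = {}
    for chrom, grp in imprinted.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        length = anatomy[chrom].length_bp
        for i, rid in enumerate(g["region_id"]):
            prev_end = ends[i - 1] if i > 0 else 0
            next_start = starts[i + 1] if i + 1 < len(g) else length
            left = min(1_200_000, (starts[i] - prev_end) // 2 - 1, starts[i])
            right = min(1_200_000, (next_start - ends[i]) // 2 - 1, length - ends[i])
            bounds[rid] = (max(0, left), max(0, right))
    return bounds


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort; deterministic given ``cfg.seed``."""
    regions = cfg.resolved_regions()
    anatomy = cfg.resolved_anatomy()
    bad = set(regions["chrom"]) - set(anatomy)
    if bad:
        raise ValueError(f"regions on chromosomes absent from anatomy: {sorted(bad)}")
    imprinted = regions[regions["klass"] == "imprinted_dmr"].reset_index(drop=True)
    ctx_regions = regions[regions["klass"] != "imprinted_dmr"].reset_index(drop=True)

    # -- samples --------------------------------------------------------
    sample_rows = []
    for i in range(cfg.n_normals):
        sample_rows.append((f"N{i:03d}", "normal", i, 1.0, np.nan))
    for i in range(cfg.n_tumors):
        idx = _TUMOR_IDX_BASE + i
        rng = _rng(cfg.seed, _ROLE_SAMPLE, idx)
        latent = float(rng.random())
        purity = float(np.clip(rng.normal(cfg.purity_mean, cfg.purity_sd), 0.05, 1.0))
        sample_rows.append((f"T{i:03d}", "tumor", idx, purity, latent))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "group", "sample_idx", "purity", "latent_factor"]
    )

    # -- truth and epimutations -----------------------------------------
    truth = inject_epimutations(_draw_truth(cfg, samples, imprinted), cfg)

    # -- probe manifest --------------------------------------------------
    man_rows = []
    probe_slices: dict[str, tuple[int, int]] = {}
    cursor = 0
    for reg in regions.itertuples():
        n_probes = (
            cfg.probes_per_region
            if reg.klass == "imprinted_dmr"
            else cfg.context_probes_per_region
        )
        positions = np.linspace(reg.start, reg.end - 1, n_probes).astype(int)
        for k, pos in enumerate(positions):
            man_rows.append(
                (f"cg{cursor + k:08d}", reg.chrom, int(pos), np.nan, np.nan, reg.region_id)
            )
        probe_slices[reg.region_id] = (cursor, cursor + n_probes)
        cursor += n_probes
    manifest = pd.DataFrame(
        man_rows,
        columns=["probe_id", "chrom", "pos", "nearest_snp_distance_bp",
                 "nearest_snp_maf", "region_id"],
    )

    # -- beta matrix -----------------------------------------------------
    n_probes_total = cursor
    beta = np.empty((n_probes_total, len(samples)), dtype=float)
    sample_col = {sid: j for j, sid in enumerate(samples["sample_id"])}

    for row in truth.itertuples():
        lo, hi = probe_slices[row.region_id]
        rng = _rng(cfg.seed, _ROLE_BETA, row.sample_idx, row.region_idx)
        vals = _noisy_probes(rng, row.mixed_beta, hi - lo, cfg.noise_sd)
        beta[lo:hi, sample_col[row.sample_id]] = vals

    ctx_rows = []
    n_imprinted = len(imprinted)
    for s in samples.itertuples():
        for j, reg in enumerate(ctx_regions.itertuples()):
            r_idx = n_imprinted + j
            rng = _rng(cfg.seed, _ROLE_CONTEXT, s.sample_idx, r_idx)
            if s.group == "tumor" and rng.random() < s.latent_factor:
                level = float(rng.uniform(0.25, 0.95))
            else:
                rng.random()  # keep the stream layout identical for both arms
                level = 0.05
            mixed = mix_purity(level, 0.05, s.purity)
            lo, hi = probe_slices[reg.region_id]
            beta[lo:hi, sample_col[s.sample_id]] = _noisy_probes(
                rng, mixed, hi - lo, cfg.noise_sd
            )
            ctx_rows.append((s.sample_id, reg.region_id, reg.klass, level, mixed))
    context_levels = pd.DataFrame(
        ctx_rows, columns=["sample_id", "region_id", "klass", "level", "mixed_level"]
    )

    beta_df = pd.DataFrame(
        beta, index=manifest["probe_id"].to_numpy(), columns=samples["sample_id"].to_numpy()
    )
    beta_df.index.name = "probe_id"

    # -- segments (aberrant imprinted loci only; the rest is assumed 2:1) --
    flank_bounds = _segment_bounds(imprinted, anatomy)
    reg_by_id = imprinted.set_index("region_id")
    seg_rows = []
    for row in truth.itertuples():
        if not row.is_tumor or (row.total_cn, row.minor_cn) == (2, 1):
            continue
        reg = reg_by_id.loc[row.region_id]
        max_left, max_right = flank_bounds[row.region_id]
        left = int(row.flank_u_left * (max_left + 1))
        right = int(row.flank_u_right * (max_right + 1))
        seg_rows.append(
            (
                row.sample_id, reg["chrom"], int(reg["start"]) - left,
                int(reg["end"]) + right, row.total_cn, row.minor_cn,
            )
        )
    segments = io_formats.validate_segments(
        pd.DataFrame(
            seg_rows,
            columns=["sample_id", "chrom", "start", "end", "total_cn", "minor_cn"],
        )
        if seg_rows
        else pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end", "total_cn", "minor_cn"]
        ).astype({"start": int, "end": int, "total_cn": int, "minor_cn": int})
    )

    return SimulatedCohort(
        config=cfg,
        regions=regions,
        anatomy=anatomy,
        manifest=manifest,
        beta=BetaMatrix(beta_df),
        segments=segments,
        truth=truth,
        context_levels=context_levels,
        samples=samples,
    )


def simulate_rrbs_counts(cohort: SimulatedCohort, sample_id: str) -> pd.DataFrame:
    """RRBS-style site table (chrom, pos, meth_count, total_count) for one sample.

    Sites are the imprinted-DMR probe positions; per-site coverage is
    Poisson(``rrbs_mean_coverage``) with zero-coverage sites dropped, and the
    methylated read count is Binomial(coverage, site methylation), where the
    site methylation is the sample's purity-mixed locus fraction.
    """
    cfg = cohort.config
    srow = cohort.samples.set_index("sample_id").loc[sample_id]
    rng = _rng(cfg.seed, _ROLE_RRBS, int(srow["sample_idx"]))
    truth = cohort.truth[cohort.truth["sample_id"] == sample_id].set_index("region_id")
    man = cohort.manifest
    rows = []
    for reg in cohort.regions[cohort.regions["klass"] == "imprinted_dmr"].itertuples():
        frac = float(truth.loc[reg.region_id, "mixed_beta"])
        probes = man[man["region_id"] == reg.region_id]
        cov = rng.poisson(cfg.rrbs_mean_coverage, len(probes))
        meth = rng.binomial(np.maximum(cov, 1), frac)
        for pos, c, m in zip(probes["pos"], cov, meth):
            if c == 0:
                continue
            rows.append((reg.chrom, int(pos), int(m), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth_count", "total_count"])


def write_cohort(cohort: SimulatedCohort, outdir, force: bool = False) -> dict[str, Path]:
    """Write the cohort in the pipeline's file dialects plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "manifest": outdir / "manifest.tsv",
        "segments": outdir / "segments.tsv",
        "regions": outdir / "regions.bed",
        "anatomy": outdir / "anatomy.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "context_levels": outdir / "context_levels.tsv",
        "config": outdir / "sim_config.yaml",
    }
    existing = [p for p in paths.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]} (pass force=True / --force)"
        )
    io_formats.write_beta_matrix(cohort.beta, paths["beta"])
    io_formats.write_probe_manifest(cohort.manifest, paths["manifest"])
    io_formats.write_segments(cohort.segments, paths["segments"])
    io_formats.write_regions_bed(cohort.regions, paths["regions"])
    io_formats.write_anatomy(cohort.anatomy, paths["anatomy"])
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    cohort.context_levels.to_csv(paths["context_levels"], sep="\t", index=False)
    cohort.config.to_yaml(paths["config"])
    return paths
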