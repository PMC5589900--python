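import numpy as np
import pandas as pd
import pytest

from imprintcna.core import BetaMatrix, ChromosomeAnatomy


@pytest.fixture
def anatomy():
    return {
        "chr1": ChromosomeAnatomy("chr1", 100_000_000, 45_000_000, 50_000_000),
        "chr2": ChromosomeAnatomy("chr2", 80_000_000, 35_000_000, 40_000_000),
    }


@pytest.fixture
def tiny_regions():
    """Two imprinted DMRs and one CIMP region on the toy karyotype."""
    return pd.DataFrame(
        {
            "region_id": ["DMR_A", "DMR_B", "CIMP_1"],
            "chrom": ["chr1", "chr2", "chr1"],
            "start": [10_000_000, 20_000_000, 30_000_000],
            "end": [10_004_000, 20_004_000, 30_004_000],
            "klass": ["imprinted_dmr", "imprinted_dmr", "cimp"],
            "methylated_parent": ["maternal", "paternal", "none"],
        }
    )


@pytest.fixture
def tiny_manifest(tiny_regions):
    rows = []
    k = 0
    for reg in tiny_regions.itertuples():
        for j in range(3):
            rows.append(
                (f"cg{k:06d}", reg.chrom, reg.start + 100 * j, np.nan, np.nan, reg.region_id)
            )
            k += 1
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "chrom", "pos",
            "nearest_snp_distance_bp", "nearest_snp_maf", "region_id",
        ],
    )


@pytest.fixture
def tiny_beta(tiny_manifest):
    rng = np.random.default_rng(42)
    samples = ["N1", "N2", "N3", "T1", "T2"]
    beta = pd.DataFrame(
        rng.uniform(0.4, 0.6, (len(tiny_manifest), len(samples))),
        index=tiny_manifest["probe_id"].to_numpy(),
        columns=samples,
    )
    beta.index.name = "probe_id"
    return BetaMatrix(beta)


def qc_fixture(n_probes: int = 1000, n_samples: int = 20, seed: int = 5):
    """A beta matrix + manifest exercising every probe-removal rule.

    Probes 0-49 fail the detection filter (p = 0.02 in 15% of samples),
    50-99 carry a missing value, 100-149 sit 3 bp from a MAF-0.02 SNP,
    150-199 map to chrX; the rest are clean autosomal probes.
    """
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:06d}" for i in range(n_probes)]
    samples = [f"S{j:02d}" for j in range(n_samples)]
    beta = pd.DataFrame(
        rng.uniform(0, 1, (n_probes, n_samples)), index=probes, columns=samples
    )
    det = pd.DataFrame(0.001, index=probes, columns=samples)
    n_fail = int(0.15 * n_samples)
    det.iloc[0:50, 0:n_fail] = 0.02
    beta.iloc[50:100, 3] = np.nan
    chrom = ["chr5"] * n_probes
    dist = [np.nan] * n_probes
    maf = [np.nan] * n_probes
    for i in range(100, 150):
        dist[i], maf[i] = 3, 0.02
    for i in range(150, 200):
        chrom[i] = "chrX"
    manifest = pd.DataFrame(
        {
            "probe_id": probes,
            "chrom": chrom,
            "pos": np.arange(n_probes) * 1000,
            "nearest_snp_distance_bp": dist,
            "nearest_snp_maf": maf,
            "region_id": ["r0"] * n_probes,
        }
    )
    return BetaMatrix(beta, det), manifest
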