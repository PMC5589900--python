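import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imprintcna import io_formats
from imprintcna.imprint import classify_state, predicted_methylation
from imprintcna.simulate import (
    SimulationConfig,
    default_region_set,
    mix_purity,
    simulate_cohort,
    simulate_rrbs_counts,
)


def small_cfg(**kw):
    base = dict(
        n_tumors=15, n_normals=5, n_cimp=3, n_bivalent=3, n_dmv=3,
        probes_per_region=4, seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"cna_rate": 1.4},
            {"epimutation_rate": -0.1},
            {"max_total_cn": 1},
            {"probes_per_region": 1},
            {"purity_mean": 1.5},
            {"cna_rate": 0.7, "cnnloh_rate": 0.5},
            {"rrbs_mean_coverage": 0},
        ],
    )
    def test_invalid_config_rejected_before_generation(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_cfg(noise_sd=0.01, seed=9)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = simulate_cohort(small_cfg())
        b = simulate_cohort(small_cfg())
        assert a.beta.beta.equals(b.beta.beta)
        assert a.truth.equals(b.truth)
        assert a.segments.equals(b.segments)

    def test_seed_changes_truth(self):
        a = simulate_cohort(small_cfg(seed=1))
        b = simulate_cohort(small_cfg(seed=2))
        assert not a.truth.equals(b.truth)


class TestGenerativeModel:
    def test_diploid_noise_free_cohort_is_exactly_half(self):
        cfg = small_cfg(cna_rate=0.0, cnnloh_rate=0.0, epimutation_rate=0.0, noise_sd=0.0)
        c = simulate_cohort(cfg)
        dmr_probes = c.manifest[
            c.manifest["region_id"].isin(
                c.regions.loc[c.regions["klass"] == "imprinted_dmr", "region_id"]
            )
        ]["probe_id"]
        assert (c.beta.beta.loc[dmr_probes] == 0.5).all().all()

    def test_noise_free_betas_equal_copy_ratio(self):
        c = simulate_cohort(small_cfg(noise_sd=0.0, cna_rate=0.6))
        means = c.beta.beta.groupby(c.manifest.set_index("probe_id")["region_id"]).mean()
        for row in c.truth.itertuples():
            if row.total_cn == 0:
                continue
            assert means.loc[row.region_id, row.sample_id] == pytest.approx(
                row.meth_copies / row.total_cn, abs=1e-12
            )

    def test_four_to_one_minor_methylated_reads_quarter(self):
        c = simulate_cohort(small_cfg(noise_sd=0.0, cna_rate=0.9, n_tumors=40,
                                      epimutation_rate=0.0))
        t = c.truth
        sel = t[(t["total_cn"] == 4) & (t["minor_cn"] == 1)
                & (t["minor_parent"] == t["methylated_parent"])]
        assert len(sel) > 0
        assert (sel["tumor_beta"] == 0.25).all()

    def test_segments_and_truth_agree(self):
        c = simulate_cohort(small_cfg(cna_rate=0.6, noise_sd=0.0))
        from imprintcna.cna import overlap_locus_state

        imprinted = c.regions[c.regions["klass"] == "imprinted_dmr"]
        states = overlap_locus_state(
            c.segments, imprinted, c.anatomy, samples=list(c.beta.samples)
        ).set_index(["sample_id", "region_id"])
        for row in c.truth.itertuples():
            st = states.loc[(row.sample_id, row.region_id)]
            assert (st["total_cn"], st["minor_cn"]) == (row.total_cn, row.minor_cn)

    def test_segments_parse_back_through_io(self, tmp_path):
        c = simulate_cohort(small_cfg(cna_rate=0.6))
        io_formats.write_segments(c.segments, tmp_path / "seg.tsv")
        back = io_formats.read_segments(tmp_path / "seg.tsv")
        pd.testing.assert_frame_equal(back, c.segments)


class TestEpimutations:
    def test_rate_zero_leaves_truth_unchanged(self):
        c = simulate_cohort(small_cfg(epimutation_rate=0.0))
        assert (c.truth["epimutation"] == "none").all()
        assert (c.truth["meth_copies"] == c.truth["meth_copies_base"]).all()

    def test_hyper_at_diploid_locus_classifies_hypermethylated(self):
        cfg = small_cfg(cna_rate=0.0, cnnloh_rate=0.0, epimutation_rate=0.5,
                        noise_sd=0.0, n_tumors=30)
        c = simulate_cohort(cfg)
        hyper = c.truth[c.truth["epimutation"] == "hyper"]
        assert len(hyper) > 0
        assert (hyper["tumor_beta"] == 1.0).all()
        for b in hyper["tumor_beta"]:
            assert classify_state(b, 0.5) == "hypermethylated"

    def test_intermediate_flips_exactly_one_copy(self):
        c = simulate_cohort(small_cfg(epimutation_rate=0.6, cna_rate=0.6, n_tumors=40))
        inter = c.truth[c.truth["epimutation"] == "intermediate"]
        assert len(inter) > 0
        assert (abs(inter["meth_copies"] - inter["meth_copies_base"]) == 1).all()

    def test_injected_events_always_change_the_locus(self):
        c = simulate_cohort(small_cfg(epimutation_rate=0.6, cna_rate=0.5, n_tumors=40))
        hit = c.truth[c.truth["epimutation"] != "none"]
        assert (hit["meth_copies"] != hit["meth_copies_base"]).all()


class TestPurity:
    @pytest.mark.parametrize(
        "bt,bn,p,expected",
        [(0.9, 0.5, 1.0, 0.9), (0.9, 0.5, 0.0, 0.5), (1.0, 0.5, 0.722, 0.861)],
    )
    def test_linear_mix(self, bt, bn, p, expected):
        assert mix_purity(bt, bn, p) == pytest.approx(expected)

    def test_attenuation_monotone_at_epimutated_loci(self):
        cfg = small_cfg(noise_sd=0.0, epimutation_rate=0.3, n_tumors=30)
        c = simulate_cohort(cfg)
        epi = c.truth[c.truth["epimutation"] != "none"]
        prev = None
        for p in (1.0, 0.8, 0.6):
            devs = []
            for row in epi.itertuples():
                obs = mix_purity(row.tumor_beta, 0.5, p)
                devs.append(abs(obs - predicted_methylation(row.total_cn, row.minor_cn, obs)))
            m = np.mean(devs)
            assert prev is None or m <= prev + 1e-12
            prev = m


class TestRRBS:
    def test_mean_coverage_near_target(self):
        c = simulate_cohort(small_cfg(rrbs_mean_coverage=30, probes_per_region=10))
        sites = simulate_rrbs_counts(c, "T000")
        assert sites["total_count"].mean() == pytest.approx(30, rel=0.1)

    def test_fully_methylated_sites_saturate(self):
        cfg = small_cfg(cnnloh_rate=0.9, cna_rate=0.0, epimutation_rate=0.0,
                        noise_sd=0.0, n_tumors=10)
        c = simulate_cohort(cfg)
        t = c.truth.set_index(["sample_id", "region_id"])
        sites = simulate_rrbs_counts(c, "T000")
        region_of_pos = {
            (r.chrom, r.pos): r.region_id for r in c.manifest.itertuples()
        }
        for s in sites.itertuples():
            frac = t.loc[("T000", region_of_pos[(s.chrom, s.pos)]), "mixed_beta"]
            if frac == 1.0:
                assert s.meth_count == s.total_count
            if frac == 0.0:
                assert s.meth_count == 0

    def test_rrbs_agrees_with_array_averages(self):
        cfg = small_cfg(rrbs_mean_coverage=100, cna_rate=0.7, epimutation_rate=0.3,
                        n_tumors=10, probes_per_region=10, seed=4)
        c = simulate_cohort(cfg)
        sites = simulate_rrbs_counts(c, "T003")
        imprinted = c.regions[c.regions["klass"] == "imprinted_dmr"]
        rrbs_means = io_formats.aggregate_rrbs_regions(sites, imprinted, min_coverage=10)
        array_means = (
            c.beta.beta["T003"]
            .groupby(c.manifest.set_index("probe_id")["region_id"])
            .mean()
            .reindex(rrbs_means.index)
        )
        ok = rrbs_means.notna()
        rho = stats.spearmanr(rrbs_means[ok], array_means[ok]).statistic
        assert rho > 0.9


class TestRegionLayout:
    def test_default_region_set_counts_and_classes(self):
        regions = default_region_set(37, 30, 442, 166)
        assert regions["klass"].value_counts().to_dict() == {
            "bivalent": 442, "dmv": 166, "imprinted_dmr": 37, "cimp": 30,
        }
        imp = regions[regions["klass"] == "imprinted_dmr"]
        assert set(imp["methylated_parent"]) == {"maternal", "paternal"}

    def test_adding_samples_preserves_existing_draws(self):
        a = simulate_cohort(small_cfg(n_tumors=5))
        b = simulate_cohort(small_cfg(n_tumors=8))
        shared = a.truth.merge(
            b.truth, on=["sample_id", "region_id"], suffixes=("_a", "_b")
        )
        assert (shared["total_cn_a"] == shared["total_cn_b"]).all()
        assert (shared["meth_copies_a"] == shared["meth_copies_b"]).all()
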