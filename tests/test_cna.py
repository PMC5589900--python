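import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintcna import cna
from imprintcna.core import ChromosomeAnatomy, CopyNumberSegment


def seg_df(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "total_cn", "minor_cn"]
    )


class TestIsCnnloh:
    @pytest.mark.parametrize(
        "total,minor,expected",
        [(2, 0, True), (14, 0, True), (1, 0, False), (2, 1, False), (0, 0, False)],
    )
    def test_definition(self, total, minor, expected):
        assert cna.is_cnnloh(total, minor) is expected

    @given(st.integers(min_value=2, max_value=50))
    def test_monotone_in_total_for_lost_minor(self, total):
        assert cna.is_cnnloh(total, 0)


class TestBaselinePloidy:
    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_uniform_genome_returns_its_total(self, k):
        segs = seg_df([("S", "chr1", 0, 10_000_000, k, k // 2)])
        assert cna.estimate_baseline_ploidy(segs) == k

    def test_majority_total_wins(self):
        # 70% of base pairs at total 2, 30% at total 6
        segs = seg_df(
            [("S", "chr1", 0, 70_000_000, 2, 1), ("S", "chr2", 0, 30_000_000, 6, 3)]
        )
        # brute-force oracle: per-megabase expansion, plain median
        expanded = np.repeat([2, 6], [70, 30])
        assert np.median(expanded) == 2
        assert cna.estimate_baseline_ploidy(segs) == 2

    def test_weighted_median_against_expansion_oracle(self):
        rng = np.random.default_rng(17)
        totals = rng.integers(1, 9, 12)
        lengths = rng.integers(1, 50, 12)  # megabases
        segs = seg_df(
            [
                ("S", f"chr{i}", 0, int(l) * 1_000_000, int(t), 0 if t == 1 else 1)
                for i, (t, l) in enumerate(zip(totals, lengths))
            ]
        )
        oracle = int(np.floor(np.median(np.repeat(totals, lengths)) + 0.5))
        assert cna.estimate_baseline_ploidy(segs) == max(1, oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cna.estimate_baseline_ploidy(seg_df([]))


class TestBoundedness:
    ANATOMY = ChromosomeAnatomy("chr1", 100_000_000, 45_000_000, 50_000_000)

    def _cls(self, start, end):
        seg = CopyNumberSegment("S", "chr1", start, end, 4, 1)
        return cna.classify_boundedness(seg, self.ANATOMY)

    def test_segment_at_chromosome_start_is_telomere_bound(self):
        assert self._cls(0, 5_000_000) == "telomere_bound"

    def test_segment_overlapping_centromere(self):
        assert self._cls(44_000_000, 52_000_000) == "centromere_bound"

    def test_strictly_beyond_one_megabase_is_internal(self):
        # nearest anchor (telomere) at 1,000,001 bp
        assert self._cls(1_000_001, 2_000_000) == "internal"

    def test_exactly_one_megabase_is_still_bound(self):
        assert self._cls(1_000_000, 2_000_000) == "telomere_bound"

    def test_depends_only_on_coordinates(self):
        a = CopyNumberSegment("S", "chr1", 10_000_000, 20_000_000, 8, 0)
        b = CopyNumberSegment("X", "chr1", 10_000_000, 20_000_000, 1, 0)
        assert cna.classify_boundedness(a, self.ANATOMY) == cna.classify_boundedness(
            b, self.ANATOMY
        )


class TestOverlapLocusState:
    @pytest.fixture
    def regions(self):
        return pd.DataFrame(
            {
                "region_id": ["D1"],
                "chrom": ["chr1"],
                "start": [10_000_000],
                "end": [10_001_000],
                "klass": ["imprinted_dmr"],
                "methylated_parent": ["maternal"],
            }
        )

    def test_single_covering_segment(self, regions, anatomy):
        segs = seg_df([("S1", "chr1", 9_000_000, 11_000_000, 4, 1)])
        out = cna.overlap_locus_state(segs, regions, anatomy)
        row = out.iloc[0]
        assert (row.total_cn, row.minor_cn) == (4, 1)
        assert not row.assumed
        assert row.aberration == "amplification"

    def test_one_bp_overlap_is_eligible(self, regions, anatomy):
        segs = seg_df([("S1", "chr1", 9_000_000, 10_000_001, 3, 0)])
        out = cna.overlap_locus_state(segs, regions, anatomy)
        assert out.iloc[0].total_cn == 3
        assert not out.iloc[0].assumed

    def test_largest_overlap_wins_for_split_region(self, regions, anatomy):
        # 60% of the DMR under a 3:1 segment, 40% under 2:0
        segs = seg_df(
            [
                ("S1", "chr1", 9_000_000, 10_000_600, 3, 1),
                ("S1", "chr1", 10_000_600, 11_000_000, 2, 0),
            ]
        )
        out = cna.overlap_locus_state(segs, regions, anatomy)
        assert (out.iloc[0].total_cn, out.iloc[0].minor_cn) == (3, 1)

    def test_tie_broken_toward_higher_total(self, regions, anatomy):
        segs = seg_df(
            [
                ("S1", "chr1", 9_000_000, 10_000_500, 2, 0),
                ("S1", "chr1", 10_000_500, 11_000_000, 5, 1),
            ]
        )
        out = cna.overlap_locus_state(segs, regions, anatomy)
        assert out.iloc[0].total_cn == 5

    def test_uncovered_region_assumed_diploid(self, regions, anatomy):
        segs = seg_df([("S1", "chr2", 0, 1_000_000, 4, 1)])
        out = cna.overlap_locus_state(segs, regions, anatomy)
        row = out.iloc[0]
        assert (row.total_cn, row.minor_cn, row.assumed) == (2, 1, True)
        assert row.aberration == "normal"

    def test_one_row_per_sample_region_pair(self, regions, anatomy):
        regions2 = pd.concat(
            [regions, regions.assign(region_id="D2", chrom="chr2", start=1000, end=2000)]
        )
        segs = seg_df([("S1", "chr1", 0, 20_000_000, 3, 1)])
        out = cna.overlap_locus_state(
            segs, regions2, anatomy, samples=["S1", "S2", "S3"]
        )
        assert len(out) == 3 * 2
        assert set(out["sample_id"]) == {"S1", "S2", "S3"}

    def test_region_chromosome_missing_from_anatomy(self, regions, anatomy):
        segs = seg_df([("S1", "chr1", 0, 1_000_000, 2, 1)])
        bad = regions.assign(chrom="chr9")
        with pytest.raises(ValueError, match="chr9"):
            cna.overlap_locus_state(segs, bad, anatomy)


class TestCnaSizeSummary:
    def _states(self, rows):
        cols = [
            "sample_id", "region_id", "total_cn", "minor_cn", "assumed",
            "ploidy_ratio", "cnnloh", "aberration", "boundedness",
            "seg_start", "seg_end", "seg_length",
        ]
        return pd.DataFrame(rows, columns=cols)

    def test_two_row_case(self):
        states = self._states(
            [
                ("S1", "R", 4, 1, False, 2.0, False, "amplification", "internal",
                 0, 8_000_000, 8_000_000),
                ("S2", "R", 3, 1, False, 1.5, False, "amplification", "telomere_bound",
                 0, 40_000_000, 40_000_000),
            ]
        )
        table, frac = cna.cna_size_summary(states)
        internal = table[table["boundedness"] == "internal"].iloc[0]
        bound = table[table["boundedness"] == "telomere_bound"].iloc[0]
        assert internal.mean_length_bp < bound.mean_length_bp
        assert frac == 1.0

    def test_region_without_aberrations_absent(self):
        states = self._states(
            [
                ("S1", "R1", 4, 1, False, 2.0, False, "amplification", "internal",
                 0, 8_000_000, 8_000_000),
                ("S1", "R2", 2, 1, False, 1.0, False, "normal", "not_applicable",
                 0, 1_000, 1_000),
            ]
        )
        table, _ = cna.cna_size_summary(states)
        assert set(table["region_id"]) == {"R1"}

    def test_simulated_cohort_internal_smaller(self):
        rng = np.random.default_rng(23)
        rows = []
        for i in range(10):  # 10 regions, each with internal and bound events
            for j in range(5):
                rows.append(
                    (f"S{j}", f"R{i}", 6, 1, False, 3.0, False, "amplification",
                     "internal", 0, 0, rng.uniform(1e6, 10e6))
                )
                rows.append(
                    (f"S{j}", f"R{i}", 3, 1, False, 1.5, False, "amplification",
                     "telomere_bound", 0, 0, rng.uniform(20e6, 60e6))
                )
        _, frac = cna.cna_size_summary(self._states(rows))
        assert frac == pytest.approx(1.0)
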