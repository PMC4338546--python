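"""Cohort-level CNV landscape rules on constructed segment sets."""

import pytest

from tgct.cnv_landscape import (
    arm_and_chromosome_summary,
    artifact_region_filter,
    chromothripsis_flag,
    classify_scale,
    empirical_focal_background,
    exclude_unstable_samples,
    focal_recurrence_significance,
    genome_cnv_fraction,
    map_focal_to_genes,
    meta_with_external,
    rank_recurrent_genes,
)
from tgct.drivers import binomial_recurrence_test
from tgct.genome import ArmDefinition
from tgct.models import CnvSegment, GeneModel, RecurrenceRow, SampleRecord


def seg(sample="S1", chrom="1", start=0, end=1000, call="gain", scale=None,
        n_bins=3, ratio=None):
    if ratio is None:
        ratio = 1.5 if call == "gain" else (0.5 if call == "loss" else 1.0)
    s = CnvSegment(sample_id=sample, chrom=chrom, start=start, end=end,
                   n_bins=n_bins, mean_ratio=ratio, call=call,
                   specificity=1.0)
    s.scale = scale
    return s


ARMS = [
    ArmDefinition("1", "p", 0, 10_000_000),
    ArmDefinition("1", "q", 10_000_000, 24_000_000),
    ArmDefinition("12", "p", 0, 3_580_000),
    ArmDefinition("12", "q", 3_580_000, 13_385_190),
    ArmDefinition("21", "p", 0, 1_320_000, acrocentric=True),
    ArmDefinition("21", "q", 1_320_000, 4_812_990, acrocentric=True),
    ArmDefinition("X", "p", 0, 6_060_000),
    ArmDefinition("X", "q", 6_060_000, 15_527_056),
]


class TestClassifyScale:
    @pytest.mark.parametrize("length,expected", [
        (3_000_000, "large"),    # boundary belongs to large-scale
        (2_999_999, "focal"),
        (8_500, "focal"),
        (12_000_000, "large"),
    ])
    def test_boundary(self, length, expected):
        (s,) = classify_scale([seg(end=length)])
        assert s.scale == expected

    def test_neutral_segments_get_no_scale(self):
        (s,) = classify_scale([seg(call="neutral", scale="focal")])
        assert s.scale is None

    def test_partition_focal_xor_large(self):
        segs = [seg(end=e) for e in (1, 10_000, 3_000_000, 9_999_999)]
        classify_scale(segs)
        assert all((s.scale == "focal") != (s.scale == "large") for s in segs)


class TestArmSummary:
    def test_isochromosome_12p(self):
        segs = [seg(chrom="12", start=0, end=3_500_000, call="gain")]
        summary = arm_and_chromosome_summary(segs, ARMS)
        assert summary.arm_calls["S1"]["12p"] == "gain"
        assert "12q" not in summary.arm_calls["S1"]
        assert summary.isochromosome_12p == {"S1"}

    def test_whole_chromosome_gain_needs_both_arms(self):
        segs = [seg(chrom="X", start=0, end=15_500_000, call="gain")]
        summary = arm_and_chromosome_summary(segs, ARMS)
        assert summary.chrom_calls["S1"]["X"] == "gain"
        # p arm only: no chromosome call
        p_only = [seg(chrom="X", start=0, end=6_000_000, call="gain")]
        summary = arm_and_chromosome_summary(p_only, ARMS)
        assert "X" not in summary.chrom_calls.get("S1", {})

    def test_acrocentric_chromosome_called_from_q_arm(self):
        segs = [seg(chrom="21", start=1_320_000, end=4_812_000, call="gain")]
        summary = arm_and_chromosome_summary(segs, ARMS)
        assert summary.chrom_calls["S1"]["21"] == "gain"

    def test_partial_arm_coverage_below_threshold_not_called(self):
        segs = [seg(chrom="12", start=0, end=2_000_000, call="gain")]
        summary = arm_and_chromosome_summary(segs, ARMS)
        assert "S1" not in summary.arm_calls

    def test_no_segments_no_events(self):
        summary = arm_and_chromosome_summary([], ARMS)
        assert not summary.arm_calls and not summary.chrom_calls

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError, match="absent from the arm table"):
            arm_and_chromosome_summary([seg(chrom="99")], ARMS)


class TestGenomeFraction:
    def test_no_events_zero(self):
        assert genome_cnv_fraction([seg(call="neutral")], 10_000_000) == 0.0

    def test_overlap_counted_once(self):
        segs = [seg(start=0, end=1_000_000),
                seg(start=500_000, end=1_500_000)]
        assert genome_cnv_fraction(segs, 10_000_000) == pytest.approx(15.0)

    def test_invariant_under_segment_splitting(self):
        whole = [seg(start=0, end=2_000_000)]
        split = [seg(start=0, end=700_000), seg(start=700_000, end=2_000_000)]
        g = 50_000_000
        assert genome_cnv_fraction(whole, g) == \
            genome_cnv_fraction(split, g)


class TestChromothripsis:
    def _arm_segs(self, n, sample="S1"):
        return [seg(sample=sample, chrom="1", start=10_100_000 + i * 100_000,
                    end=10_100_000 + i * 100_000 + 20_000, scale="focal")
                for i in range(n)]

    def test_strictly_more_than_twenty_required(self):
        assert chromothripsis_flag(self._arm_segs(21), ARMS) == {"S1": ["1q"]}
        assert chromothripsis_flag(self._arm_segs(20), ARMS) == {}

    def test_centromere_spanning_segments_count_toward_neither_arm(self):
        spanning = [seg(chrom="1", start=9_990_000 + i, end=10_010_000 + i)
                    for i in range(25)]
        assert chromothripsis_flag(spanning, ARMS) == {}

    def test_fixture_flags_exactly_the_constructed_unstable_samples(
            self, fixture_run):
        _, report, _ = fixture_run
        truth = report  # flags computed by the pipeline
        bundle_truth = {"T32", "T33", "T34"}
        assert set(report.chromothripsis) == bundle_truth


GENES = [GeneModel("FSIP2", "2", 18_660_000, 18_757_000),
         GeneModel("NEXT", "2", 18_800_000, 18_830_000)]


class TestGeneMapping:
    def test_amplification_inside_gene_yields_one_event(self):
        s = seg(chrom="2", start=18_668_000, end=18_676_500, scale="focal")
        events = map_focal_to_genes([s], GENES)
        assert len(events) == 1
        assert events[0].gene == "FSIP2"
        assert events[0].direction == "gain"

    def test_multi_gene_segment_yields_event_per_gene(self):
        s = seg(chrom="2", start=18_650_000, end=18_820_000, scale="focal")
        assert {e.gene for e in map_focal_to_genes([s], GENES)} == \
            {"FSIP2", "NEXT"}

    def test_no_overlap_no_events(self):
        s = seg(chrom="2", start=1_000, end=2_000, scale="focal")
        assert map_focal_to_genes([s], GENES) == []

    def test_large_and_neutral_segments_ignored(self):
        segs = [seg(chrom="2", start=18_000_000, end=22_000_000, scale="large"),
                seg(chrom="2", start=18_668_000, end=18_700_000,
                    call="neutral", scale=None)]
        assert map_focal_to_genes(segs, GENES) == []


class TestArtifactFilter:
    def _events(self, spec):
        """spec: list of (sample, start, direction)."""
        out = []
        for sample, start, direction in spec:
            s = seg(sample=sample, chrom="2", start=start, end=start + 12_000,
                    call=direction, scale="focal")
            out.extend(map_focal_to_genes([s], [GeneModel("G", "2", start,
                                                          start + 50_000)]))
        return out

    def test_bidirectional_recurrent_region_removed(self):
        events = self._events([("S1", 100, "gain"), ("S2", 100, "gain"),
                               ("S3", 100, "loss"), ("S4", 100, "loss")])
        kept, report = artifact_region_filter(events)
        assert kept == []
        assert report[0]["n_samples"] == 4

    def test_unidirectional_recurrence_retained(self):
        events = self._events([(f"S{i}", 100, "gain") for i in range(5)])
        kept, report = artifact_region_filter(events)
        assert len(kept) == 5 and report == []

    def test_rare_region_retained_even_if_bidirectional(self):
        events = self._events([("S1", 100, "gain"), ("S2", 100, "loss")])
        kept, _ = artifact_region_filter(events)
        assert len(kept) == 2


class TestUnstableExclusion:
    def _samples(self, n):
        return [SampleRecord(f"S{i}", "seminoma", 30.0) for i in range(n)]

    def test_uniform_counts_exclude_nobody(self):
        samples = self._samples(10)
        counts = {s.sample_id: 2 for s in samples}
        retained, excluded = exclude_unstable_samples(samples, counts)
        assert excluded == [] and len(retained) == 10

    def test_single_extreme_outlier_excluded(self):
        samples = self._samples(41)
        counts = {s.sample_id: 1 for s in samples}
        counts["S40"] = 40
        retained, excluded = exclude_unstable_samples(samples, counts)
        assert excluded == ["S40"]
        assert len(retained) == 40

    def test_tiny_cohorts_never_filtered(self):
        samples = self._samples(2)
        retained, excluded = exclude_unstable_samples(
            samples, {"S0": 0, "S1": 1000})
        assert excluded == []

    def test_fixture_excludes_exactly_three(self, fixture_run):
        _, report, _ = fixture_run
        assert sorted(report.excluded_samples) == ["T32", "T33", "T34"]
        assert len(report.retained_samples) == 39


class TestRecurrenceRanking:
    def test_totals_and_threshold(self):
        samples = [SampleRecord(f"S{i}", "seminoma", 30.0) for i in range(10)]
        gene = GeneModel("G1", "2", 0, 50_000)
        other = GeneModel("G2", "2", 200_000, 230_000)
        events = []
        for i in range(5):
            s = seg(sample=f"S{i}", chrom="2", start=0, end=12_000,
                    call="gain", scale="focal")
            events.extend(map_focal_to_genes([s], [gene]))
        for i in range(4):  # below the >=5 bar
            s = seg(sample=f"S{i}", chrom="2", start=200_000, end=212_000,
                    call="gain", scale="focal")
            events.extend(map_focal_to_genes([s], [other]))
        rows = rank_recurrent_genes(events, samples)
        assert len(rows) == 1
        assert rows[0].genes == ("G1",)
        assert (rows[0].losses, rows[0].gains, rows[0].total) == (0, 5, 5)

    def test_identical_footprints_collapse(self):
        samples = [SampleRecord(f"S{i}", "seminoma", 30.0) for i in range(8)]
        cluster = [GeneModel("A", "2", 0, 10_000),
                   GeneModel("B", "2", 20_000, 30_000)]
        events = []
        for i in range(6):
            s = seg(sample=f"S{i}", chrom="2", start=0, end=30_000,
                    call="gain", scale="focal")
            events.extend(map_focal_to_genes([s], cluster))
        (row,) = rank_recurrent_genes(events, samples)
        assert row.genes == ("A", "B")
        assert row.gains == 6


class TestFocalSignificance:
    def test_zero_affected_gives_one(self):
        row = RecurrenceRow(("G",), "2:0-1", 0, 0, ())
        assert focal_recurrence_significance(row, 39, 0.01) == 1.0

    def test_matches_enumeration(self):
        row = RecurrenceRow(("G",), "2:0-1", 0, 6,
                            tuple(f"S{i}" for i in range(6)))
        p = focal_recurrence_significance(row, 39, 0.01)
        assert p == pytest.approx(binomial_recurrence_test(6, 39, 0.01),
                                  rel=1e-12)
        import math
        brute = sum(math.comb(39, k) * 0.01 ** k * 0.99 ** (39 - k)
                    for k in range(6, 40))
        assert p == pytest.approx(brute, rel=1e-9)

    def test_affected_exceeding_cohort_raises(self):
        row = RecurrenceRow(("G",), "2:0-1", 0, 6,
                            tuple(f"S{i}" for i in range(6)))
        with pytest.raises(ValueError):
            focal_recurrence_significance(row, 5, 0.01)

    def test_meta_of_single_equivalent_p(self):
        res = meta_with_external(0.004, 1.0)
        assert res.df == 4
        # Fisher with a unit p-value weakens but never contradicts
        assert res.combined_p > 0.004

    def test_empirical_background_scales_with_gene_and_cohort(self):
        samples = [SampleRecord(f"S{i}", "seminoma", 30.0) for i in range(10)]
        gene = GeneModel("G1", "2", 0, 50_000)
        s = seg(sample="S0", chrom="2", start=0, end=12_000, call="gain",
                scale="focal")
        events = map_focal_to_genes([s], [gene])
        p = empirical_focal_background(events, samples, gene, 100_000_000)
        expected = (1 / 10) * (12_000 + 50_000) / 100_000_000
        assert p == pytest.approx(expected, rel=1e-12)
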