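"""Outlier extraction, region merging/intersection, gene assignment."""

import numpy as np
import pandas as pd
import pytest

from poolscan.vcfio import GeneModel, table_from_cohort
from poolscan.windows import compute_window_stats
from poolscan.sweeps import (
    SweepRegion,
    ThresholdConfig,
    assign_genes,
    combine_region_sets,
    extract_outlier_windows,
    genome_fraction,
    intersect_region_sets,
    merge_windows_to_regions,
    regions_for_breed,
)


def _stats(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "z_hp_a", "z_fst_a_b"])


class TestExtractOutliers:
    def test_threshold_conventions(self):
        stats = _stats(
            [
                ("chr1", 0, 200_000, -4.1, 0.0),      # Hp outlier (autosome)
                ("chr1", 100_000, 300_000, -3.9, 0.0),  # not extreme enough
                ("chrX", 0, 200_000, -3.5, 0.0),      # Hp outlier under chrX cut
                ("chr2", 0, 200_000, 0.0, 4.0),       # exactly 4: strict, no
                ("chr2", 100_000, 300_000, 0.0, 4.2),  # FST outlier
                ("chr3", 0, 200_000, np.nan, np.nan),  # missing never qualifies
            ]
        )
        out = extract_outlier_windows(stats)
        hp = out["hp_a"]
        assert [(r.chrom, r.start) for r in hp.itertuples(index=False)] == [
            ("chr1", 0), ("chrX", 0)
        ]
        fst = out["fst_a_b"]
        assert [(r.chrom, r.start) for r in fst.itertuples(index=False)] == [
            ("chr2", 100_000)
        ]

    def test_chrx_thresholds_must_be_less_extreme(self):
        with pytest.raises(ValueError):
            ThresholdConfig(z_hp_auto=-3, z_hp_x=-4)
        with pytest.raises(ValueError):
            ThresholdConfig(z_fst_auto=3, z_fst_x=4)

    def test_detection_monotone_in_thresholds(self, small_cohort):
        """Loosening the cut-offs never removes an outlier window."""
        config, cohort = small_cohort
        stats = compute_window_stats(table_from_cohort(cohort), config.chrom_lengths)
        strict = extract_outlier_windows(stats, ThresholdConfig(-4, 4, -3, 3))
        loose = extract_outlier_windows(stats, ThresholdConfig(-3, 3, -2, 2))
        for key, wins in strict.items():
            strict_set = {(r.chrom, r.start) for r in wins.itertuples(index=False)}
            loose_set = {(r.chrom, r.start) for r in loose[key].itertuples(index=False)}
            assert strict_set <= loose_set


class TestMerging:
    def test_overlapping_and_disjoint(self):
        regions = merge_windows_to_regions(
            [("chr1", 0, 200_000, -4.5), ("chr1", 100_000, 300_000, -5.0),
             ("chr1", 500_000, 700_000, -4.2)]
        )
        assert [(r.start, r.end) for r in regions] == [(0, 300_000), (500_000, 700_000)]
        assert regions[0].peak_z == -5.0

    def test_bookended_windows_merge(self):
        regions = merge_windows_to_regions(
            [("chr1", 0, 200_000, -4.1), ("chr1", 200_000, 400_000, -4.1)]
        )
        assert [(r.start, r.end) for r in regions] == [(0, 400_000)]

    def test_ten_halfstep_windows_span_1_1_mb(self):
        wins = [("chr1", i * 100_000, i * 100_000 + 200_000, -4.1) for i in range(10)]
        regions = merge_windows_to_regions(wins)
        assert len(regions) == 1
        assert regions[0].width == 1_100_000  # 200k + 9 * 100k

    def test_idempotent_and_order_independent(self):
        wins = [("chr2", 400_000, 600_000, -4.0), ("chr1", 0, 200_000, -4.2),
                ("chr2", 500_000, 700_000, -6.0), ("chr1", 100_000, 300_000, -4.1)]
        a = merge_windows_to_regions(wins)
        b = merge_windows_to_regions(list(reversed(wins)))
        assert [(r.chrom, r.start, r.end, r.peak_z) for r in a] == [
            (r.chrom, r.start, r.end, r.peak_z) for r in b
        ]
        again = merge_windows_to_regions(
            [(r.chrom, r.start, r.end, r.peak_z) for r in a]
        )
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in a]

    def test_merged_output_never_overlaps(self):
        rng = np.random.default_rng(5)
        wins = [
            ("chr1", int(s), int(s) + 200_000, -4.5)
            for s in rng.integers(0, 5_000_000, 100) // 100_000 * 100_000
        ]
        regions = merge_windows_to_regions(wins)
        for prev, nxt in zip(regions, regions[1:]):
            assert prev.end <= nxt.start


class TestCombineIntersect:
    def test_intersection_examples(self):
        a = [SweepRegion("chr1", 0, 300_000, source=frozenset({"hp_a"}))]
        b = [SweepRegion("chr1", 200_000, 500_000, source=frozenset({"fst_a_b"}))]
        overlap, bp = intersect_region_sets(a, b)
        assert [(r.start, r.end) for r in overlap] == [(200_000, 300_000)]
        assert bp == 100_000
        assert overlap[0].source == frozenset({"hp_a", "fst_a_b"})

    def test_disjoint_sets_empty_intersection(self):
        a = [SweepRegion("chr1", 0, 100)]
        b = [SweepRegion("chr1", 200, 300)]
        overlap, bp = intersect_region_sets(a, b)
        assert overlap == [] and bp == 0

    def test_subset_intersection_is_subset(self):
        a = [SweepRegion("chr1", 100, 200)]
        b = [SweepRegion("chr1", 0, 1000)]
        overlap, bp = intersect_region_sets(a, b)
        assert [(r.start, r.end) for r in overlap] == [(100, 200)]
        assert bp == 100

    def test_union_concatenates_provenance(self):
        a = [SweepRegion("chr1", 0, 300, source=frozenset({"hp_a"}))]
        b = [SweepRegion("chr1", 200, 500, source=frozenset({"fst_a_b"}))]
        union = combine_region_sets(a, b)
        assert [(r.start, r.end) for r in union] == [(0, 500)]
        assert union[0].source == frozenset({"hp_a", "fst_a_b"})


class TestAssignGenes:
    GENES = [
        GeneModel("inside", "chr1", 100_000, 120_000),
        GeneModel("flank_hit", "chr1", 350_000, 360_000),
        GeneModel("too_far", "chr1", 401_000, 410_000),
        GeneModel("other_chrom", "chr2", 0, 10_000),
    ]

    def test_flank_overlap(self):
        regions = assign_genes([SweepRegion("chr1", 0, 300_000)], self.GENES, flank=100_000)
        assert regions[0].genes == ("flank_hit", "inside")

    def test_zero_flank_bookended_gene_excluded(self):
        gene = GeneModel("bookend", "chr1", 300_000, 310_000)
        regions = assign_genes([SweepRegion("chr1", 0, 300_000)], [gene], flank=0)
        assert regions[0].genes == ()


class TestGenomeFraction:
    def test_printed_identities(self):
        genome = {"all": 2_587_507_083}
        _, pct = genome_fraction([SweepRegion("all", 0, 45_700_000)], genome)
        assert round(pct, 2) == 1.77
        _, pct = genome_fraction([SweepRegion("all", 0, 51_700_000)], genome)
        assert round(pct, 1) == 2.0

    def test_empty_and_overlapping(self):
        total, pct = genome_fraction([], {"chr1": 1000})
        assert (total, pct) == (0, 0.0)
        with pytest.raises(ValueError, match="overlap"):
            genome_fraction(
                [SweepRegion("chr1", 0, 100), SweepRegion("chr1", 50, 150)],
                {"chr1": 1000},
            )


class TestEndToEndRecovery:
    def test_planted_sweep_recovered_for_swept_breed(self, small_cohort):
        config, cohort = small_cohort
        stats = compute_window_stats(table_from_cohort(cohort), config.chrom_lengths)
        outliers = extract_outlier_windows(stats)
        regions = regions_for_breed(outliers, "breed1")
        sweep = config.sweeps[0]
        assert any(
            r.chrom == sweep.chrom and r.start < sweep.end and r.end > sweep.start
            for r in regions
        )
        # the union carries Hp provenance for the swept breed
        hit = next(r for r in regions if r.chrom == sweep.chrom and r.start < sweep.end)
        assert any(s.startswith("hp_breed1") for s in hit.source)
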