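import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restquant import region_stats as rs
from tests.conftest import regions


class TestRegionSetBasics:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            regions(("chr1", 10, 10))
        with pytest.raises(ValueError):
            regions(("chr1", -1, 5))

    def test_summit_must_be_inside(self):
        with pytest.raises(ValueError):
            regions(("chr1", 0, 100, 100))

    def test_merge_idempotent_and_order_invariant(self):
        a = regions(("chr1", 0, 10), ("chr1", 5, 20), ("chr2", 0, 5))
        b = regions(("chr2", 0, 5), ("chr1", 5, 20), ("chr1", 0, 10))
        ma, mb = a.merged(), b.merged()
        pd.testing.assert_frame_equal(ma.df, mb.df)
        pd.testing.assert_frame_equal(ma.df, ma.merged().df)
        assert len(ma) == 2

    def test_adjacent_half_open_intervals_do_not_merge_overlap(self):
        merged = regions(("chr1", 0, 10), ("chr1", 10, 20)).merged()
        # [0,10) and [10,20) are book-ended: merged as one span but the
        # overlap test treats them as non-overlapping intervals
        peaks = regions(("chr1", 0, 10))
        dom = regions(("chr1", 10, 20))
        assert rs.overlap_fraction(peaks, dom) == 0.0
        assert len(merged) == 1

    def test_bed_round_trip_byte_identical(self, tmp_path):
        path = tmp_path / "a.bed"
        content = "chr1\t0\t100\nchr1\t200\t300\nchr2\t5\t50\n"
        path.write_text(content)
        out = tmp_path / "b.bed"
        rs.RegionSet.read_bed(path).write_bed(out)
        assert out.read_bytes() == path.read_bytes()

    def test_narrowpeak_round_trip_summit_and_q(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t500\tpeak1\t0\t.\t5.5\t10\t6\t50\n")
        peaks = rs.RegionSet.read_narrowpeak(path)
        assert peaks.summits()[0] == 150
        assert peaks.df["qvalue"][0] == pytest.approx(1e-6)
        out = tmp_path / "b.narrowPeak"
        peaks.write_narrowpeak(out)
        assert rs.RegionSet.read_narrowpeak(out).summits()[0] == 150


class TestOverlapFraction:
    def test_peaks_inside_domains(self):
        peaks = regions(("chr1", 10, 20), ("chr1", 50, 60))
        domains = regions(("chr1", 0, 100))
        assert rs.overlap_fraction(peaks, domains) == 1.0

    def test_disjoint_chromosomes(self):
        assert (
            rs.overlap_fraction(regions(("chr1", 0, 10)), regions(("chr2", 0, 10)))
            == 0.0
        )

    def test_half_open_single_bp_boundary(self):
        peak = regions(("chr1", 100, 200))
        assert rs.overlap_fraction(peak, regions(("chr1", 199, 300))) == 1.0
        assert rs.overlap_fraction(peak, regions(("chr1", 200, 300))) == 0.0

    def test_unknown_chromosome_is_coordinate_error(self, toy_genome):
        with pytest.raises(rs.CoordinateError):
            rs.overlap_fraction(
                regions(("chrX", 0, 10)), regions(("chr1", 0, 10)), toy_genome
            )


class TestRandomizeRegions:
    def test_single_chromosome_lengths_exact(self):
        genome = rs.Genome({"chrZ": 10_000})
        src = regions(("chrZ", 0, 100), ("chrZ", 500, 800), ("chrZ", 900, 901))
        out = rs.randomize_regions(src, genome, seed=5)
        assert set(out.df["chrom"]) == {"chrZ"}
        assert sorted(out.lengths) == sorted(src.lengths)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_length_multiset_preserved_every_seed(self, seed):
        genome = rs.Genome({"chr1": 50_000, "chr2": 10_000})
        src = regions(
            ("chr1", 0, 700), ("chr1", 100, 101), ("chr2", 0, 700), ("chr2", 5, 305)
        )
        out = rs.randomize_regions(src, genome, seed=seed)
        assert sorted(out.lengths) == sorted(src.lengths)
        out.validate_against(genome)

    def test_region_longer_than_every_chromosome(self):
        src = rs.RegionSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        )
        with pytest.raises(rs.PlacementError):
            rs.randomize_regions(src, rs.Genome({"chr1": 50, "chr2": 80}))

    def test_uniform_coverage_expectation(self):
        # 1 bp regions vs a domain covering half the genome
        genome = rs.Genome({"chr1": 1_000_000})
        domain = regions(("chr1", 0, 500_000))
        n = 3000
        src = rs.RegionSet(
            pd.DataFrame({"chrom": "chr1", "start": np.zeros(n, int), "end": np.ones(n, int)})
        )
        out = rs.randomize_regions(src, genome, seed=11)
        frac = rs.overlap_fraction(out, domain)
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se


class TestPermutationOverlap:
    def test_maximal_statistic_hits_p_floor(self, toy_genome):
        # every observed peak overlaps; the null essentially never ties
        domains = regions(("chr1", 0, 500_000))
        starts = np.arange(20) * 10_000
        peaks = rs.RegionSet(
            pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})
        )
        res = rs.permutation_overlap(peaks, domains, toy_genome, n_perm=200, seed=0)
        assert res.observed == 20
        assert res.p == pytest.approx(1 / 201)

    def test_empty_domains_degenerate(self, toy_genome):
        peaks = regions(("chr1", 10, 500))
        domains = rs.RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        res = rs.permutation_overlap(peaks, domains, toy_genome, n_perm=50, seed=0)
        assert res.observed == 0
        assert res.p == 1.0
        assert res.degenerate and res.z == 0.0

    def test_seed_reproducible(self, toy_genome):
        peaks = regions(("chr1", 10, 500), ("chr1", 5000, 5400))
        domains = regions(("chr1", 0, 100_000))
        r1 = rs.permutation_overlap(peaks, domains, toy_genome, n_perm=300, seed=42)
        r2 = rs.permutation_overlap(peaks, domains, toy_genome, n_perm=300, seed=42)
        assert r1 == r2

    def test_fraction_statistic_same_p(self, toy_genome):
        peaks = regions(("chr1", 10, 500), ("chr1", 5000, 5400))
        domains = regions(("chr1", 0, 100_000))
        rc = rs.permutation_overlap(peaks, domains, toy_genome, n_perm=300, seed=7)
        rf = rs.permutation_overlap(
            peaks, domains, toy_genome, n_perm=300, seed=7, statistic="fraction"
        )
        assert rc.p == rf.p
        assert rf.observed == pytest.approx(rc.observed / 2)


class TestConsensusPresence:
    def test_two_of_three_with_close_summits(self):
        rep1 = regions(("chr1", 900, 1100, 1000))
        rep2 = regions(("chr1", 940, 1140, 1040))
        rep3 = rs.RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        consensus, presence = rs.consensus_presence(
            [rep1, rep2, rep3], min_support=2, summit_window_bp=100
        )
        assert len(consensus) == 1
        assert consensus.df.loc[0, "start"] == 900
        assert consensus.df.loc[0, "end"] == 1140
        assert presence.shape == (1, 3)

    def test_singleton_peak_absent(self):
        rep1 = regions(("chr1", 900, 1100, 1000))
        empty = rs.RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        consensus, _ = rs.consensus_presence(
            [rep1, empty, empty], min_support=2, summit_window_bp=100
        )
        assert len(consensus) == 0

    def test_boundary_summit_distance_equal_to_window_joins(self):
        rep1 = regions(("chr1", 900, 1100, 1000))
        rep2 = regions(("chr1", 1000, 1200, 1100))
        consensus, _ = rs.consensus_presence(
            [rep1, rep2], min_support=2, summit_window_bp=100
        )
        assert len(consensus) == 1
        consensus2, _ = rs.consensus_presence(
            [rep1, rep2], min_support=2, summit_window_bp=99
        )
        assert len(consensus2) == 0

    def test_replicate_order_invariance(self):
        reps = [
            regions(("chr1", 900, 1100, 1000), ("chr2", 0, 200, 100)),
            regions(("chr1", 940, 1140, 1040)),
            regions(("chr2", 20, 220, 120)),
        ]
        c1, _ = rs.consensus_presence(reps, min_support=2, summit_window_bp=100)
        c2, _ = rs.consensus_presence(reps[::-1], min_support=2, summit_window_bp=100)
        pd.testing.assert_frame_equal(
            c1.df[["chrom", "start", "end"]], c2.df[["chrom", "start", "end"]]
        )

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            rs.consensus_presence(
                [regions(("chr1", 0, 10))] * 2, summit_window_bp=-1
            )


class TestDifferentialPresence:
    def test_emerging_and_neither(self):
        peak = ("chr1", 900, 1100, 1000)
        empty = rs.RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        group_a = [empty, empty, empty]
        group_b = [regions(peak), regions(peak), regions(peak)]
        emerging, vanishing = rs.differential_presence(group_a, group_b)
        assert len(emerging) == 1 and len(vanishing) == 0
        # 2-of-3 in both groups -> neither list
        group_a2 = [regions(peak), regions(peak), empty]
        emerging2, vanishing2 = rs.differential_presence(group_a2, group_b)
        assert len(emerging2) == 0 and len(vanishing2) == 0

    def test_planted_emerging_and_vanishing_recovered(self):
        # 5 peaks only in group A, 5 only in group B, 3 shared
        a_only = [("chr1", 1000 * i, 1000 * i + 200, 1000 * i + 100) for i in range(1, 6)]
        b_only = [("chr1", 1000 * i, 1000 * i + 200, 1000 * i + 100) for i in range(10, 15)]
        shared = [("chr2", 1000 * i, 1000 * i + 200, 1000 * i + 100) for i in range(3)]
        group_a = [regions(*(a_only + shared)) for _ in range(3)]
        group_b = [regions(*(b_only + shared)) for _ in range(3)]
        emerging, vanishing = rs.differential_presence(group_a, group_b)
        assert len(emerging) == 5
        assert len(vanishing) == 5
        assert set(emerging.df["start"]) == {s for _, s, _, _ in b_only}
        assert set(vanishing.df["start"]) == {s for _, s, _, _ in a_only}


class TestAnnotationZtest:
    def test_worked_normal_tail(self):
        rand = [15.0, 20.0, 25.0, 20.0, 20.0]  # mean 20, sample sd 3.5355
        sd = np.std(rand, ddof=1)
        out = rs.annotation_ztest({"promoter": 30}, {"promoter": rand})
        row = out.iloc[0]
        assert row["z"] == pytest.approx((30 - 20) / sd)
        from scipy.stats import norm

        assert row["p"] == pytest.approx(norm.sf((30 - 20) / sd))

    def test_observed_equals_mean(self):
        out = rs.annotation_ztest({"x": 20}, {"x": [10.0, 20.0, 30.0]})
        assert out.iloc[0]["z"] == 0.0
        assert out.iloc[0]["p"] == 0.5

    def test_degenerate_constant_null(self):
        out = rs.annotation_ztest({"x": 30}, {"x": [20] * 10})
        row = out.iloc[0]
        assert row["degenerate"]
        assert row["z"] == np.inf
        assert row["p"] == pytest.approx(1 / 11)

    def test_depletion_direction(self):
        out = rs.annotation_ztest(
            {"x": 10}, {"x": [15.0, 20.0, 25.0]}, alternative="less"
        )
        assert out.iloc[0]["p"] < 0.5


class TestAnnotateToTss:
    def _tss(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "chrom": ["chr1", "chr1", "chr2"],
                "tss": [10_000, 50_000, 10_000],
                "strand": ["+", "-", "+"],
            }
        )

    def _peaks(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "qvalue"])
        return rs.RegionSet(df)

    def test_boundary_window_closed_and_q_strict(self):
        peaks = self._peaks(
            [
                ("chr1", 12_800, 13_200, 13_000, 1e-9),  # exactly tss+3000 -> kept
                ("chr1", 49_000, 49_400, 49_200, 1e-5),  # q == 1e-5 -> dropped
            ]
        )
        genes = rs.annotate_to_tss(peaks, self._tss())
        assert genes.members == frozenset({"A"})

    def test_toy_table_two_genes(self):
        peaks = self._peaks(
            [
                ("chr1", 9_900, 10_300, 10_100, 1e-9),  # A, near TSS
                ("chr1", 48_500, 48_900, 48_700, 1e-9),  # B, within 3000
                ("chr1", 60_000, 60_400, 60_200, 1e-9),  # outside every window
                ("chr2", 9_000, 9_400, 9_200, 1e-4),  # C but fails q
            ]
        )
        genes = rs.annotate_to_tss(peaks, self._tss())
        assert genes.members == frozenset({"A", "B"})

    def test_missing_qvalues_schema_error(self):
        peaks = regions(("chr1", 9_900, 10_300, 10_100))
        with pytest.raises(KeyError):
            rs.annotate_to_tss(peaks, self._tss(), q_max=1e-5)

    def test_no_q_filter_without_qvalues(self):
        peaks = regions(("chr1", 9_900, 10_300, 10_100))
        genes = rs.annotate_to_tss(peaks, self._tss(), q_max=None)
        assert genes.members == frozenset({"A"})
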