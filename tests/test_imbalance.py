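"""Strand-aware coverage, junction counting, fold-change and changepoint fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusimba.gene_model import BreakpointSpec, exon_partition
from fusimba.imbalance import (
    ImbalanceResult,
    ImbalanceThresholds,
    JunctionCounts,
    StrandedCoverage,
    auto_breakpoint,
    count_spliced_reads,
    evaluate_imbalance,
    imbalance_statistic,
    stranded_exon_coverage,
    transcript_strand,
)
from fusimba.simulate import SimConfig, simulate_sample

from conftest import make_read, sense_pair


def brute_force_pileup(reads, gene, orientation="RF"):
    """Per-base pileup restricted to gene-strand reads, averaged per exon."""
    span = gene.span
    sense = np.zeros(span[1] - span[0])
    anti = np.zeros(span[1] - span[0])
    for read in reads:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < 1
            or read.reference_name != gene.chrom
        ):
            continue
        track = (
            sense
            if transcript_strand(read, orientation) == gene.strand
            else anti
        )
        for bs, be in read.get_blocks():
            for pos in range(max(bs, span[0]), min(be, span[1])):
                track[pos - span[0]] += 1
    def per_exon(track):
        return np.array(
            [track[s - span[0] : e - span[0]].mean() for s, e in gene.exons]
        )
    return per_exon(sense), per_exon(anti)


class TestStrandedCoverage:
    def test_ten_sense_reads_give_10x_single_exon(self, header, single_exon_gene):
        # single-end sense reads for a '+' gene under RF align on '-'
        reads = [
            make_read(header, f"r{i}", "chr1", 1000, "100M", reverse=True)
            for i in range(10)
        ]
        cov = stranded_exon_coverage(reads, single_exon_gene)
        assert cov.sense_mean_depth.tolist() == [10.0]
        assert cov.antisense_mean_depth.tolist() == [0.0]

    def test_antisense_unspliced_reads_do_not_leak_into_sense(
        self, header, single_exon_gene
    ):
        sense = [
            make_read(header, f"s{i}", "chr1", 1000, "100M", reverse=True)
            for i in range(10)
        ]
        anti = [
            make_read(header, f"a{i}", "chr1", 1000, "100M", reverse=False)
            for i in range(7)
        ]
        cov = stranded_exon_coverage(sense + anti, single_exon_gene)
        assert cov.sense_mean_depth.tolist() == [10.0]
        assert cov.antisense_mean_depth.tolist() == [7.0]

    def test_random_fixture_matches_brute_force_pileup(self, plus_gene):
        bp = BreakpointSpec("PLUS6", 3, "3prime")
        config = SimConfig(
            gene=plus_gene,
            breakpoint=bp,
            seed=11,
            tcc=80,
            fusion_expression=5.0,
            wildtype_expression=1.0,
            antisense_premrna_depth=2.0,
        )
        reads, _, _ = simulate_sample(config)
        cov = stranded_exon_coverage(reads, plus_gene)
        oracle_sense, oracle_anti = brute_force_pileup(reads, plus_gene)
        np.testing.assert_allclose(cov.sense_mean_depth, oracle_sense, atol=1e-9)
        np.testing.assert_allclose(cov.antisense_mean_depth, oracle_anti, atol=1e-9)

    def test_coverage_conserves_total_aligned_bases(self, plus_gene):
        config = SimConfig(
            gene=plus_gene,
            breakpoint=BreakpointSpec("PLUS6", 2, "3prime"),
            seed=5,
            fusion_expression=4.0,
            wildtype_expression=1.5,
            antisense_premrna_depth=1.0,
        )
        reads, _, _ = simulate_sample(config)
        cov = stranded_exon_coverage(reads, plus_gene)
        total = float(
            ((cov.sense_mean_depth + cov.antisense_mean_depth) * cov.exon_lengths).sum()
        )
        oracle = 0
        for read in reads:
            for bs, be in read.get_blocks():
                for s, e in plus_gene.exons:
                    oracle += max(0, min(be, e) - max(bs, s))
        assert total == pytest.approx(oracle)

    def test_filtered_reads_are_excluded(self, header, single_exon_gene):
        reads = [
            make_read(header, "ok", "chr1", 1000, "100M", reverse=True),
            make_read(header, "dup", "chr1", 1000, "100M", reverse=True, duplicate=True),
            make_read(header, "sec", "chr1", 1000, "100M", reverse=True, secondary=True),
            make_read(header, "mq0", "chr1", 1000, "100M", reverse=True, mapq=0),
        ]
        cov = stranded_exon_coverage(reads, single_exon_gene)
        assert cov.sense_mean_depth.tolist() == [1.0]

    def test_missing_contig_in_header_raises(self, single_exon_gene, tmp_path):
        import pysam

        path = tmp_path / "empty.sam"
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrOther", "LN": 1000}]}
        )
        with pysam.AlignmentFile(str(path), "w", header=header):
            pass
        with pytest.raises(ValueError, match="chr1"):
            stranded_exon_coverage(str(path), single_exon_gene)


class TestCountSplicedReads:
    def test_84_vs_0_one_sided_junctions(self, header, alk_like_gene, alk_breakpoint):
        # junction between exons 21 and 20 (transcription order) of the
        # minus-strand gene: entirely within the 3' partition
        e21 = alk_like_gene.exons[20]
        e20 = alk_like_gene.exons[19]
        gap = e20[0] - e21[1]
        reads = []
        for i in range(84):
            reads.extend(
                sense_pair(
                    header,
                    f"j{i}",
                    "chr2",
                    "-",
                    e21[1] - 50,
                    f"50M{gap}N50M",
                    mate_cigar="50M",  # mate 1 stays unspliced within exon 21
                )
            )
        jc = count_spliced_reads(reads, alk_like_gene, alk_breakpoint)
        assert (jc.n5, jc.n3, jc.n_spanning) == (0, 84, 0)

    def test_unspliced_reads_count_nothing(self, header, plus_gene):
        bp = BreakpointSpec("PLUS6", 3, "3prime")
        reads = sense_pair(header, "u", "chr1", "+", 1000, "100M")
        jc = count_spliced_reads(reads, plus_gene, bp)
        assert (jc.n5, jc.n3, jc.n_spanning) == (0, 0, 0)

    def test_boundary_crossing_junction_is_spanning(self, header, plus_gene):
        bp = BreakpointSpec("PLUS6", 3, "3prime")
        # exon 3 ends at 2100, exon 4 starts at 2500
        reads = sense_pair(header, "x", "chr1", "+", 2050, "50M400N50M",
                           mate_cigar="50M")  # only mate 2 crosses the boundary
        jc = count_spliced_reads(reads, plus_gene, bp)
        assert (jc.n5, jc.n3, jc.n_spanning) == (0, 0, 1)

    def test_antisense_spliced_reads_ignored(self, header, plus_gene):
        bp = BreakpointSpec("PLUS6", 3, "3prime")
        # single-end forward read = antisense for a '+' gene under RF
        reads = [make_read(header, "a", "chr1", 1050, "50M400N50M", reverse=False)]
        jc = count_spliced_reads(reads, plus_gene, bp)
        assert (jc.n5, jc.n3, jc.n_spanning) == (0, 0, 0)


class TestAntisenseInvariance:
    def test_added_antisense_changes_no_reported_number(
        self, plus_gene, header
    ):
        bp = BreakpointSpec("PLUS6", 3, "3prime")
        base = SimConfig(
            gene=plus_gene,
            breakpoint=bp,
            seed=21,
            fusion_expression=6.0,
            wildtype_expression=0.5,
            antisense_premrna_depth=0.0,
        )
        reads, _, _ = simulate_sample(base)
        anti = [
            make_read(header, f"anti{i}", "chr1", 1000 + 37 * i, "80M")
            for i in range(50)
        ]
        cov_clean = stranded_exon_coverage(reads, plus_gene)
        cov_noisy = stranded_exon_coverage(reads + anti, plus_gene)
        np.testing.assert_array_equal(
            cov_clean.sense_mean_depth, cov_noisy.sense_mean_depth
        )
        assert count_spliced_reads(reads, plus_gene, bp) == count_spliced_reads(
            reads + anti, plus_gene, bp
        )


class TestImbalanceStatistic:
    def cov(self, depths, lengths=None):
        n = len(depths)
        lengths = lengths or [100] * n
        return StrandedCoverage("G", np.array(depths), np.zeros(n), np.array(lengths))

    def test_printed_means_give_fold_change_under_pseudocount(self):
        # two pseudo-exons carrying the side means directly
        cov = self.cov([0.03, 7.37])
        m5, m3, fc = imbalance_statistic(
            cov, (frozenset({1}), frozenset({2})), "3prime", epsilon=0.05
        )
        assert (m5, m3) == (0.03, 7.37)
        assert fc == pytest.approx(7.42 / 0.08)  # 92.75

    def test_equal_means_give_unity(self):
        cov = self.cov([3.3, 3.3, 3.3, 3.3])
        _, _, fc = imbalance_statistic(
            cov, (frozenset({1, 2}), frozenset({3, 4})), "3prime", epsilon=0.7
        )
        assert fc == pytest.approx(1.0)

    def test_zero_other_side_bounded_by_pseudocount(self):
        cov = self.cov([0.0, 5.0])
        _, _, fc = imbalance_statistic(
            cov, (frozenset({1}), frozenset({2})), "3prime", epsilon=0.05
        )
        assert fc == pytest.approx(101.0)

    def test_length_weighting(self):
        cov = self.cov([1.0, 3.0, 10.0], lengths=[300, 100, 100])
        m5, m3, _ = imbalance_statistic(
            cov, (frozenset({1, 2}), frozenset({3})), "3prime"
        )
        assert m5 == pytest.approx((1.0 * 300 + 3.0 * 100) / 400)
        m5_plain, _, _ = imbalance_statistic(
            cov, (frozenset({1, 2}), frozenset({3})), "3prime", length_weighted=False
        )
        assert m5_plain == pytest.approx(2.0)

    def test_empty_side_rejected(self):
        cov = self.cov([1.0, 2.0])
        with pytest.raises(ValueError):
            imbalance_statistic(cov, (frozenset(), frozenset({1, 2})), "3prime")

    @given(
        retained=st.floats(0.1, 50),
        other=st.floats(0.0, 50),
        bump=st.floats(0.1, 10),
    )
    @settings(derandomize=True, max_examples=50)
    def test_fold_change_monotone_in_each_mean(self, retained, other, bump):
        eps = 0.05
        fc = (retained + eps) / (other + eps)
        assert (retained + bump + eps) / (other + eps) > fc
        assert (retained + eps) / (other + bump + eps) < fc

    def test_pseudocount_limit_drives_fold_change_to_unity(self):
        cov = self.cov([0.0, 9.0])
        _, _, fc = imbalance_statistic(
            cov, (frozenset({1}), frozenset({2})), "3prime", epsilon=1e9
        )
        assert fc == pytest.approx(1.0, abs=1e-6)


def rss_oracle(y):
    """Exhaustive two-mean step fit; returns (best k, rss per k, null rss)."""
    n = len(y)
    rss = {}
    for k in range(1, n):
        left, right = y[:k], y[k:]
        rss[k] = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
    null = ((y - y.mean()) ** 2).sum()
    best = min(rss, key=lambda k: (rss[k], k))
    return best, rss, null


class TestAutoBreakpoint:
    def test_clean_step_recovered(self):
        k, gain = auto_breakpoint([0, 0, 0, 8, 8, 8], epsilon=0.05)
        assert k == 3
        assert gain > 0

    def test_constant_profile_gives_zero_gain_and_first_boundary(self):
        k, gain = auto_breakpoint([2.0, 2.0, 2.0, 2.0])
        assert k == 1
        assert gain == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_four_exons_rejected(self):
        with pytest.raises(ValueError, match="4 exons"):
            auto_breakpoint([1.0, 5.0, 5.0])

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60)
    def test_agrees_with_exhaustive_rss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        depths = rng.lognormal(mean=rng.normal(0, 2), sigma=1.0, size=n)
        eps = 0.05
        k_impl, gain_impl = auto_breakpoint(depths, eps)
        y = np.log2(depths + eps)
        k_oracle, rss, null = rss_oracle(y)
        assert k_impl == k_oracle
        assert gain_impl == pytest.approx(null - rss[k_oracle], abs=1e-9)
        assert all(rss[k_impl] <= rss[k] + 1e-12 for k in rss)


class TestEvaluateImbalance:
    def result(self, mean5, mean3, n5, n3, retained="3prime"):
        eps = 0.05
        retained_mean, other_mean = (
            (mean3, mean5) if retained == "3prime" else (mean5, mean3)
        )
        return ImbalanceResult(
            gene_id="G",
            breakpoint=BreakpointSpec("G", 19, retained),
            mean5=mean5,
            mean3=mean3,
            fold_change=(retained_mean + eps) / (other_mean + eps),
            junctions=JunctionCounts(n5=n5, n3=n3),
        )

    def test_alk_like_case_is_flagged_for_orthogonal_confirmation(self):
        out = evaluate_imbalance(self.result(0.03, 7.37, 0, 84))
        assert out.flagged
        assert out.recommendation == "orthogonal_confirmation"

    def test_balanced_gene_not_flagged(self):
        out = evaluate_imbalance(self.result(5.0, 5.0, 40, 40))
        assert not out.flagged and out.recommendation == "none"

    def test_high_fold_change_with_shallow_retained_depth_not_flagged(self):
        # FC = 50 but retained mean below the 2x depth floor
        res = self.result(0.0, 0.5, 0, 30)
        res.fold_change = 50.0
        assert not evaluate_imbalance(res).flagged

    def test_junction_delta_required(self):
        out = evaluate_imbalance(self.result(0.03, 7.37, 40, 42))
        assert not out.flagged

    def test_5prime_retained_side_supported(self):
        out = evaluate_imbalance(self.result(7.37, 0.03, 84, 0, retained="5prime"))
        assert out.flagged
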