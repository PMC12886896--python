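"""Synthetic generators: determinism, planted-effect bookkeeping, null cases."""

import numpy as np
import pytest

from germ_epimem import synth, tracks
from germ_epimem.core_io import tss_of
from germ_epimem.smallrna import filter_22g
from germ_epimem.synth import ChipSimParams, SyntheticTruth


class TestGenome:
    def test_seeded_determinism(self):
        a = synth.simulate_genome(1, 10_000, seed=1)
        b = synth.simulate_genome(1, 10_000, seed=1)
        assert a.sequences == b.sequences

    def test_shape(self):
        g = synth.simulate_genome(2, 5_000, seed=1)
        assert list(g.lengths.values()) == [5000, 5000]
        assert len(g.lengths) == 2

    def test_different_seeds_differ(self):
        a = synth.simulate_genome(1, 10_000, seed=1)
        b = synth.simulate_genome(1, 10_000, seed=2)
        assert a.sequences != b.sequences

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_genome(1, 10, seed=1)


class TestAnnotation:
    def test_layout_non_overlapping(self):
        genome = synth.simulate_genome(1, 10_000, seed=3)
        ann = synth.simulate_annotation(genome, 5, gene_length=500, spacing=1000, seed=3)
        assert len(ann) == 5
        intervals = sorted((g.interval.start, g.interval.end) for g in ann)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2

    def test_capacity_error(self):
        genome = synth.simulate_genome(1, 10_000, seed=3)
        with pytest.raises(ValueError, match="capacity"):
            synth.simulate_annotation(genome, 50, gene_length=500, spacing=1000, seed=3)

    def test_seeded_determinism(self):
        genome = synth.simulate_genome(1, 20_000, seed=4)
        a = synth.simulate_annotation(genome, 8, seed=4)
        b = synth.simulate_annotation(genome, 8, seed=4)
        assert [(g.gene_id, g.interval) for g in a] == [(g.gene_id, g.interval) for g in b]


class TestChipLibrary:
    def test_null_multiplier_gives_equal_expectation(self, toy_genome, toy_annotation):
        """With multiplier 1 the IP read count near any TSS matches between
        genotypes within Poisson error."""
        truth = SyntheticTruth(
            enriched_genes={toy_annotation.gene_ids[0]: 1.0}, params={"seed": 5}
        )
        params = ChipSimParams(seed=5, depth=50_000, background_rate=0.05,
                               baseline_peak_height=200.0)
        wt = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "wild_type", "IP", 1
        )
        mut = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "mutant", "IP", 1
        )
        gene = toy_annotation[toy_annotation.gene_ids[0]]
        chrom, tss = tss_of(gene)

        def near_tss(rs):
            df = rs.reads
            sel = (df["chrom"] == chrom) & (df["pos5"] - tss).abs().le(500)
            return int(sel.sum())

        n_wt, n_mut = near_tss(wt), near_tss(mut)
        assert abs(n_wt - n_mut) < 4 * np.sqrt(n_wt + n_mut)

    def test_input_library_flat_coverage(self, toy_genome, toy_annotation):
        truth = SyntheticTruth(params={"seed": 6})
        params = ChipSimParams(seed=6, depth=100_000)
        rs = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "wild_type", "input", 1
        )
        assert rs.library_size == 100_000
        track = tracks.bin_coverage(rs, toy_genome, bin_size=1000, fragment_length=200)
        values = np.concatenate([track.values[c] for c in track.values])
        # flat within sampling error: each kilobase bin sees ~depth*1200/L reads
        expected = 100_000 * 1200 / 100_000
        assert abs(values.mean() - expected) < 3 * values.std() / np.sqrt(len(values))

    def test_planted_multiplier_recovered_in_read_ratio(self, toy_genome, toy_annotation):
        planted = toy_annotation.gene_ids[3]
        truth = SyntheticTruth(enriched_genes={planted: 3.0}, params={"seed": 7})
        params = ChipSimParams(seed=7, depth=100_000, background_rate=0.02,
                               baseline_peak_height=2000.0)
        wt = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "wild_type", "IP", 1
        )
        mut = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "mutant", "IP", 1
        )
        chrom, tss = tss_of(toy_annotation[planted])

        def near(rs):
            df = rs.reads
            return int(((df["chrom"] == chrom) & (df["pos5"] - tss).abs().le(500)).sum())

        background = 0.02 * 1000  # expected background reads in the +-500 window
        ratio = (near(mut) - background) / (near(wt) - background)
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_seeded_determinism_and_stream_independence(self, toy_genome, toy_annotation):
        truth = SyntheticTruth(params={"seed": 8})
        params = ChipSimParams(seed=8, depth=10_000)
        a = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "wild_type", "IP", 1
        )
        b = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "wild_type", "IP", 1
        )
        c = synth.simulate_chip_library(
            toy_annotation, truth, params, toy_genome, "wild_type", "IP", 2
        )
        assert a.reads.equals(b.reads)
        assert not a.reads.equals(c.reads)

    def test_unknown_genotype_or_role_rejected(self, toy_genome, toy_annotation):
        truth = SyntheticTruth(params={"seed": 9})
        params = ChipSimParams(seed=9)
        with pytest.raises(ValueError):
            synth.simulate_chip_library(
                toy_annotation, truth, params, toy_genome, "het", "IP", 1
            )
        with pytest.raises(ValueError):
            synth.simulate_chip_library(
                toy_annotation, truth, params, toy_genome, "mutant", "IGG", 1
            )


class TestSmallRNA:
    def test_frac_valid_one_all_pass_filter(self, toy_genome, toy_annotation):
        truth = SyntheticTruth(params={"seed": 10})
        reads, per_gene = synth.simulate_smallrna_fastq(
            toy_genome, toy_annotation, truth, n_reads=500, frac_valid=1.0, seed=10
        )
        kept, report = filter_22g(reads)
        assert len(kept) == 500
        assert per_gene.sum() == 500

    def test_frac_valid_zero_all_fail(self, toy_genome, toy_annotation):
        truth = SyntheticTruth(params={"seed": 10})
        reads, per_gene = synth.simulate_smallrna_fastq(
            toy_genome, toy_annotation, truth, n_reads=500, frac_valid=0.0, seed=10
        )
        kept, _ = filter_22g(reads)
        assert kept == []
        assert per_gene.sum() == 0

    def test_bookkeeping_exact_and_binomial(self, toy_genome, toy_annotation):
        truth = SyntheticTruth(params={"seed": 12})
        n = 10_000
        reads, per_gene = synth.simulate_smallrna_fastq(
            toy_genome, toy_annotation, truth, n_reads=n, frac_valid=0.6, seed=12
        )
        kept, _ = filter_22g(reads)
        assert len(kept) == per_gene.sum()  # exact bookkeeping
        assert abs(len(kept) - 0.6 * n) < 4 * np.sqrt(n * 0.6 * 0.4)

    def test_mutant_multipliers_shift_sampling(self, toy_genome, toy_annotation):
        up = toy_annotation.gene_ids[0]
        truth = SyntheticTruth(sr_up_genes={up: 2.0}, params={"seed": 13})
        _, wt_counts = synth.simulate_smallrna_fastq(
            toy_genome, toy_annotation, truth, 20_000, 1.0, seed=13, genotype="wild_type"
        )
        _, mut_counts = synth.simulate_smallrna_fastq(
            toy_genome, toy_annotation, truth, 20_000, 1.0, seed=13, genotype="mutant"
        )
        assert mut_counts[up] > 2 * wt_counts[up]


class TestCountMatrix:
    def test_null_effect_empty_truth(self):
        matrix, truth = synth.simulate_count_matrix(100, effect_log2fc=0.0, seed=1)
        assert truth.de_genes == {}
        means = matrix.counts.to_numpy().reshape(100, 2, 4).mean(axis=2)
        # NB(100, 0.1): var of the across-feature group-mean difference is
        # ~2*1100/(4*100), sd ~2.3; allow 4 sd
        assert abs(means[:, 0].mean() - means[:, 1].mean()) < 10

    def test_zero_dispersion_is_poisson(self):
        matrix, _ = synth.simulate_count_matrix(
            2000, reps=10, base_mean=100.0, dispersion=0.0, seed=2
        )
        arr = matrix.counts.to_numpy().astype(float)
        # variance ~= mean across features for Poisson
        ratio = arr.var(axis=1, ddof=1).mean() / arr.mean(axis=1).mean()
        assert 0.9 < ratio < 1.1

    def test_seeded_determinism(self):
        a, _ = synth.simulate_count_matrix(50, seed=3)
        b, _ = synth.simulate_count_matrix(50, seed=3)
        assert a.counts.equals(b.counts)

    def test_planted_effect_recorded_and_applied(self):
        matrix, truth = synth.simulate_count_matrix(
            500, effect_log2fc=2.0, frac_affected=0.1, base_mean=100.0,
            dispersion=0.01, seed=4
        )
        assert len(truth.de_genes) == 50
        arr = matrix.counts
        affected = list(truth.de_genes)
        ratio = arr.loc[affected].iloc[:, 4:].mean().mean() / arr.loc[affected].iloc[:, :4].mean().mean()
        assert ratio == pytest.approx(4.0, rel=0.1)
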