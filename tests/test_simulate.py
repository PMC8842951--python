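import numpy as np
import pytest

from gametephase.datatypes import GT_MISSING, ConfigError
from gametephase.simulate import (SimConfig, mda_amplification_factors,
                                  read_sequences, simulate_all,
                                  simulate_cell_observations,
                                  simulate_cell_reads, simulate_diploid_genome,
                                  simulate_meiosis)


class TestDiploidGenome:
    def test_zero_snp_rate_gives_identical_haplotypes(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=5_000, snp_rate=0.0, seed=3)
        truth = simulate_diploid_genome(cfg)
        assert truth.panel.n_loci == 0
        assert np.array_equal(truth.hap_a[0], truth.hap_b[0])

    def test_snp_count_within_binomial_interval(self):
        # oracle: n ~ Binomial(100000, 0.002); 99% interval 200 +/- 2.576*sd
        # sd = sqrt(100000 * 0.002 * 0.998) = 14.13 -> [163, 237]
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, snp_rate=0.002, seed=1)
        truth = simulate_diploid_genome(cfg)
        assert 163 <= truth.panel.n_loci <= 237
        pos = truth.panel.pos
        assert np.all(np.diff(pos) > 0)

    def test_haplotypes_differ_exactly_at_snp_loci(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length=20_000, snp_rate=0.005, seed=5)
        truth = simulate_diploid_genome(cfg)
        for ci, chrom in enumerate(truth.chrom_names):
            sl = truth.panel.chrom_slice(chrom)
            diff = np.flatnonzero(truth.hap_a[ci] != truth.hap_b[ci])
            assert np.array_equal(diff, truth.panel.pos[sl])

    def test_determinism(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=30_000, snp_rate=0.002, seed=9)
        t1 = simulate_diploid_genome(cfg)
        t2 = simulate_diploid_genome(cfg)
        assert np.array_equal(t1.hap_a[0], t2.hap_a[0])
        assert np.array_equal(t1.hap_b[0], t2.hap_b[0])
        assert np.array_equal(t1.panel.pos, t2.panel.pos)

    def test_too_few_expected_snps_rejected(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=100, snp_rate=0.001)
        with pytest.raises(ConfigError):
            simulate_diploid_genome(cfg)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            simulate_diploid_genome(SimConfig(snp_rate=1.5))


class TestMeiosis:
    def test_zero_lambda_single_segment(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length=10_000, snp_rate=0.01,
                        n_cells=5, crossover_lambda=0.0, seed=2)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        assert truth.n_crossovers().sum() == 0
        for c in range(5):
            o = truth.origin_at(c, 0, np.arange(0, 10_000, 997))
            assert np.unique(o).size == 1

    def test_poisson_mean_within_3_se(self):
        # oracle: SE of the mean of 1000 Poisson(2) draws = sqrt(2/1000)
        cfg = SimConfig(n_chromosomes=4, chrom_length=50_000, snp_rate=0.01,
                        n_cells=250, crossover_lambda=2.0, seed=4)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        mean = truth.n_crossovers().mean()
        assert abs(mean - 2.0) < 3 * np.sqrt(2.0 / 1000)

    def test_alternation_at_breakpoint(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=10_000, snp_rate=0.01,
                        n_cells=50, crossover_lambda=1.0, seed=6)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        for c in range(50):
            bp = truth.cell_breaks[c][0]
            if bp.size != 1:
                continue
            p = int(bp[0])
            left = truth.origin_at(c, 0, np.array([p - 1]))[0]
            right = truth.origin_at(c, 0, np.array([p]))[0]
            assert left != right


class TestObservations:
    def test_noise_free_matrix_is_exact_projection(self, tiny_sim):
        cfg, truth, matrix, _ = tiny_sim
        for c in range(cfg.n_cells):
            expected = truth.snp_origin(c, 0)
            assert np.array_equal(matrix.data[c], expected)

    def test_missing_fraction_near_target(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=200_000, snp_rate=0.002,
                        n_cells=30, missing_rate_target=0.4, genotype_error=0.0,
                        seed=8)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        matrix = simulate_cell_observations(truth)
        rates = matrix.missing_rate()
        assert np.mean((rates >= 0.30) & (rates <= 0.50)) >= 0.9

    def test_all_a_cell_matches_hap_a(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=50_000, snp_rate=0.004,
                        n_cells=10, crossover_lambda=0.0, genotype_error=0.0,
                        missing_rate_target=0.0, seed=12)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        matrix = simulate_cell_observations(truth)
        for c in range(10):
            origin = truth.cell_start_origin[c, 0]
            assert np.all(matrix.data[c] == origin)

    def test_het_injection_counted(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=50_000, snp_rate=0.01,
                        n_cells=5, het_call_rate=0.2, genotype_error=0.0,
                        missing_rate_target=0.0, seed=13)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        matrix = simulate_cell_observations(truth)
        assert np.all(matrix.n_het_raw > 0)
        # demoted het calls appear as MISSING but keep n_called at full panel
        assert np.all(matrix.n_called == truth.panel.n_loci)
        miss = (matrix.data == GT_MISSING).sum(axis=1)
        assert np.array_equal(miss, matrix.n_het_raw)


class TestReads:
    def test_total_bases_near_expectation(self):
        # amplification bias is flattened (large shape) so the expectation
        # oracle total = mean_depth * chrom_length applies directly
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000, snp_rate=0.002,
                        n_cells=1, mean_depth=20.0, read_length=100,
                        mda_gamma_shape=200.0, seed=14)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        reads = simulate_cell_reads(truth)
        total = int((reads.end - reads.start).sum())
        assert abs(total - 2_000_000) <= 200_000

    def test_read_fully_inside_segment_has_that_origin(self, tiny_sim):
        cfg, truth, _, reads = tiny_sim
        for i in range(0, reads.n_reads, 97):
            c, ch = int(reads.cell_idx[i]), int(reads.chrom_idx[i])
            span_origins = truth.origin_at(
                c, ch, np.arange(reads.start[i], reads.end[i]))
            if np.unique(span_origins).size == 1:
                assert reads.origin[i] == span_origins[0]

    def test_bias_off_reduces_depth_cv(self):
        base = dict(n_chromosomes=1, chrom_length=100_000, snp_rate=0.002,
                    n_cells=1, mean_depth=10.0, seed=15)
        cv = {}
        for label, shape in (("flat", 1e6), ("biased", 0.5)):
            cfg = SimConfig(mda_gamma_shape=shape, **base)
            truth = simulate_meiosis(simulate_diploid_genome(cfg))
            reads = simulate_cell_reads(truth)
            depth = np.zeros(10)
            np.add.at(depth, reads.start // 10_000, 1.0)
            cv[label] = depth.std() / depth.mean()
        assert cv["flat"] < cv["biased"]

    def test_placements_within_chromosome(self, tiny_sim):
        cfg, truth, _, reads = tiny_sim
        assert np.all(reads.start >= 0)
        assert np.all(reads.end <= cfg.chrom_length)

    def test_read_length_exceeding_chromosome_rejected(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000, snp_rate=0.01,
                        read_length=2_000, seed=1)
        truth = simulate_meiosis(simulate_diploid_genome(cfg))
        with pytest.raises(ConfigError):
            simulate_cell_reads(truth)

    def test_read_sequences_match_haplotypes(self, tiny_sim):
        cfg, truth, _, reads = tiny_sim
        seqs = read_sequences(truth, reads)
        bases = np.array(list("ACGT"))
        for i in (0, reads.n_reads // 2, reads.n_reads - 1):
            c, ch = int(reads.cell_idx[i]), int(reads.chrom_idx[i])
            gam = truth.gamete_codes(c, ch)
            expected = "".join(bases[gam[reads.start[i]:reads.end[i]]])
            assert seqs[i] == expected


class TestDeterminismAndConservation:
    def test_full_rerun_identical(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=40_000, snp_rate=0.003,
                        n_cells=4, mean_depth=2.0, seed=21)
        t1, m1, r1 = simulate_all(cfg)
        t2, m2, r2 = simulate_all(cfg)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(r1.start, r2.start)
        assert np.array_equal(r1.origin, r2.origin)

    def test_mda_factors_shared_between_stages(self):
        cfg = SimConfig(seed=5)
        f1 = mda_amplification_factors(cfg)
        f2 = mda_amplification_factors(cfg)
        assert np.array_equal(f1, f2)
        assert f1.shape == (cfg.n_cells, cfg.n_chromosomes, cfg.n_windows())
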