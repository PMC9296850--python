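"""k-mer tables, depth estimation, soft capping, windows, enrichment."""

import numpy as np
import pytest
from scipy import stats

from conftest import random_dna
from plastidqc.coverage import (
    CapLevel,
    CoverageProfile,
    EnrichmentResult,
    ReadPair,
    build_kmer_table,
    estimate_pair_depth,
    flag_low_windows,
    snp_low_coverage_enrichment,
    soft_cap,
    windowed_coverage,
)
from plastidqc.errors import InputError, ParameterError
from plastidqc.simulate import simulate_reads
from plastidqc.structure import CircularSequence
from plastidqc._seqnum import revcomp


def pair(m1, m2="ACGTACGTACGTACGTACGT"):
    return ReadPair("p", m1, m2)


class TestKmerTable:
    def test_short_read_counts_expected_kmers(self):
        table = build_kmer_table([pair("ACGTACGT", "ACGTACGT")], k=5)
        # each mate yields 4 windows of length 5
        assert int(table.counts.sum()) == 8

    def test_duplicated_read_doubles_counts(self):
        p = pair("ACGTTGCAACGTTGCA", "TTTTCCCCGGGGAAAA")
        t1 = build_kmer_table([p], k=5)
        t2 = build_kmer_table([p, p], k=5)
        assert np.array_equal(t1.codes, t2.codes)
        assert np.array_equal(t1.counts * 2, t2.counts)

    def test_reverse_complement_collapses(self):
        s = "ACGTTGCAACGTTGCAAC"
        t1 = build_kmer_table([pair(s, s)], k=5)
        t2 = build_kmer_table([pair(revcomp(s), revcomp(s))], k=5)
        assert np.array_equal(t1.codes, t2.codes)
        assert np.array_equal(t1.counts, t2.counts)

    def test_k_domain(self):
        with pytest.raises(ParameterError):
            build_kmer_table([], k=16)
        with pytest.raises(ParameterError):
            build_kmer_table([], k=33)

    def test_read_with_n_skips_those_windows(self):
        table = build_kmer_table([pair("ACGTNACGTA", "ACGTNACGTA")], k=5)
        # only windows fully inside the N-free halves survive: positions
        # 5..9 give one 5-mer per mate
        assert int(table.counts.sum()) == 2


class TestEstimatePairDepth:
    def test_unique_junk_pair_estimates_bottom_of_scale(self, rng):
        # every k-mer occurs once -> median count 1, corrected by the
        # read-length factor L/(L-k+1); far below any realistic cap, so
        # junk pairs are always retained
        p = ReadPair("j", random_dna(rng, 60), random_dna(rng, 60))
        table = build_kmer_table([p], k=31)
        assert estimate_pair_depth(p, table) == pytest.approx(60 / 30)

    def test_both_mates_shorter_than_k(self):
        p = ReadPair("s", "ACGTACGT", "ACGTACGT")
        table = build_kmer_table([p], k=31)
        assert estimate_pair_depth(p, table) == 0.0

    def test_simulated_100x_estimates_within_binomial_bounds(self, rng):
        genome = CircularSequence(random_dna(rng, 5_000))
        profile = CoverageProfile(np.full(5_000, 100.0))
        pairs = simulate_reads(genome, profile, seed=11)
        table = build_kmer_table(pairs, 31)
        estimates = [estimate_pair_depth(p, table) for p in pairs[:200]]
        assert 80 <= np.median(estimates) <= 120


class TestSoftCap:
    def test_all_pairs_below_target_retained(self, rng):
        genome = CircularSequence(random_dna(rng, 3_000))
        profile = CoverageProfile(np.full(3_000, 50.0))
        pairs = simulate_reads(genome, profile, seed=5)
        kept = soft_cap(pairs, CapLevel(500), seed=1)
        assert kept == pairs

    def test_deterministic_given_seed(self, rng):
        genome = CircularSequence(random_dna(rng, 3_000))
        profile = CoverageProfile(np.full(3_000, 400.0))
        pairs = simulate_reads(genome, profile, seed=5)
        k1 = soft_cap(pairs, CapLevel(100), seed=9)
        k2 = soft_cap(pairs, CapLevel(100), seed=9)
        assert [p.id for p in k1] == [p.id for p in k2]

    def test_order_preserved_and_one_tailed(self, rng):
        genome = CircularSequence(random_dna(rng, 3_000))
        profile = CoverageProfile(np.full(3_000, 400.0))
        pairs = simulate_reads(genome, profile, seed=5)
        kept = soft_cap(pairs, CapLevel(200), seed=9)
        ids = [p.id for p in pairs]
        kept_ids = [p.id for p in kept]
        assert kept_ids == [i for i in ids if i in set(kept_ids)]

    def test_retained_fraction_matches_binomial_expectation(self, rng):
        genome = CircularSequence(random_dna(rng, 4_000))
        profile = CoverageProfile(np.full(4_000, 800.0))
        pairs = simulate_reads(genome, profile, seed=7)
        target = 400
        kept = soft_cap(pairs, CapLevel(target), seed=3)
        n = len(pairs)
        frac = len(kept) / n
        sd = np.sqrt(0.25 / n)
        assert 0.5 - 4 * sd <= frac <= 0.5 + 4 * sd

    def test_empty_input(self):
        assert soft_cap([], CapLevel(100), seed=0) == []


class TestWindowedCoverage:
    def test_constant_profile(self):
        prof = CoverageProfile(np.full(1_000, 10.0))
        assert np.allclose(windowed_coverage(prof, 250), 10.0)

    def test_stepwise_arithmetic(self):
        prof = CoverageProfile(np.arange(500, dtype=float))
        wd = windowed_coverage(prof, 250)
        assert np.allclose(wd, [np.mean(np.arange(250)), np.mean(np.arange(250, 500))])

    def test_window_equal_to_genome(self):
        prof = CoverageProfile(np.arange(700, dtype=float))
        wd = windowed_coverage(prof, 700)
        assert len(wd) == 1
        assert wd[0] == pytest.approx(prof.genome_wide_depth)

    def test_partial_final_window_averaged_over_actual_length(self):
        prof = CoverageProfile(np.concatenate([np.full(250, 4.0), np.full(100, 8.0)]))
        wd = windowed_coverage(prof, 250)
        assert np.allclose(wd, [4.0, 8.0])


class TestFlagLowWindows:
    def test_uniform_profile_no_flags(self):
        flags = flag_low_windows(np.full(10, 100.0), 100.0)
        assert not flags.any()

    def test_worked_depth_example_both_windows_flagged(self):
        flags = flag_low_windows(np.array([1_200.0, 2_300.0]), 8_410.0)
        assert flags.tolist() == [True, True]

    def test_exact_half_is_flagged_inclusive(self):
        flags = flag_low_windows(np.array([50.0, 50.01]), 100.0)
        assert flags.tolist() == [True, False]


class TestEnrichment:
    def test_snps_concentrated_in_small_flagged_area_significant(self):
        flags = np.zeros(100, dtype=bool)
        flags[:10] = True  # 10% of the genome
        snps = list(np.arange(20) * 50)  # 20 SNPs, all in the first 10 windows
        res = snp_low_coverage_enrichment(snps, flags, window=100, n_perm=999, seed=1)
        assert res.observed_fraction == 1.0
        assert res.p_value <= 0.01

    def test_empty_flags_give_p_one(self):
        flags = np.zeros(50, dtype=bool)
        res = snp_low_coverage_enrichment([10, 500], flags, window=100, n_perm=999, seed=1)
        assert res.observed_fraction == 0.0
        assert res.p_value == 1.0

    def test_zero_snps_not_applicable(self):
        res = snp_low_coverage_enrichment([], np.zeros(10, dtype=bool), 100)
        assert not res.applicable and res.p_value is None

    def test_null_calibration_p_values_roughly_uniform(self):
        rng = np.random.default_rng(42)
        flags = np.zeros(80, dtype=bool)
        flags[rng.choice(80, 20, replace=False)] = True
        pvals = []
        for rep in range(60):
            snps = rng.integers(0, 8_000, size=15)
            res = snp_low_coverage_enrichment(
                snps, flags, window=100, n_perm=999, seed=int(rng.integers(1 << 30))
            )
            pvals.append(res.p_value)
        # conservative-valid permutation p-values: uniform-ish, never
        # anti-conservative in aggregate
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_n_perm_domain(self):
        with pytest.raises(ParameterError):
            snp_low_coverage_enrichment([1], np.zeros(10, dtype=bool), 100, n_perm=10)


class TestReadPairValidation:
    def test_empty_mate_rejected(self):
        with pytest.raises(InputError):
            ReadPair("x", "", "ACGT")

    def test_quality_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ReadPair("x", "ACGT", "ACGT", qual1="II")
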