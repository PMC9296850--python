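"""The synthetic-data generator: determinism, truth records, reads."""

import numpy as np
import pytest

from conftest import SMALL_SPEC, random_dna
from plastidqc.coverage import CoverageProfile, flag_low_windows, windowed_coverage
from plastidqc.errors import ParameterError
from plastidqc.simulate import (
    DEFECT_MODES,
    DefectSpec,
    PlastomeSpec,
    generate_plastome,
    mutate_individual,
    simulate_assembler_output,
    simulate_reads,
)
from plastidqc.structure import detect_inverted_repeat


class TestGeneratePlastome:
    def test_total_length_is_sum_of_regions(self, small_plastome):
        spec = small_plastome.spec
        assert len(small_plastome.genome) == spec.lsc_len + spec.ssc_len + 2 * spec.ir_len

    def test_ir_detection_recovers_planted_arm_exactly(self, small_plastome, small_partition):
        assert small_partition.ir_length == small_plastome.spec.ir_len
        assert small_partition.region_lengths == small_plastome.truth["region_lengths"]

    def test_deterministic_per_seed(self):
        a = generate_plastome(SMALL_SPEC)
        b = generate_plastome(SMALL_SPEC)
        assert a.genome.residues == b.genome.residues
        assert [g.name for g in a.genes] == [g.name for g in b.genes]

    def test_different_seed_different_genome(self):
        other = generate_plastome(PlastomeSpec(
            lsc_len=30_000, ssc_len=6_000, ir_len=9_000, n_genes=40, seed=2
        ))
        assert other.genome.residues != generate_plastome(SMALL_SPEC).genome.residues

    def test_contains_an_intron_gene(self, small_plastome):
        assert any(len(g.spans) == 2 for g in small_plastome.genes)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            PlastomeSpec(lsc_len=5_000, ssc_len=6_000, ir_len=9_000)
        with pytest.raises(ParameterError):
            PlastomeSpec(ir_len=500)


class TestMutateIndividual:
    def test_zero_events_identity(self, small_plastome):
        out, events = mutate_individual(small_plastome, 0, 0, seed=3)
        assert out.residues == small_plastome.genome.residues
        assert events == []

    def test_event_counts_and_reproducibility(self, small_plastome):
        out1, ev1 = mutate_individual(small_plastome, 2, 1, seed=9)
        out2, ev2 = mutate_individual(small_plastome, 2, 1, seed=9)
        assert out1.residues == out2.residues
        assert ev1 == ev2
        assert sum(e["type"] == "substitution" for e in ev1) == 2
        assert sum(e["type"] in ("insertion", "deletion") for e in ev1) == 1

    def test_parameter_recovery_via_alignment(self, small_plastome):
        from plastidqc.compare import count_differences, pairwise_align

        out, _ = mutate_individual(small_plastome, 2, 1, seed=9)
        rec = count_differences(pairwise_align(small_plastome.genome, out))
        assert rec.snp_count == 2
        assert rec.indel_event_count == 1
        assert rec.total_diff_count == 3


class TestSimulateAssemblerOutput:
    def test_every_mode_produces_truth(self, small_plastome):
        for mode in DEFECT_MODES:
            asm, truth = simulate_assembler_output(
                small_plastome, [DefectSpec(mode, seed=5)]
            )
            assert truth["modes"] == [mode]
            assert len(asm.contigs) == truth["n_contigs"]

    def test_junction_split_breakpoint_at_irb_ssc_junction(self, small_plastome):
        asm, truth = simulate_assembler_output(
            small_plastome, [DefectSpec("junction_split")]
        )
        assert len(asm.contigs) == 2
        p = small_plastome.partition
        assert truth["breakpoints"] == [p.irb.end]
        assert len(asm.contigs[0]) == p.irb.end

    def test_spurious_insertion_length_in_documented_range(self, small_plastome):
        for seed in range(5):
            _, truth = simulate_assembler_output(
                small_plastome, [DefectSpec("spurious_insertion", seed=seed)]
            )
            assert 170 <= truth["insertion_length"] <= 334

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            DefectSpec("shredder")

    def test_polyN_span_recorded_and_found(self, small_plastome):
        from plastidqc.postprocess import find_polyN

        asm, truth = simulate_assembler_output(
            small_plastome, [DefectSpec("polyN_insertion", {"run_length": 25})]
        )
        spans = find_polyN(asm.contigs[0].residues, min_run=5)
        assert spans == [tuple(truth["polyN_spans"][0])]


class TestSimulateReads:
    def test_uniform_profile_realized_depth_within_5_percent(self, rng):
        from plastidqc.structure import CircularSequence

        genome = CircularSequence(random_dna(rng, 5_000))
        profile = CoverageProfile(np.full(5_000, 100.0))
        pairs, truth = simulate_reads(genome, profile, seed=8, return_truth=True)
        realized = len(pairs) * 2 * truth["read_len"] / len(genome)
        assert abs(realized - 100) / 100 <= 0.05
        # reads really come from the genome
        doubled = genome.residues * 2
        assert all(p.mate1 in doubled for p in pairs[:50])

    def test_deterministic_per_seed(self, rng):
        from plastidqc.structure import CircularSequence

        genome = CircularSequence(random_dna(rng, 2_000))
        profile = CoverageProfile(np.full(2_000, 50.0))
        a = simulate_reads(genome, profile, seed=4)
        b = simulate_reads(genome, profile, seed=4)
        assert [(p.mate1, p.mate2) for p in a] == [(p.mate1, p.mate2) for p in b]

    def test_planted_dip_profile_flagged_exactly(self):
        """A profile with a single 250 bp window dipping to 30% of the
        mean flags exactly that window."""
        L = 5_000
        depth = np.full(L, 400.0)
        depth[2_000:2_250] = 120.0  # 30% of mean
        profile = CoverageProfile(depth)
        wd = windowed_coverage(profile, 250)
        flags = flag_low_windows(wd, profile.genome_wide_depth)
        assert flags[8]
        assert flags.sum() == 1

    def test_dip_depresses_realized_coverage_locally(self, rng):
        """Reads sampled under a dipped profile leave the dip region with
        measurably lower mapped depth (fragment-length smoothing keeps the
        realized dip shallower than the profile's)."""
        from plastidqc.structure import CircularSequence

        L = 5_000
        genome = CircularSequence(random_dna(rng, L))
        depth = np.full(L, 400.0)
        depth[1_900:2_350] = 40.0
        pairs, truth = simulate_reads(
            genome, CoverageProfile(depth), seed=6, return_truth=True
        )
        realized = np.zeros(L)
        rl = truth["read_len"]
        for s, ins in zip(truth["starts"], truth["inserts"]):
            realized[np.arange(s, s + rl) % L] += 1
            realized[np.arange(s + ins - rl, s + ins) % L] += 1
        dip_mean = realized[2_050:2_200].mean()
        flank_mean = np.concatenate([realized[:1_500], realized[2_800:]]).mean()
        assert dip_mean < 0.5 * flank_mean

    def test_error_rate_produces_substitutions_only(self, rng):
        from plastidqc.structure import CircularSequence

        genome = CircularSequence(random_dna(rng, 2_000))
        profile = CoverageProfile(np.full(2_000, 30.0))
        pairs = simulate_reads(genome, profile, error_rate=0.05, seed=2)
        doubled = genome.residues * 2
        mismatched = sum(p.mate1 not in doubled for p in pairs)
        assert mismatched > 0
        assert all(len(p.mate1) == 150 for p in pairs)
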