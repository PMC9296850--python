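"""Region extraction, indel/inversion coding, supermatrix export."""

import itertools

import numpy as np
import pytest

from plastidqc._seqnum import revcomp
from plastidqc.annotate import GeneAnnotation
from plastidqc.errors import ParameterError
from plastidqc.phylo import (
    code_inversions,
    concatenate_partitions,
    extract_regions,
    mask_hotspots,
    simple_indel_coding,
)
from plastidqc.structure import CircularSequence


def sic_oracle(alignment):
    """Independent, literal-minded application of the simple indel coding
    rules, used as the ground truth for the set-based implementation.

    Rules applied per taxon and character, with explicit loops:
    a character is any internal (non-terminal) maximal gap run observed in
    any taxon; a taxon is 1 if it shows exactly that run, ? if one of its
    own gap runs (or a terminal gap) strictly contains the character span,
    else 0.
    """
    taxa = list(alignment)
    ncol = len(alignment[taxa[0]])

    def runs_of(taxon):
        row = alignment[taxon]
        out = []
        start = None
        for i in range(ncol + 1):
            gap = i < ncol and row[i] == "-"
            if gap and start is None:
                start = i
            elif not gap and start is not None:
                out.append((start, i))
                start = None
        return out

    def is_terminal(taxon, run):
        row = alignment[taxon]
        s, e = run
        return all(c == "-" for c in row[:s]) and s == 0 or (
            all(c == "-" for c in row[e:]) and e == ncol
        )

    chars = []
    for taxon in taxa:
        for run in runs_of(taxon):
            if not is_terminal(taxon, run) and run not in chars:
                chars.append(run)
    chars.sort()
    states = {}
    for taxon in taxa:
        symbols = ""
        own = runs_of(taxon)
        for char in chars:
            s, e = char
            symbol = "0"
            for run in own:
                rs, re_ = run
                if run == char and not is_terminal(taxon, run):
                    symbol = "1"
                    break
                if rs <= s and e <= re_ and run != char:
                    symbol = "?"
                    break
            symbols += symbol
        states[taxon] = symbols
    return chars, states


@pytest.fixture(scope="module")
def toy_annotated_genome():
    rng = np.random.default_rng(21)

    def dna(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    # layout: spacer geneA spacer geneB(2-span) spacer geneC spacer(wraps)
    pieces = {
        "s0": dna(50),
        "geneA": "ATG" + "AAA" * 20 + "TAA",
        "s1": dna(40),
        "exon1": "ATG" + "CCA" * 10,
        "intron": dna(90),
        "exon2": "GGA" * 10 + "TAA",
        "s2": dna(30),
        "geneC": "ATG" + "GAA" * 15 + "TAA",
        "s3": dna(60),
    }
    seq = "".join(pieces.values())
    pos = {}
    cursor = 0
    for name, part in pieces.items():
        pos[name] = (cursor, cursor + len(part))
        cursor += len(part)
    genes = [
        GeneAnnotation("geneA", (pos["geneA"],), "+", "CDS"),
        GeneAnnotation("geneB", (pos["exon1"], pos["exon2"]), "+", "CDS"),
        GeneAnnotation("geneC", (pos["geneC"],), "+", "CDS"),
    ]
    return CircularSequence(seq), genes


class TestExtractRegions:
    def test_toy_genome_counts_and_wraparound_spacer(self, toy_annotated_genome):
        genome, genes = toy_annotated_genome
        regions = extract_regions(genome, genes)
        assert regions.counts == (3, 1, 3)
        assert "geneB_intron1" in regions.introns
        assert "geneC_geneA" in regions.spacers  # crosses the origin

    def test_abutting_genes_skip_zero_length_spacer(self):
        genome = CircularSequence("ATGAAATAAATGCCCTAAACGTACGTAGGG")
        genes = [
            GeneAnnotation("g1", ((0, 9),), "+", "CDS"),
            GeneAnnotation("g2", ((9, 18),), "+", "CDS"),
        ]
        regions = extract_regions(genome, genes)
        assert "g1_g2" not in regions.spacers
        assert "g2_g1" in regions.spacers

    def test_unannotated_genome_warns_and_is_empty(self, rng):
        genome = CircularSequence("".join(rng.choice(list("ACGT"), 200)))
        with pytest.warns(UserWarning):
            regions = extract_regions(genome, [])
        assert regions.counts == (0, 0, 0)


class TestMaskHotspots:
    def test_empty_mask_identity(self):
        aln = {"a": "ACGT", "b": "ACCT"}
        assert mask_hotspots(aln, []) == aln

    def test_full_mask_empties_alignment(self):
        aln = {"a": "ACGT", "b": "ACCT"}
        out = mask_hotspots(aln, [(0, 4)])
        assert all(v == "" for v in out.values())

    def test_mask_shortens_by_span_sizes(self):
        aln = {"a": "ACGTACGT", "b": "ACCTACCT"}
        out = mask_hotspots(aln, [(1, 3), (6, 7)])
        assert all(len(v) == 5 for v in out.values())

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            mask_hotspots({"a": "ACGT"}, [(2, 9)])


class TestSimpleIndelCoding:
    def test_single_shared_gap(self):
        aln = {"t1": "AC--GT", "t2": "ACTTGT", "t3": "AC--GT"}
        m = simple_indel_coding(aln)
        assert m.characters == [(2, 4)]
        assert m.states == {"t1": "1", "t2": "0", "t3": "1"}

    def test_nested_gaps_subsumption_scores_inapplicable(self):
        aln = {"t1": "A----T", "t2": "A--CCT", "t3": "AAACCT"}
        m = simple_indel_coding(aln)
        assert m.characters == [(1, 3), (1, 5)]
        # t1's gap (1,5) subsumes char (1,3) -> ?; t2 has residues over
        # part of (1,5) -> 0
        assert m.states["t1"] == "?1"
        assert m.states["t2"] == "10"
        assert m.states["t3"] == "00"

    def test_gapless_alignment_zero_characters(self):
        aln = {"t1": "ACGT", "t2": "ACGT"}
        m = simple_indel_coding(aln)
        assert m.characters == []

    def test_terminal_gaps_not_coded(self):
        aln = {"t1": "--CGT", "t2": "AACGT"}
        m = simple_indel_coding(aln)
        assert m.characters == []

    def test_terminal_gap_makes_overlapping_character_inapplicable(self):
        aln = {"t1": "---CGTT", "t2": "AA-CGTT", "t3": "AACCGTT"}
        m = simple_indel_coding(aln)
        assert m.characters == [(2, 3)]
        assert m.states["t1"] == "?"
        assert m.states["t2"] == "1"
        assert m.states["t3"] == "0"

    @pytest.mark.parametrize("n_taxa,ncol", [(2, 5), (3, 4)])
    def test_exhaustive_agreement_with_oracle(self, n_taxa, ncol):
        """Set-based implementation matches the literal rule application on
        every gap pattern of small alignments over {A, -}."""
        rows = ["".join(bits) for bits in itertools.product("A-", repeat=ncol)]
        checked = 0
        for combo in itertools.product(rows, repeat=n_taxa):
            aln = {f"t{i}": row for i, row in enumerate(combo)}
            expected_chars, expected_states = sic_oracle(aln)
            m = simple_indel_coding(aln)
            assert m.characters == expected_chars, aln
            assert m.states == expected_states, aln
            checked += 1
        assert checked == len(rows) ** n_taxa

    def test_random_larger_patterns_agree_with_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            aln = {
                f"t{i}": "".join(rng.choice(["A", "-"], size=8)) for i in range(4)
            }
            expected = sic_oracle(aln)
            m = simple_indel_coding(aln)
            assert (m.characters, m.states) == expected, aln


class TestCodeInversions:
    def test_no_inversions_identity(self):
        aln = {"t1": "ACGTAC", "t2": "ACCTAC"}
        matrix, out = code_inversions(aln, {})
        assert out == aln
        assert matrix.characters == []

    def test_planted_inversion_recovered(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=40))
        span = (10, 22)
        taxa = {}
        truth = {}
        for i in range(5):
            row = base
            if i < 2:  # carriers show the reverse-complemented segment
                row = row[: span[0]] + revcomp(row[span[0]:span[1]]) + row[span[1]:]
            taxa[f"t{i}"] = row
            truth[f"t{i}"] = base
        matrix, corrected = code_inversions(
            taxa, {"t0": [span], "t1": [span]}
        )
        assert matrix.characters == [span]
        assert matrix.states == {"t0": "1", "t1": "1", "t2": "0", "t3": "0", "t4": "0"}
        assert corrected == truth

    def test_span_outside_alignment_rejected(self):
        with pytest.raises(ParameterError):
            code_inversions({"t1": "ACGT"}, {"t1": [(0, 9)]})

    def test_double_application_is_identity(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=30))
        span = (5, 15)
        aln = {"t1": base, "t2": base}
        _, once = code_inversions(aln, {"t1": [span]})
        _, twice = code_inversions(once, {"t1": [span]})
        assert twice == aln


class TestConcatenatePartitions:
    def test_lengths_and_offsets(self):
        alignments = {
            "rbcL": {"t1": "ACGT", "t2": "ACCT"},
            "matK": {"t1": "GG", "t2": "GA"},
        }
        aln_with_gap = {"t1": "AC--GT", "t2": "ACTTGT"}
        indels = simple_indel_coding(aln_with_gap)
        sm = concatenate_partitions(alignments, indels)
        assert sm.length == 4 + 2 + 1
        names = [p[0] for p in sm.partitions]
        assert names == ["matK", "rbcL", "indels"]  # name-sorted + binary last
        offsets = [(p[1], p[2]) for p in sm.partitions]
        assert offsets == [(0, 2), (2, 6), (6, 7)]

    def test_order_invariance(self):
        a = {"r1": {"t": "AAAA"}, "r2": {"t": "CC"}}
        b = {"r2": {"t": "CC"}, "r1": {"t": "AAAA"}}
        assert concatenate_partitions(a).matrix == concatenate_partitions(b).matrix

    def test_missing_taxon_filled(self):
        alignments = {
            "r1": {"t1": "ACGT", "t2": "ACCT"},
            "r2": {"t1": "GG"},
        }
        sm = concatenate_partitions(alignments)
        assert sm.matrix["t2"].endswith("??")

    def test_phylip_round_trip(self, tmp_path):
        from Bio import AlignIO

        sm = concatenate_partitions({"r": {"tax1": "ACGTAC", "tax2": "AC-TAC"}})
        path = tmp_path / "matrix.phy"
        sm.write_phylip(path)
        back = AlignIO.read(str(path), "phylip-relaxed")
        rows = {rec.id: str(rec.seq) for rec in back}
        assert rows == sm.matrix

    def test_nexus_and_partition_files_written(self, tmp_path):
        aln_with_gap = {"t1": "AC--GT", "t2": "ACTTGT"}
        sm = concatenate_partitions(
            {"r": aln_with_gap}, simple_indel_coding(aln_with_gap)
        )
        nexus = tmp_path / "matrix.nex"
        parts = tmp_path / "parts.txt"
        sm.write_nexus(nexus)
        sm.write_raxml_partitions(parts)
        text = nexus.read_text()
        assert "BEGIN DATA;" in text and "MATRIX" in text
        lines = parts.read_text().splitlines()
        assert lines[0].startswith("DNA, r = 1-6")
        assert lines[1].startswith("BIN, indels = 7-7")
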