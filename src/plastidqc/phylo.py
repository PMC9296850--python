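"""Phylogenetic matrix preparation: region extraction, hotspot masking,
simple indel coding, inversion coding, and partitioned supermatrix export.

Alignments are plain mappings ``{taxon: aligned row}`` with ``-`` for
gaps.  Indels are converted into binary characters under simple indel
coding: every distinct internal gap (identical 5' and 3' bounds) is one
presence/absence character; a taxon whose own gap strictly subsumes a
character's span is scored inapplicable (?).  Terminal gaps are treated
as missing data, not as events.  Tree search itself is external; this
module only produces the input matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._seqnum import revcomp
from .annotate import GeneAnnotation, spliced_cds
from .errors import InputError, ParameterError
from .structure import CircularSequence

__all__ = [
    "RegionSet",
    "IndelCharacterMatrix",
    "extract_regions",
    "mask_hotspots",
    "simple_indel_coding",
    "code_inversions",
    "concatenate_partitions",
    "Supermatrix",
]

Alignment = Dict[str, str]


@dataclass
class RegionSet:
    """Named coding regions, introns, and intergenic spacers of one
    annotated genome."""

    coding: Dict[str, str] = field(default_factory=dict)
    introns: Dict[str, str] = field(default_factory=dict)
    spacers: Dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> Tuple[int, int, int]:
        return len(self.coding), len(self.introns), len(self.spacers)


def extract_regions(
    genome: CircularSequence, genes: Sequence[GeneAnnotation]
) -> RegionSet:
    """Extract coding regions, introns, and intergenic spacers.

    Coding regions are the concatenated CDS spans per gene; introns are
    the gaps between spans of multi-span genes; spacers are the
    inter-gene intervals walking the circle, including the single
    wrap-around spacer across the origin, named ``geneA_geneB`` after
    their flanking genes.  Zero-length spacers are skipped.
    """
    regions = RegionSet()
    if not genes:
        import warnings

        warnings.warn("no annotations; returning an empty region set")
        return regions
    for gene in genes:
        if gene.feature_type == "CDS":
            regions.coding[gene.name] = spliced_cds(genome, gene)
        else:
            regions.coding.setdefault(gene.name, genome.fetch(gene.start, gene.end))
        genomic = sorted(gene.spans)
        for i, ((_, e1), (s2, _)) in enumerate(zip(genomic, genomic[1:]), start=1):
            regions.introns[f"{gene.name}_intron{i}"] = genome.fetch(e1, s2)
    by_start = sorted(genes, key=lambda g: g.start)
    L = len(genome)
    for g1, g2 in zip(by_start, by_start[1:] + by_start[:1]):
        start = g1.end
        end = g2.start if g2.start >= g1.end else g2.start + L
        if end - start <= 0:
            continue
        regions.spacers[f"{g1.name}_{g2.name}"] = genome.fetch(start, end)
    return regions


def _check_alignment(alignment: Alignment) -> int:
    if not alignment:
        raise InputError("empty alignment")
    lengths = {len(row) for row in alignment.values()}
    if len(lengths) != 1:
        raise InputError("alignment rows differ in length")
    return lengths.pop()


def mask_hotspots(
    alignment: Alignment, mask_spans: Sequence[Tuple[int, int]]
) -> Alignment:
    """Remove user-supplied column spans (0-based half-open) from an
    alignment.  Spans come from manual inspection of unclear-homology
    areas (typically poly-A/T microsatellites)."""
    ncol = _check_alignment(alignment)
    drop = set()
    for s, e in mask_spans:
        if s < 0 or e > ncol or s > e:
            raise ParameterError(f"mask span ({s}, {e}) outside alignment")
        drop.update(range(s, e))
    keep = [i for i in range(ncol) if i not in drop]
    return {t: "".join(row[i] for i in keep) for t, row in alignment.items()}


@dataclass
class IndelCharacterMatrix:
    """Binary gap characters: spans plus one state string per taxon."""

    characters: List[Tuple[int, int]]
    states: Dict[str, str]

    def __post_init__(self):
        for t, s in self.states.items():
            if len(s) != len(self.characters):
                raise InputError(f"taxon {t}: state count mismatch")
            if set(s) - set("01?"):
                raise InputError(f"taxon {t}: invalid state symbols")
        for k in range(len(self.characters)):
            if not any(s[k] == "1" for s in self.states.values()):
                raise InputError(f"character {k}: no taxon scored present")


def _gap_runs(row: str) -> Tuple[List[Tuple[int, int]], Tuple[int, int]]:
    """Internal gap runs of one row plus the terminal-gap extents.

    Returns (internal_runs, (lead_end, trail_start)): columns before
    ``lead_end`` or at/after ``trail_start`` are terminal gap columns.
    """
    n = len(row)
    lead = 0
    while lead < n and row[lead] == "-":
        lead += 1
    trail = n
    while trail > lead and row[trail - 1] == "-":
        trail -= 1
    runs = []
    i = lead
    while i < trail:
        if row[i] == "-":
            j = i
            while j < trail and row[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs, (lead, trail)


def simple_indel_coding(alignment: Alignment) -> IndelCharacterMatrix:
    """Simple indel coding of an alignment's internal gaps.

    Each distinct internal gap span defines one binary character.  A
    taxon scores present (1) when it carries exactly that gap, absent (0)
    when it has residues somewhere across the span without a subsuming
    gap, and inapplicable (?) when its own gap (or a terminal gap)
    strictly subsumes the character span with different bounds.  Gaps
    partially overlapping a character, with neither equal nor subsuming
    bounds, score absent.
    """
    _check_alignment(alignment)
    per_taxon = {t: _gap_runs(row) for t, row in alignment.items()}
    chars = sorted({run for runs, _ in per_taxon.values() for run in runs})
    states: Dict[str, str] = {}
    for taxon, (runs, (lead, trail)) in per_taxon.items():
        run_set = set(runs)
        symbols = []
        for (s, e) in chars:
            if (s, e) in run_set:
                symbols.append("1")
            elif e <= lead or s >= trail:
                symbols.append("?")  # inside a terminal gap: missing data
            elif any(rs <= s and e <= re and (rs, re) != (s, e) for rs, re in runs):
                symbols.append("?")
            else:
                symbols.append("0")
        states[taxon] = "".join(symbols)
    return IndelCharacterMatrix(list(chars), states)


def code_inversions(
    alignment: Alignment,
    inversion_spans: Dict[str, Sequence[Tuple[int, int]]],
) -> Tuple[IndelCharacterMatrix, Alignment]:
    """Code user-identified inversions as binary characters and
    re-integrate the reverse-complemented spans into the alignment.

    ``inversion_spans`` maps each carrier taxon to its inverted column
    spans (0-based half-open, alignment coordinates).  Every distinct
    span becomes one presence/absence character; carriers' spans are
    reverse-complemented in the returned alignment so that sites align
    positionally across all taxa.
    """
    ncol = _check_alignment(alignment)
    spans = sorted({tuple(s) for lst in inversion_spans.values() for s in lst})
    for s, e in spans:
        if s < 0 or e > ncol or s >= e:
            raise ParameterError(f"inversion span ({s}, {e}) outside alignment")
    corrected = dict(alignment)
    states: Dict[str, str] = {}
    for taxon in alignment:
        carried = {tuple(s) for s in inversion_spans.get(taxon, ())}
        states[taxon] = "".join("1" if sp in carried else "0" for sp in spans)
        row = corrected[taxon]
        for s, e in carried:
            row = row[:s] + revcomp(row[s:e]) + row[e:]
        corrected[taxon] = row
    if spans:
        matrix = IndelCharacterMatrix(list(spans), states)
    else:
        matrix = IndelCharacterMatrix([], {t: "" for t in alignment})
    return matrix, corrected


@dataclass
class Supermatrix:
    """Concatenated nucleotide regions plus a binary character partition."""

    matrix: Dict[str, str]
    partitions: List[Tuple[str, int, int, str]]  # name, start, end, datatype

    @property
    def length(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0

    def write_phylip(self, path) -> None:
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        aln = MultipleSeqAlignment(
            SeqRecord(Seq(seq), id=taxon, description="")
            for taxon, seq in self.matrix.items()
        )
        AlignIO.write(aln, str(path), "phylip-relaxed")

    def write_nexus(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(
                f"  DIMENSIONS NTAX={len(self.matrix)} NCHAR={self.length};\n"
            )
            fh.write(
                "  FORMAT DATATYPE=STANDARD SYMBOLS=\"ACGTNRYSWKMBDHV01\" "
                "GAP=- MISSING=?;\n  MATRIX\n"
            )
            for taxon, seq in self.matrix.items():
                fh.write(f"    {taxon}  {seq}\n")
            fh.write("  ;\nEND;\n")

    def write_raxml_partitions(self, path) -> None:
        with open(path, "w") as fh:
            for name, start, end, datatype in self.partitions:
                model = "DNA" if datatype == "DNA" else "BIN"
                fh.write(f"{model}, {name} = {start + 1}-{end}\n")


def concatenate_partitions(
    alignments: Dict[str, Alignment],
    indel_matrix: Optional[IndelCharacterMatrix] = None,
) -> Supermatrix:
    """Concatenate region alignments (name-sorted) and append binary
    indel/inversion characters as a second partition.

    Taxa absent from a region are filled with the missing symbol ``?``.
    Empty regions are excluded.
    """
    taxa = sorted({t for aln in alignments.values() for t in aln})
    if indel_matrix is not None:
        taxa = sorted(set(taxa) | set(indel_matrix.states))
    rows = {t: [] for t in taxa}
    partitions = []
    offset = 0
    for name in sorted(alignments):
        aln = alignments[name]
        if not aln:
            continue
        ncol = _check_alignment(aln)
        if ncol == 0:
            continue
        for t in taxa:
            rows[t].append(aln.get(t, "?" * ncol))
        partitions.append((name, offset, offset + ncol, "DNA"))
        offset += ncol
    if indel_matrix is not None and indel_matrix.characters:
        ncol = len(indel_matrix.characters)
        for t in taxa:
            rows[t].append(indel_matrix.states.get(t, "?" * ncol))
        partitions.append(("indels", offset, offset + ncol, "BIN"))
        offset += ncol
    return Supermatrix({t: "".join(parts) for t, parts in rows.items()}, partitions)
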