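"""File input/output: FASTA, paired FASTQ (gzip-aware), BED, GFF3,
GenBank gene extraction, and per-base depth tables.

Coordinates are 0-based half-open internally, 1-based inclusive in
GFF3/GenBank, and 0-based half-open in BED, following each format's
convention.
"""

from __future__ import annotations

import gzip
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotate import GeneAnnotation
from .coverage import CoverageProfile, ReadPair
from .errors import InputError
from .postprocess import Contig
from .structure import CircularSequence, QuadripartitePartition

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "write_bed_partition",
    "write_bed_flags",
    "read_genbank_genes",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_depth_tsv",
]


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> List[Contig]:
    """All records of a FASTA file as contigs."""
    with _open(path) as fh:
        return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    """Write (name, sequence) records wrapped at ``width`` columns."""
    with _open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq_pairs(path1, path2) -> List[ReadPair]:
    """Read paired FASTQ files (plain or gzip) into ReadPairs."""
    pairs = []
    with _open(path1) as f1, _open(path2) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            pairs.append(ReadPair(id1.split()[0], s1, s2, q1, q2))
    return pairs


def write_fastq_pairs(path1, path2, pairs: Sequence[ReadPair]) -> None:
    with _open(path1, "wt") as f1, _open(path2, "wt") as f2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.mate1)
            q2 = p.qual2 or "I" * len(p.mate2)
            f1.write(f"@{p.id}/1\n{p.mate1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.mate2}\n+\n{q2}\n")


def write_bed_partition(path, partition: QuadripartitePartition, chrom: str = "plastome") -> None:
    """Quadripartite partition as BED (0-based half-open); wrap-around
    spans are split at the origin."""
    L = partition.genome_length
    with open(path, "w") as fh:
        for name, span in (
            ("LSC", partition.lsc), ("IRb", partition.irb),
            ("SSC", partition.ssc), ("IRa", partition.ira),
        ):
            if span.end <= L:
                fh.write(f"{chrom}\t{span.start}\t{span.end}\t{name}\n")
            else:
                fh.write(f"{chrom}\t{span.start}\t{L}\t{name}\n")
                fh.write(f"{chrom}\t0\t{span.end - L}\t{name}\n")


def write_bed_flags(path, flags, window: int, genome_length: int, chrom: str = "plastome") -> None:
    """Low-coverage window flags as BED intervals."""
    with open(path, "w") as fh:
        for i, flagged in enumerate(flags):
            if flagged:
                start = i * window
                end = min(start + window, genome_length)
                fh.write(f"{chrom}\t{start}\t{end}\tlow_coverage\n")


_GENE_FEATURES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank_genes(path) -> Tuple[CircularSequence, List[GeneAnnotation]]:
    """Genome sequence and gene annotations from a GenBank flat file."""
    record = SeqIO.read(str(path), "genbank")
    topology = record.annotations.get("topology", "circular")
    genome = CircularSequence(str(record.seq), topology)
    genes: List[GeneAnnotation] = []
    seen = set()
    for feat in record.features:
        if feat.type not in _GENE_FEATURES:
            continue
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        if name in seen:
            continue
        seen.add(name)
        strand = "-" if feat.location.strand == -1 else "+"
        spans = [(int(p.start), int(p.end)) for p in feat.location.parts]
        spans.sort(reverse=(strand == "-"))
        genes.append(GeneAnnotation(name, tuple(spans), strand, feat.type))
    return genome, genes


def read_gff3_genes(path) -> List[GeneAnnotation]:
    """Gene annotations from a GFF3 file written by this package."""
    by_gene: Dict[Tuple[str, str, str], List[Tuple[int, int]]] = {}
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] not in _GENE_FEATURES:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("Name", attrs.get("ID", "?"))
            key = (name, cols[6], cols[2])
            by_gene.setdefault(key, []).append((int(cols[3]) - 1, int(cols[4])))
    genes = []
    for (name, strand, ftype), spans in by_gene.items():
        spans.sort(reverse=(strand == "-"))
        genes.append(GeneAnnotation(name, tuple(spans), strand, ftype))
    genes.sort(key=lambda g: g.start)
    return genes


def write_gff3_genes(path, genes: Sequence[GeneAnnotation], seqid: str = "plastome") -> None:
    """Gene annotations as GFF3 (1-based inclusive coordinates)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            for s, e in sorted(gene.spans):
                fh.write(
                    f"{seqid}\tplastidqc\t{gene.feature_type}\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\tID={gene.name};Name={gene.name}\n"
                )


def read_depth_tsv(path, genome_length: Optional[int] = None) -> CoverageProfile:
    """Per-base depth from a samtools-style TSV (chrom, 1-based pos, depth).

    Positions absent from the file are zero; ``genome_length`` defaults to
    the largest position seen.
    """
    positions = []
    depths = []
    with _open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise InputError("depth TSV needs >= 3 columns")
            positions.append(int(cols[1]) - 1)
            depths.append(float(cols[2]))
    if not positions:
        raise InputError("empty depth table")
    L = genome_length or (max(positions) + 1)
    depth = np.zeros(L)
    depth[np.array(positions)] = depths
    return CoverageProfile(depth)
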