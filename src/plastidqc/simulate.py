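"""Synthetic plastomes, individuals, sequencing reads, and assembler
outputs carrying documented defect modes.

The generator emulates a circular quadripartite plastome (~162 kb by
default: LSC 87.6 kb, IRs 30.5 kb, SSC 13.4 kb) with a realistic gene
complement laid out in the conventional order (the 5' LSC gene block,
single-copy CDS and tRNA genes, an intron-containing rps16), paired
150 bp reads from ~300 bp fragments under an arbitrary per-base coverage
profile, and assemblies degraded by the failure modes observed in
practice: junction splits, compensated IR expansion, LSC duplication next
to the IR, IRa truncation, loss of the 5' LSC gene block, SNP clusters,
spurious insertions, SSC flips, rotated start points, and poly-N runs.

Every generator output is deterministic for a given seed and comes with a
machine-readable truth record; downstream recovery tests compare against
that record, never against hand-entered numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seqnum import revcomp
from .annotate import GeneAnnotation
from .coverage import CoverageProfile, ReadPair
from .errors import ParameterError
from .postprocess import Assembly, Contig, Provenance
from .structure import CircularSequence, QuadripartitePartition, Span

__all__ = [
    "PlastomeSpec",
    "DefectSpec",
    "SyntheticPlastome",
    "DEFECT_MODES",
    "generate_plastome",
    "mutate_individual",
    "simulate_assembler_output",
    "simulate_reads",
    "plant_internal_stop",
]

# conventional plastid gene order; the first 17 names form the 5' LSC
# block that degraded assemblies are known to drop wholesale
_LSC_GENES = [
    ("trnH-GUG", "tRNA"), ("psbA", "CDS"), ("trnK-UUU", "tRNA"), ("matK", "CDS"),
    ("rps16", "CDS"), ("trnQ-UUG", "tRNA"), ("psbK", "CDS"), ("psbI", "CDS"),
    ("trnS-GCU", "tRNA"), ("trnG-UCC", "tRNA"), ("trnR-UCU", "tRNA"), ("atpA", "CDS"),
    ("atpF", "CDS"), ("atpH", "CDS"), ("atpI", "CDS"), ("rps2", "CDS"),
    ("rpoC2", "CDS"), ("rpoC1", "CDS"), ("rpoB", "CDS"), ("trnC-GCA", "tRNA"),
    ("petN", "CDS"), ("psbM", "CDS"), ("trnD-GUC", "tRNA"), ("trnY-GUA", "tRNA"),
    ("trnE-UUC", "tRNA"), ("trnT-GGU", "tRNA"), ("psbD", "CDS"), ("psbC", "CDS"),
    ("trnS-UGA", "tRNA"), ("psbZ", "CDS"), ("trnG-GCC", "tRNA"), ("trnM-CAU", "tRNA"),
    ("rps14", "CDS"), ("psaB", "CDS"), ("psaA", "CDS"), ("ycf3", "CDS"),
    ("trnS-GGA", "tRNA"), ("rps4", "CDS"), ("trnT-UGU", "tRNA"), ("trnL-UAA", "tRNA"),
    ("trnF-GAA", "tRNA"), ("ndhJ", "CDS"), ("ndhK", "CDS"), ("ndhC", "CDS"),
    ("trnV-UAC", "tRNA"), ("atpE", "CDS"), ("atpB", "CDS"), ("rbcL", "CDS"),
    ("accD", "CDS"), ("psaI", "CDS"), ("ycf4", "CDS"), ("cemA", "CDS"),
    ("petA", "CDS"), ("psbJ", "CDS"), ("psbL", "CDS"), ("psbF", "CDS"),
    ("psbE", "CDS"), ("petL", "CDS"), ("petG", "CDS"), ("trnW-CCA", "tRNA"),
    ("trnP-UGG", "tRNA"), ("psaJ", "CDS"), ("rpl33", "CDS"), ("rps18", "CDS"),
    ("rpl20", "CDS"), ("clpP", "CDS"), ("psbB", "CDS"), ("psbN", "CDS"),
]
_SSC_GENES = [
    ("ndhF", "CDS"), ("rpl32", "CDS"), ("ccsA", "CDS"), ("ndhD", "CDS"),
    ("psaC", "CDS"), ("ndhE", "CDS"), ("ndhG", "CDS"), ("ndhI", "CDS"),
    ("ndhA", "CDS"), ("ndhH", "CDS"), ("rps15", "CDS"), ("ycf1", "CDS"),
]
#: gene whose CDS is split by an intron in the generated annotation
_INTRON_GENE = "rps16"

DEFECT_MODES = (
    "junction_split",
    "ir_expansion_compensated",
    "lsc_duplication_adjacent_ir",
    "ira_truncation",
    "missing_5prime_lsc_block",
    "snp_cluster_low_coverage",
    "spurious_insertion",
    "flipped_ssc",
    "rotated_start",
    "polyN_insertion",
)

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class PlastomeSpec:
    """Parameters of a synthetic quadripartite plastome."""

    lsc_len: int = 87_600
    ssc_len: int = 13_400
    ir_len: int = 30_500
    n_genes: int = 80
    gc_fraction: float = 0.37
    seed: int = 0

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ParameterError("all region lengths must be positive")
        if self.ir_len < 1000:
            raise ParameterError("ir_len must be >= 1000")
        if self.lsc_len <= self.ssc_len:
            raise ParameterError("LSC must be longer than SSC")
        if not 0 < self.gc_fraction < 1:
            raise ParameterError("gc_fraction must be in (0, 1)")

    @property
    def total_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class DefectSpec:
    """One assembler failure mode with its magnitude parameters."""

    mode: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in DEFECT_MODES:
            raise ParameterError(f"unknown defect mode {self.mode!r}")


@dataclass
class SyntheticPlastome:
    """A generated genome with its ground truth."""

    genome: CircularSequence
    partition: QuadripartitePartition
    genes: List[GeneAnnotation]
    spec: PlastomeSpec
    truth: dict


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _layout_region(rng, names, region_len, gc, min_spacer=40):
    """Place genes with random spacers inside one single-copy region.

    Returns (sequence, [(name, type, spans_relative, strand)]).  The
    first and last ``min_spacer`` bases are always spacer so the region
    junctions stay gene-free.
    """
    n = len(names)
    lengths = {}
    intron_len = {}
    for name, ftype in names:
        if ftype == "tRNA":
            lengths[name] = 72
        else:
            lengths[name] = int(rng.integers(80, 380)) * 3
        if name == _INTRON_GENE:
            intron_len[name] = int(rng.integers(250, 400))
            lengths[name] += intron_len[name]
    total_genes = sum(lengths.values())
    budget = region_len - total_genes - min_spacer * (n + 1)
    if budget < 0:
        raise ParameterError("genes do not fit the region; reduce n_genes")
    extra = rng.multinomial(budget, np.full(n + 1, 1 / (n + 1)))
    parts: List[str] = []
    placed = []
    pos = 0
    for i, (name, ftype) in enumerate(names):
        spacer = min_spacer + int(extra[i])
        parts.append(_random_seq(rng, spacer, gc))
        pos += spacer
        glen = lengths[name]
        strand = "+" if rng.random() < 0.5 else "-"
        if ftype == "CDS" and name == _INTRON_GENE:
            ilen = intron_len[name]
            cds = _random_cds(rng, (glen - ilen) // 3)
            cut = (len(cds) // 2 // 3) * 3
            exon1, exon2 = cds[:cut], cds[cut:]
            intron = _random_seq(rng, ilen, gc)
            genomic = exon1 + intron + exon2
            spans = [(pos, pos + len(exon1)), (pos + len(exon1) + ilen, pos + glen)]
        elif ftype == "CDS":
            genomic = _random_cds(rng, glen // 3)
            spans = [(pos, pos + glen)]
        else:
            genomic = _random_seq(rng, glen, gc)
            spans = [(pos, pos + glen)]
        if strand == "-":
            genomic = revcomp(genomic)
            spans = spans[::-1]
        parts.append(genomic)
        pos += glen
        placed.append((name, ftype, spans, strand))
    tail = region_len - pos
    parts.append(_random_seq(rng, tail, gc))
    return "".join(parts), placed


def _guard_junctions(seq: str) -> str:
    """Force the region's first base to A and its last base away from T so
    that exact repeat extension across region junctions is blocked."""
    first = "A"
    last = seq[-1] if seq[-1] != "T" else "C"
    return first + seq[1:-1] + last


def generate_plastome(spec: PlastomeSpec = PlastomeSpec()) -> SyntheticPlastome:
    """Generate an annotated canonical plastome with exact IRs.

    The output genome is already canonical (starts at LSC base 1, SSC in
    its lexicographically smaller orientation) and its region junctions
    are guarded so that exact inverted-repeat detection recovers the
    planted arm length exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_ssc = min(len(_SSC_GENES), max(1, round(spec.n_genes * 0.15)))
    n_lsc = spec.n_genes - n_ssc
    if n_lsc > len(_LSC_GENES):
        raise ParameterError(f"n_genes must be <= {len(_LSC_GENES) + len(_SSC_GENES)}")
    lsc_names = _LSC_GENES[:n_lsc]
    ssc_names = _SSC_GENES[:n_ssc]
    lsc, lsc_placed = _layout_region(rng, lsc_names, spec.lsc_len, spec.gc_fraction)
    ssc, ssc_placed = _layout_region(rng, ssc_names, spec.ssc_len, spec.gc_fraction)
    ir = _random_seq(rng, spec.ir_len, spec.gc_fraction)
    lsc = _guard_junctions(lsc)
    ssc = _guard_junctions(ssc)
    # canonical SSC orientation: first base A, last base not T makes the
    # forward orientation lexicographically smaller than its reverse
    # complement, so canonicalization keeps the genome as generated
    genome_str = lsc + ir + ssc + revcomp(ir)
    L = len(genome_str)
    assert L == spec.total_length
    genome = CircularSequence(genome_str, "circular")
    partition = QuadripartitePartition(
        lsc=Span(0, spec.lsc_len),
        irb=Span(spec.lsc_len, spec.lsc_len + spec.ir_len),
        ssc=Span(spec.lsc_len + spec.ir_len, spec.lsc_len + spec.ir_len + spec.ssc_len),
        ira=Span(L - spec.ir_len, L),
        ir_length=spec.ir_len,
        ir_mismatches=0,
        genome_length=L,
    )
    genes: List[GeneAnnotation] = []
    for name, ftype, spans, strand in lsc_placed:
        genes.append(GeneAnnotation(name, tuple(spans), strand, ftype))
    off = spec.lsc_len + spec.ir_len
    for name, ftype, spans, strand in ssc_placed:
        shifted = tuple((s + off, e + off) for s, e in spans)
        genes.append(GeneAnnotation(name, shifted, strand, ftype))
    truth = {
        "seed": spec.seed,
        "region_lengths": {
            "LSC": spec.lsc_len, "IRb": spec.ir_len,
            "SSC": spec.ssc_len, "IRa": spec.ir_len,
        },
        "genes": [g.name for g in genes],
        "total_length": L,
    }
    return SyntheticPlastome(genome, partition, genes, spec, truth)


def mutate_individual(
    plastome: SyntheticPlastome,
    n_subs: int,
    n_indels: int,
    seed: int = 0,
    allow_ir: bool = False,
    min_separation: int = 30,
) -> Tuple[CircularSequence, List[dict]]:
    """Plant exactly ``n_subs`` substitutions and ``n_indels`` single-base
    indels at recorded, well-separated positions.

    Positions fall in the single-copy regions unless ``allow_ir`` is set
    (an IR mutation would otherwise make the arms unequal).  Events are
    separated by at least ``min_separation`` bases and kept away from
    region junctions so that canonicalization and pairwise alignment
    recover exactly the planted counts.
    """
    if n_subs + n_indels == 0:
        return plastome.genome, []
    rng = np.random.default_rng(seed)
    p = plastome.partition
    margin = 60
    windows = [
        (p.lsc.start + margin, p.lsc.end - margin),
        (p.ssc.start + margin, p.ssc.end - margin),
    ]
    if allow_ir:
        windows.append((p.irb.start + margin, p.irb.end - margin))
    candidates = np.concatenate([np.arange(a, b) for a, b in windows])
    positions: List[int] = []
    order = rng.permutation(len(candidates))
    for idx in order:
        if len(positions) == n_subs + n_indels:
            break
        pos = int(candidates[idx])
        if all(abs(pos - q) >= min_separation for q in positions):
            positions.append(pos)
    if len(positions) < n_subs + n_indels:
        raise ParameterError("could not place all events with the requested separation")
    seq = list(plastome.genome.residues)
    events = []
    for i, pos in enumerate(sorted(positions, reverse=True)):
        if i < n_indels:
            if rng.random() < 0.5:
                base = str(rng.choice(list("ACGT")))
                seq.insert(pos, base)
                events.append({"type": "insertion", "position": pos, "base": base})
            else:
                events.append({"type": "deletion", "position": pos, "base": seq[pos]})
                del seq[pos]
        else:
            old = seq[pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            seq[pos] = new
            events.append({"type": "substitution", "position": pos, "from": old, "to": new})
    return CircularSequence("".join(seq), "circular"), events[::-1]


def plant_internal_stop(
    plastome: SyntheticPlastome, gene_name: str, seed: int = 0
) -> Tuple[CircularSequence, dict]:
    """Introduce a premature TAA stop codon into one CDS gene.

    Models the SNP-driven loss of gene functionality that marks a locally
    mis-assembled genome.  Returns the altered genome and a truth record.
    """
    gene = next(g for g in plastome.genes if g.name == gene_name)
    if gene.feature_type != "CDS":
        raise ParameterError(f"{gene_name} is not a CDS gene")
    rng = np.random.default_rng(seed)
    spans = sorted(gene.spans)
    s, e = spans[0]
    # pick an internal codon of the first exon, on the coding strand
    n_codons = (e - s) // 3
    codon_idx = int(rng.integers(2, max(3, n_codons - 2)))
    seq = list(plastome.genome.residues)
    if gene.strand == "+":
        cpos = s + 3 * codon_idx
        seq[cpos : cpos + 3] = list("TAA")
    else:
        cpos = e - 3 * codon_idx - 3
        seq[cpos : cpos + 3] = list(revcomp("TAA"))
    truth = {"gene": gene_name, "codon_index": codon_idx, "position": cpos}
    return CircularSequence("".join(seq), "circular"), truth


def _comp(b: str) -> str:
    return revcomp(b)


def simulate_assembler_output(
    plastome: SyntheticPlastome,
    defects: Sequence[DefectSpec],
    software: str = "simulated",
) -> Tuple[Assembly, dict]:
    """Apply defect modes in order and emit an Assembly plus truth record.

    The truth record states the expected pairwise differences against the
    clean genome (region length differences, substitution and indel event
    counts), the genes expected to go missing, expected poly-N spans, and
    structural outcomes (contig count, breakpoints).  Magnitudes that
    interact with exact repeat extension at region junctions (IR
    expansion, IRa truncation, 5' LSC deletion) are nudged by a base or
    two when needed so the recorded magnitude is exactly what inverted-
    repeat detection will measure.
    """
    p = plastome.partition
    lsc = plastome.genome.region(p.lsc)
    irb = plastome.genome.region(p.irb)
    ssc = plastome.genome.region(p.ssc)
    genes = list(plastome.genes)
    truth: dict = {
        "modes": [d.mode for d in defects],
        "expected": {
            "lsc_len_dif": 0, "ssc_len_dif": 0, "ir_len_dif": 0,
            "snp_count": 0, "indel_event_count": 0, "indel_bases": 0,
        },
        "missing_genes": [],
        "polyN_spans": [],
        "n_contigs": 1,
        "breakpoints": [],
        "canonical_identical": True,
    }
    exp = truth["expected"]
    split = False
    rotation = 0
    flip_ssc = False

    for defect in defects:
        rng = np.random.default_rng(defect.seed)
        params = defect.params
        mode = defect.mode
        if mode == "ir_expansion_compensated":
            m = int(params.get("magnitude", 1000))
            # block exact-repeat extension into the remaining LSC
            while lsc[-m - 1] == _comp(lsc[0]):
                m += 1
            irb = lsc[-m:] + irb
            lsc = lsc[:-m]
            exp["lsc_len_dif"] += m
            exp["ir_len_dif"] += m
            exp["indel_event_count"] += 1
            exp["indel_bases"] += m
            truth["canonical_identical"] = False
            truth.setdefault("effective_magnitude", {})[mode] = m
        elif mode == "lsc_duplication_adjacent_ir":
            d = int(params.get("magnitude", 500))
            lsc = lsc + lsc[-d:]
            exp["lsc_len_dif"] += d
            exp["indel_event_count"] += 1
            exp["indel_bases"] += d
            truth["canonical_identical"] = False
            truth.setdefault("effective_magnitude", {})[mode] = d
        elif mode == "ira_truncation":
            t = int(params.get("magnitude", 800))
            while irb[t - 1] == _comp(lsc[0]):
                t += 1
            truth["ira_truncated_by"] = t
            exp["lsc_len_dif"] += t
            exp["ir_len_dif"] += t
            exp["indel_event_count"] += 1
            exp["indel_bases"] += t
            truth["canonical_identical"] = False
            truth.setdefault("effective_magnitude", {})[mode] = t
        elif mode == "missing_5prime_lsc_block":
            n_missing = int(params.get("n_genes", 17))
            lsc_genes = [g for g in genes if g.end <= p.lsc.length]
            block = lsc_genes[:n_missing]
            cut = max(g.end for g in block) + 10
            while lsc[-1] == _comp(lsc[cut]):
                cut += 1
            removed = cut
            lsc = lsc[cut:]
            truth["missing_genes"] = [g.name for g in block]
            genes = [g for g in genes if g.name not in truth["missing_genes"]]
            exp["lsc_len_dif"] += removed
            exp["indel_event_count"] += 1
            exp["indel_bases"] += removed
            truth["canonical_identical"] = False
        elif mode == "snp_cluster_low_coverage":
            n_snps = int(params.get("n_snps", 10))
            width = int(params.get("width", 250))
            start = int(params.get("start", len(lsc) // 2))
            offsets = rng.choice(np.arange(0, width, 3), size=n_snps, replace=False)
            chars = list(lsc)
            positions = []
            for off in sorted(int(o) for o in offsets):
                pos = start + off
                old = chars[pos]
                chars[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
                positions.append(pos)
            lsc = "".join(chars)
            exp["snp_count"] += n_snps
            truth["snp_positions"] = positions
            truth["snp_window"] = (start, start + width)
            truth["canonical_identical"] = False
        elif mode == "spurious_insertion":
            length = int(rng.integers(170, 335))
            insert = _random_seq(rng, length, 0.37)
            pos = int(params.get("position", len(lsc) // 3))
            lsc = lsc[:pos] + insert + lsc[pos:]
            exp["lsc_len_dif"] += length
            exp["indel_event_count"] += 1
            exp["indel_bases"] += length
            truth["insertion_length"] = length
            truth["canonical_identical"] = False
        elif mode == "polyN_insertion":
            run = int(params.get("run_length", 30))
            pos = int(params.get("position", 2 * len(lsc) // 3))
            lsc = lsc[:pos] + "N" * run + lsc[pos:]
            exp["lsc_len_dif"] += run
            exp["indel_event_count"] += 1
            exp["indel_bases"] += run
            truth["polyN_spans"] = [(pos, pos + run)]
            truth["canonical_identical"] = False
        elif mode == "flipped_ssc":
            flip_ssc = True
        elif mode == "rotated_start":
            rotation = int(params.get("offset", rng.integers(1, p.genome_length)))
            truth["rotation"] = rotation
        elif mode == "junction_split":
            split = True
        else:  # pragma: no cover
            raise ParameterError(mode)

    ira_full = revcomp(irb)
    if truth.get("ira_truncated_by"):
        ira_full = ira_full[: len(ira_full) - truth["ira_truncated_by"]]
    ssc_out = revcomp(ssc) if flip_ssc else ssc
    genome_str = lsc + irb + ssc_out + ira_full
    provenance = Provenance(software=software)
    if split:
        c1 = Contig("contig_1", lsc + irb)
        c2 = Contig("contig_2", ssc_out + ira_full)
        truth["n_contigs"] = 2
        truth["breakpoints"] = [len(lsc) + len(irb)]
        assembly = Assembly([c1, c2], provenance)
    else:
        if rotation:
            genome_str = genome_str[rotation % len(genome_str):] + genome_str[: rotation % len(genome_str)]
        assembly = Assembly([Contig("contig_1", genome_str)], provenance)
    truth["genome_length"] = len(lsc) + len(irb) + len(ssc_out) + len(ira_full)
    return assembly, truth


def simulate_reads(
    genome: CircularSequence,
    profile: CoverageProfile,
    read_len: int = 150,
    mean_insert: int = 300,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
    return_truth: bool = False,
):
    """Paired reads whose local rate follows a per-base coverage profile.

    Fragment starts are drawn proportionally to the profile value at the
    fragment start; inserts are Normal(mean_insert, insert_sd) clipped to
    at least ``read_len``; fragments wrap around the circular origin.
    Sequencing errors are substitution-only at ``error_rate`` per base,
    with constant phred-40 qualities.  With ``return_truth`` the pair
    list comes with a record of the sampled fragment starts and insert
    sizes (indexed like the pair ids).
    """
    if len(profile) != len(genome):
        raise ParameterError("profile length must equal genome length")
    rng = np.random.default_rng(seed)
    L = len(genome)
    n_pairs = int(round(profile.depth.sum() / (2 * read_len)))
    if n_pairs == 0:
        return ([], {"starts": [], "inserts": [], "read_len": read_len}) if return_truth else []
    weights = profile.depth / profile.depth.sum()
    starts = rng.choice(L, size=n_pairs, p=weights)
    inserts = np.clip(
        np.round(rng.normal(mean_insert, insert_sd, size=n_pairs)), read_len, L
    ).astype(np.int64)
    doubled = np.frombuffer((genome.residues * 2).encode("ascii"), dtype=np.uint8)
    offs = np.arange(read_len)
    m1 = doubled[(starts[:, None] + offs)]
    ends = starts + inserts
    m2_fwd = doubled[(ends[:, None] - read_len + offs) % (2 * L)]
    if error_rate > 0:
        for mat in (m1, m2_fwd):
            mask = rng.random(mat.shape) < error_rate
            if mask.any():
                # substitute by a distinct random base
                lut = np.frombuffer(b"ACGT", dtype=np.uint8)
                repl = lut[rng.integers(0, 4, size=int(mask.sum()))]
                cur = mat[mask]
                same = repl == cur
                repl[same] = lut[(np.searchsorted(lut, repl[same]) + 1) % 4]
                mat[mask] = repl
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    m2 = comp[m2_fwd[:, ::-1]]
    qual = "I" * read_len
    pairs = []
    for i in range(n_pairs):
        pairs.append(
            ReadPair(
                id=f"frag_{i}",
                mate1=m1[i].tobytes().decode("ascii"),
                mate2=m2[i].tobytes().decode("ascii"),
                qual1=qual,
                qual2=qual,
            )
        )
    if return_truth:
        return pairs, {"starts": starts, "inserts": inserts, "read_len": read_len}
    return pairs
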