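"""Annotation transfer and CDS validity auditing.

Gene annotations are lifted from a well-annotated reference plastome onto
a new assembly by sequence similarity (default threshold 95% for both
identity and query coverage).  Transferred protein-coding genes are then
audited: reading-frame length, start codon, terminal stop, and absence of
internal stop codons.  Internal stops that reflect the underlying
nucleotide sequence are the classic symptom of a locally mis-assembled
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import pandas as pd
from Bio.Data import CodonTable

from ._seqnum import revcomp
from .errors import InputError, ParameterError
from .structure import CircularSequence

__all__ = [
    "GeneAnnotation",
    "GeneAudit",
    "TransferResult",
    "gene_sequence",
    "spliced_cds",
    "transfer_annotations",
    "validate_cds",
    "gene_report",
]

#: plastid protein-coding genes follow the bacterial/plant-plastid code
PLASTID_CODON_TABLE = 11
#: accepted initiator codons (GTG occurs in several plastid genes);
#: pass strict_start=True to validate_cds for ATG-only auditing
START_CODONS = ("ATG", "GTG")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with one or more spans (multi-span = intron-containing).

    Spans are 0-based half-open genome coordinates, ordered 5'->3' on the
    coding strand, non-overlapping.
    """

    name: str
    spans: Tuple[Tuple[int, int], ...]
    strand: str = "+"
    feature_type: str = "CDS"

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"gene {self.name}: bad strand {self.strand!r}")
        if self.feature_type not in ("CDS", "tRNA", "rRNA"):
            raise InputError(f"gene {self.name}: bad feature type")
        spans = tuple(tuple(s) for s in self.spans)
        if not spans:
            raise InputError(f"gene {self.name}: no spans")
        genomic = sorted(spans)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise InputError(f"gene {self.name}: overlapping spans")
        object.__setattr__(self, "spans", spans)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)


@dataclass(frozen=True)
class GeneAudit:
    """Audit outcome for one gene in one assembly."""

    gene: str
    status: str  # ok | internal_stop | missing | no_start | no_terminal_stop | bad_length

    VALID = ("ok", "internal_stop", "missing", "no_start", "no_terminal_stop", "bad_length")

    def __post_init__(self):
        if self.status not in self.VALID:
            raise ParameterError(f"unknown audit status {self.status!r}")


@dataclass
class TransferResult:
    annotations: List[GeneAnnotation]
    missing: List[str]
    ambiguous: List[str] = field(default_factory=list)


def gene_sequence(genome: CircularSequence, gene: GeneAnnotation) -> str:
    """Unspliced genomic sequence of the gene extent, coding-strand
    oriented."""
    seq = genome.fetch(gene.start, gene.end)
    return seq if gene.strand == "+" else revcomp(seq)


def spliced_cds(genome: CircularSequence, gene: GeneAnnotation) -> str:
    """Concatenated exon sequence on the coding strand."""
    genomic = sorted(gene.spans)
    parts = [genome.fetch(s, e) for s, e in genomic]
    joined = "".join(parts)
    return joined if gene.strand == "+" else revcomp(joined)


def _best_hits(query: str, target: str, max_dist: int):
    """Best infix matches of query in target: (distance, [locations])."""
    res = edlib.align(query, target, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return None
    return res["editDistance"], res["locations"]


def transfer_annotations(
    reference_genes: Sequence[GeneAnnotation],
    target: CircularSequence,
    min_identity: float = 0.95,
    reference: Optional[CircularSequence] = None,
) -> TransferResult:
    """Lift reference gene annotations onto a target assembly.

    Each reference gene sequence is searched on both strands of the
    (circular) target; the best local match with identity and query
    coverage of at least ``min_identity`` is lifted over.  Genes without a
    qualifying match are reported missing; genes with several equally
    good, non-equivalent best matches are transferred at the first
    location and flagged ambiguous.
    """
    if reference is None:
        raise ParameterError("a reference genome carrying the gene sequences is required")
    L = len(target)
    doubled = target.residues + target.residues
    transferred: List[GeneAnnotation] = []
    missing: List[str] = []
    ambiguous: List[str] = []
    for gene in reference_genes:
        q = gene_sequence(reference, gene)
        max_dist = int(len(q) * (1 - min_identity))
        hits = []  # (distance, start_on_target, strand)
        fwd = _best_hits(q, doubled, max_dist)
        if fwd is not None:
            d, locs = fwd
            hits += [(d, s % L, "+") for s, _ in locs if s < L]
        rev = _best_hits(revcomp(q), doubled, max_dist)
        if rev is not None:
            d, locs = rev
            hits += [(d, s % L, "-") for s, _ in locs if s < L]
        if not hits:
            missing.append(gene.name)
            continue
        best_d = min(h[0] for h in hits)
        best = sorted(set(h for h in hits if h[0] == best_d), key=lambda h: (h[1], h[2]))
        if len(best) > 1:
            ambiguous.append(gene.name)
        _, start, hit_strand = best[0]
        # map sub-spans by their offsets from the coding 5' end of the
        # gene extent; exact for equal-length matches, approximate under
        # small indels.  q is coding-oriented, so the hit strand is the
        # coding strand on the target.
        cl = len(q)
        new_spans = []
        for s, e in sorted(gene.spans):
            if gene.strand == "+":
                o_s, o_e = s - gene.start, e - gene.start
            else:
                o_s, o_e = gene.end - e, gene.end - s
            if hit_strand == "+":
                new_spans.append((start + o_s, start + o_e))
            else:
                new_spans.append((start + cl - o_e, start + cl - o_s))
        # 5'->3' on the coding strand: ascending for '+', descending for '-'
        ordered = tuple(sorted(new_spans, reverse=(hit_strand == "-")))
        transferred.append(
            GeneAnnotation(gene.name, ordered, hit_strand, gene.feature_type)
        )
    return TransferResult(transferred, missing, ambiguous)


def validate_cds(
    cds: str,
    genetic_code: int = PLASTID_CODON_TABLE,
    strict_start: bool = False,
) -> str:
    """Audit one coding sequence; the first failed check names the status.

    Checks, in order: length is a multiple of three; the first codon is an
    accepted start; the last codon is a stop; no stop codon occurs before
    the last.  Returns one of 'bad_length', 'no_start',
    'no_terminal_stop', 'internal_stop', 'ok'.
    """
    cds = cds.upper()
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stops = set(table.stop_codons)
    if len(cds) % 3 != 0 or len(cds) < 6:
        return "bad_length"
    starts = ("ATG",) if strict_start else START_CODONS
    if cds[:3] not in starts:
        return "no_start"
    if cds[-3:] not in stops:
        return "no_terminal_stop"
    for i in range(3, len(cds) - 3, 3):
        if cds[i : i + 3] in stops:
            return "internal_stop"
    return "ok"


def audit_assembly(
    target: CircularSequence,
    reference_genes: Sequence[GeneAnnotation],
    reference: CircularSequence,
    min_identity: float = 0.95,
) -> List[GeneAudit]:
    """Transfer annotations onto one assembly and audit every CDS."""
    result = transfer_annotations(
        reference_genes, target, min_identity=min_identity, reference=reference
    )
    audits = [GeneAudit(name, "missing") for name in result.missing]
    for gene in result.annotations:
        if gene.feature_type != "CDS":
            continue
        cds = spliced_cds(target, gene)
        audits.append(GeneAudit(gene.name, validate_cds(cds)))
    return audits


def gene_report(
    assemblies: Dict[str, CircularSequence],
    reference_genes: Sequence[GeneAnnotation],
    reference: CircularSequence,
    min_identity: float = 0.95,
) -> pd.DataFrame:
    """Audit table across assemblies: internal stops and missing genes.

    Columns mirror the conventional assembly-audit layout: one row per
    assembly, a comma-joined list of genes whose translation contains an
    internal stop codon, and a list of genes with no DNA sequence at the
    expected position.
    """
    rows = []
    for label, target in assemblies.items():
        audits = audit_assembly(target, reference_genes, reference, min_identity)
        stops = sorted(a.gene for a in audits if a.status == "internal_stop")
        absent = sorted(a.gene for a in audits if a.status == "missing")
        rows.append(
            {
                "Asmb.": label,
                "Internal stop codons in translation": ", ".join(stops),
                "No DNA sequence at this position": ", ".join(absent),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Asmb.",
            "Internal stop codons in translation",
            "No DNA sequence at this position",
        ],
    )
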