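"""Reference-based assembly statistics: contig counts, largest contig,
NGA50/LGA50 contiguity, and IR sequence equality.

NGA50/LGA50 here are simplified reference-aware contiguity metrics:
contigs are decomposed into colinear aligned blocks by unique-k-mer
anchor chaining (a block breaks at any rearrangement, i.e. strand switch
or diagonal jump), blocks are sorted by decreasing length, and NGA50 is
the block length at which the cumulative length first reaches half the
reference; LGA50 is that block's 1-based rank.  When the aligned blocks
cover less than half the reference both are undefined (rendered as
"n.s.d." in reports).  This reproduces the full metric on clean and
cleanly-split assemblies; it does not reimplement a complete misassembly
classifier and may differ from one on pathological inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from ._seqnum import revcomp
from .errors import ParameterError
from .postprocess import Contig, _unique_kmer_index
from .structure import CircularSequence, QuadripartitePartition, region_sequences

__all__ = [
    "MetricsRecord",
    "contig_stats",
    "nga50_lga50",
    "ir_equality",
    "assembly_metrics",
]


@dataclass(frozen=True)
class MetricsRecord:
    """Per-assembly statistics mirroring a standard assembly QC table."""

    n_contigs: int
    largest_contig: int
    nga50: Optional[int] = None
    lga50: Optional[int] = None
    ir_equal: Optional[bool] = None
    ir_length: Optional[int] = None


def contig_stats(contigs: Sequence[Contig]) -> Tuple[int, int]:
    """Number of contigs and largest contig length.

    Callers are expected to have removed sub-100 bp fragments first
    (see :func:`plastidqc.postprocess.filter_short`).
    """
    if not contigs:
        return 0, 0
    return len(contigs), max(len(c) for c in contigs)


def _contig_anchors(contig: Contig, index: dict, k: int, L: int):
    """Anchor list [(contig_pos, ref_pos)] on the majority strand, plus
    the oriented contig length."""
    votes = {"+": [], "-": []}
    for strand, s in (("+", contig.residues), ("-", revcomp(contig.residues))):
        for off in range(0, max(0, len(s) - k + 1)):
            pos = index.get(s[off : off + k])
            if pos is not None:
                votes[strand].append((off, pos))
    strand = "+" if len(votes["+"]) >= len(votes["-"]) else "-"
    return votes[strand]


def _blocks_for_contig(anchors, contig_len: int, k: int, L: int, diag_tol: int):
    """Split a contig's anchors into colinear chains and return block
    lengths measured on the contig.

    Two consecutive anchors chain when the implied reference diagonal
    (ref - contig, modulo L) is stable within ``diag_tol``; a diagonal
    jump marks a rearrangement and breaks the block.  Repeat regions
    (e.g. the IRs) carry no unique anchors but are traversed colinearly,
    so same-diagonal anchors chain across them.  Unanchored contig flanks
    are assigned to their neighbouring block.
    """
    if not anchors:
        return []
    anchors = sorted(anchors)
    groups = [[anchors[0]]]
    for (c1, r1), (c2, r2) in zip(anchors, anchors[1:]):
        d1 = (r1 - c1) % L
        d2 = (r2 - c2) % L
        delta = min((d2 - d1) % L, (d1 - d2) % L)
        if delta <= diag_tol:
            groups[-1].append((c2, r2))
        else:
            groups.append([(c2, r2)])
    # block boundaries on the contig: midpoints between adjacent groups
    bounds = [0]
    for g1, g2 in zip(groups, groups[1:]):
        end1 = g1[-1][0] + k
        start2 = g2[0][0]
        bounds.append((end1 + start2) // 2)
    bounds.append(contig_len)
    return [bounds[i + 1] - bounds[i] for i in range(len(groups))]


def nga50_lga50(
    contigs: Sequence[Contig],
    reference: CircularSequence,
    k: int = 21,
    diag_tol: int = 50,
) -> Tuple[Optional[int], Optional[int]]:
    """Simplified NGA50 and LGA50 of a contig set against a reference.

    Returns (None, None) — "n.s.d." — when the aligned blocks sum to less
    than half the reference length or no contig aligns at all.
    """
    if not contigs:
        return None, None
    index = _unique_kmer_index(reference, k)
    L = len(reference)
    blocks = []
    for contig in contigs:
        anchors = _contig_anchors(contig, index, k, L)
        blocks.extend(_blocks_for_contig(anchors, len(contig), k, L, diag_tol))
    if not blocks:
        return None, None
    blocks.sort(reverse=True)
    half = L / 2
    cum = 0
    for rank, length in enumerate(blocks, start=1):
        cum += length
        if cum >= half:
            return length, rank
    return None, None


def ir_equality(
    genome: CircularSequence, partition: QuadripartitePartition
) -> Tuple[bool, int]:
    """Whether reverse-complement(IRa) equals IRb exactly, plus the
    mismatch count.  Symbol comparison is strict: an ambiguity code
    differing from a base counts as a mismatch."""
    _, irb, _, ira = region_sequences(genome, partition)
    rc_ira = revcomp(ira)
    mismatches = sum(1 for x, y in zip(rc_ira, irb) if x != y)
    mismatches += abs(len(rc_ira) - len(irb))
    return mismatches == 0, mismatches


def assembly_metrics(
    contigs: Sequence[Contig],
    reference: CircularSequence,
    genome: Optional[CircularSequence] = None,
    partition: Optional[QuadripartitePartition] = None,
) -> MetricsRecord:
    """Full metrics record for one assembly.

    ``genome``/``partition`` enable the IR columns; they stay "n.a."
    (None) when the assembly was never finished into a circular genome or
    no IR was detected.
    """
    n, largest = contig_stats(contigs)
    nga, lga = nga50_lga50(contigs, reference)
    ir_eq = ir_len = None
    if genome is not None and partition is not None:
        ir_eq, _ = ir_equality(genome, partition)
        ir_len = partition.ir_length
    return MetricsRecord(n, largest, nga, lga, ir_eq, ir_len)
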