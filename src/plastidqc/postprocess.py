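"""Contig post-processing: turn raw assembler output into a single circular
genome.

The pipeline mirrors the manual finishing steps practitioners apply to
organelle assemblies: drop sub-100 bp fragments, order and orient contigs
against a structural reference, merge exact overlaps of at least 15 bp,
trim duplicated endpoints (motif search, up to 3 mismatches, within 100 bp
of the ends), circularize, and report poly-N uncertainty runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seqnum import encode_bases, revcomp, validate_dna
from .errors import InputError, OrderingError, StructureError
from .structure import CircularSequence

__all__ = [
    "Contig",
    "Provenance",
    "Assembly",
    "filter_short",
    "order_contigs",
    "merge_overlaps",
    "trim_duplicate_endpoints",
    "find_polyN",
]


@dataclass
class Contig:
    """A linear assembler output piece, optionally placed on a reference."""

    id: str
    residues: str
    ref_start: Optional[int] = None
    strand: Optional[str] = None  # '+' or '-' once placed

    def __post_init__(self):
        if not self.residues:
            raise InputError(f"contig {self.id}: empty sequence")
        self.residues = self.residues.upper()
        validate_dna(self.residues, f"contig {self.id}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Provenance:
    """Where an assembly came from: software, cap level, replicate, seed."""

    software: str = "unknown"
    cap_level: Optional[float] = None
    replicate: Optional[str] = None
    seed_label: Optional[str] = None


@dataclass
class Assembly:
    """A set of contigs plus, once finished, the circular genome."""

    contigs: list
    provenance: Provenance = field(default_factory=Provenance)
    finished: Optional[CircularSequence] = None


def filter_short(contigs: Sequence[Contig], min_len: int = 100) -> list:
    """Keep contigs of at least ``min_len`` bases (inclusive), preserving
    order.  The default removes mono-/di-nucleotide scale fragments that
    would inflate contig counts."""
    return [c for c in contigs if len(c) >= min_len]


def _unique_kmer_index(reference: CircularSequence, k: int) -> dict:
    """Positions of k-mers that occur exactly once (forward) in the
    circular reference."""
    ref = reference.residues
    doubled = ref + ref[: k - 1]
    positions: dict = {}
    for i in range(len(ref)):
        kmer = doubled[i : i + k]
        if kmer in positions:
            positions[kmer] = None  # repeated; disqualify
        else:
            positions[kmer] = i
    return {kmer: pos for kmer, pos in positions.items() if pos is not None}


def order_contigs(
    contigs: Sequence[Contig],
    reference: CircularSequence,
    k: int = 21,
):
    """Place contigs on a circular reference by unique-k-mer anchoring.

    Each contig collects anchor votes on both strands; the majority strand
    wins, the reference start is the most common implied start, and the
    output is sorted by that start.  Contigs without a single anchor are
    returned separately as unplaceable.

    Returns (ordered_contigs, unplaced_contigs); ordered contigs are
    re-oriented to the forward strand and carry ``ref_start``/``strand``.
    Raises :class:`OrderingError` when nothing can be placed.
    """
    index = _unique_kmer_index(reference, k)
    L = len(reference)
    ordered = []
    unplaced = []
    ambiguous = []  # exact strand-vote ties: contigs inside an IR copy

    def modal_start(starts):
        vals, counts = np.unique(starts, return_counts=True)
        return int(vals[np.argmax(counts)])

    for contig in contigs:
        votes = {"+": [], "-": []}
        seq = contig.residues
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for off in range(0, max(1, len(s) - k + 1)):
                pos = index.get(s[off : off + k])
                if pos is not None:
                    votes[strand].append((pos - off) % L)
        if not votes["+"] and not votes["-"]:
            unplaced.append(contig)
            continue
        if votes["+"] and votes["-"] and len(votes["+"]) == len(votes["-"]):
            # a contig wholly inside one inverted-repeat arm matches both
            # copies equally; defer and resolve by overlap with neighbours
            ambiguous.append(
                (
                    contig,
                    [
                        (contig.residues, modal_start(votes["+"]), "+"),
                        (revcomp(contig.residues), modal_start(votes["-"]), "-"),
                    ],
                )
            )
            continue
        strand = "+" if len(votes["+"]) > len(votes["-"]) else "-"
        residues = contig.residues if strand == "+" else revcomp(contig.residues)
        ordered.append(
            Contig(contig.id, residues, ref_start=modal_start(votes[strand]), strand=strand)
        )
    if not ordered and not ambiguous:
        raise OrderingError("no contig could be placed on the reference")
    ordered.sort(key=lambda c: (c.ref_start, c.id))
    for contig, candidates in ambiguous:
        # both IR copies match equally well; prefer the placement that
        # covers reference span no other contig covers (the manual
        # finisher's completeness argument)
        covered = np.zeros(L, dtype=bool)
        for other in ordered:
            idx = (other.ref_start + np.arange(len(other))) % L
            covered[idx] = True
        best = None
        for residues, start, strand in candidates:
            idx = (start + np.arange(len(residues))) % L
            new_cov = int((~covered[idx]).sum())
            cand = (new_cov, strand == "+", residues, start, strand)
            if best is None or cand[:2] > best[:2]:
                best = cand
        _, _, residues, start, strand = best
        ordered.append(Contig(contig.id, residues, ref_start=start, strand=strand))
        ordered.sort(key=lambda c: (c.ref_start, c.id))
    return ordered, unplaced


def _longest_exact_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest exact suffix(a)/prefix(b) overlap of length >= min_overlap,
    0 when none exists."""
    limit = min(len(a), len(b))
    probe = b[:min_overlap]
    start = len(a) - limit
    while True:
        p = a.find(probe, start)
        if p == -1 or p > len(a) - min_overlap:
            return 0
        o = len(a) - p
        if b[:o] == a[p:]:
            return o
        start = p + 1


def merge_overlaps(ordered_contigs: Sequence[Contig], min_overlap: int = 15) -> list:
    """Merge adjacent contigs sharing an exact overlap of >= min_overlap bp.

    Overlaps carrying any mismatch are never merged.  Merging is iterated
    to a fixpoint, so chains collapse into super-contigs; the output never
    alters a single base of the inputs.
    """
    contigs = list(ordered_contigs)
    if not contigs:
        return []
    changed = True
    while changed:
        changed = False
        merged: list = [contigs[0]]
        for nxt in contigs[1:]:
            cur = merged[-1]
            if nxt.residues in cur.residues:
                # fully contained (redundant) contig adds nothing
                changed = True
                continue
            o = _longest_exact_overlap(cur.residues, nxt.residues, min_overlap)
            if o:
                merged[-1] = Contig(
                    cur.id,
                    cur.residues + nxt.residues[o:],
                    ref_start=cur.ref_start,
                    strand=cur.strand,
                )
                changed = True
            else:
                merged.append(nxt)
        contigs = merged
    return contigs


def _mismatch_positions(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_duplicate_endpoints(
    supercontig: Contig | str,
    motif_len: int = 25,
    max_mismatch: int = 3,
    end_window: int = 100,
) -> CircularSequence:
    """Remove a duplicated endpoint and circularize.

    The first and last ``motif_len`` bases are searched against the
    opposite end region; a match with at most ``max_mismatch`` mismatches
    lying within ``end_window`` of an end marks a span the assembler
    extended past the true endpoint.  The duplicated span is removed once,
    from the 3' side, and the result is returned as a circular sequence.
    """
    seq = supercontig.residues if isinstance(supercontig, Contig) else supercontig
    n = len(seq)
    if n <= motif_len:
        return CircularSequence(seq, "circular")

    def best_match(motif: str, region_start: int, region_end: int):
        hits = []
        for p in range(region_start, region_end - motif_len + 1):
            mm = _mismatch_positions(motif, seq[p : p + motif_len])
            if mm <= max_mismatch:
                hits.append((mm, p))
        return min(hits) if hits else None

    head = seq[:motif_len]
    tail = seq[-motif_len:]
    # head motif found again near the 3' end -> everything from the match on
    # is a re-assembled copy of the genome start
    hit = best_match(head, max(motif_len, n - end_window), n)
    if hit is not None:
        _, p = hit
        trimmed = seq[:p]
        if not trimmed:
            raise StructureError("endpoint trimming would empty the sequence")
        return CircularSequence(trimmed, "circular")
    # tail motif found near the 5' end -> the 3' end duplicates the start;
    # the duplicated suffix has length q + motif_len
    hit = best_match(tail, 0, min(end_window, n - motif_len))
    if hit is not None:
        _, q = hit
        cut = q + motif_len
        if cut >= n:
            raise StructureError("endpoint trimming would empty the sequence")
        return CircularSequence(seq[: n - cut], "circular")
    return CircularSequence(seq, "circular")


_POLYN = re.compile(r"N+")


def find_polyN(seq: str | CircularSequence, min_run: int = 1) -> list:
    """Maximal runs of N of at least ``min_run`` bases, as (start, end)
    half-open spans.  Poly-N runs mark assembler uncertainty; they are
    reported, never corrected, here."""
    s = seq.residues if isinstance(seq, CircularSequence) else seq.upper()
    return [
        (m.start(), m.end())
        for m in _POLYN.finditer(s)
        if m.end() - m.start() >= min_run
    ]
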