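"""Plastome structure: circular sequences, inverted-repeat detection, and
quadripartite (LSC / IRb / SSC / IRa) partitioning.

Most land-plant plastomes consist of a long single-copy region (LSC), a
short single-copy region (SSC), and two inverted repeats (IRa, IRb) that
are exact or near-exact reverse complements of each other.  This module
finds the repeats, derives the four-region partition, and canonicalizes a
circular assembly (rotation to the LSC start, homogenized SSC orientation)
so that assemblies from different tools become directly comparable.

Coordinates are 0-based half-open throughout; spans may extend past the
sequence length to express wrap-around on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seqnum import (
    WindowHasher,
    encode_unique_ambiguous,
    revcomp,
    validate_dna,
)
from .errors import InputError, ParameterError, StructureError

__all__ = [
    "CircularSequence",
    "Span",
    "QuadripartitePartition",
    "detect_inverted_repeat",
    "canonicalize",
    "region_sequences",
]


@dataclass(frozen=True)
class Span:
    """Half-open span [start, end) on a circular coordinate system.

    ``end`` may exceed the genome length to express wrap-around; ``start``
    is always within [0, genome_length).
    """

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end < self.start:
            raise StructureError(f"span end before start: {self}")


@dataclass(frozen=True)
class CircularSequence:
    """A DNA sequence with explicit topology.

    residues are upper-cased on construction and restricted to IUPAC DNA
    symbols.  Circular indexing is modulo length.
    """

    residues: str
    topology: str = "circular"

    def __post_init__(self):
        if not self.residues:
            raise InputError("empty sequence")
        if self.topology not in ("circular", "linear"):
            raise InputError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        validate_dna(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Substring [start, end); wraps around the origin when circular."""
        L = len(self.residues)
        if self.topology == "linear":
            if start < 0 or end > L:
                raise InputError("span outside linear sequence")
            return self.residues[start:end]
        n = end - start
        if n > L:
            raise InputError("span longer than circular sequence")
        start %= L
        if start + n <= L:
            return self.residues[start : start + n]
        return self.residues[start:] + self.residues[: start + n - L]

    def region(self, span: Span) -> str:
        return self.fetch(span.start, span.end)

    def rotated(self, offset: int) -> "CircularSequence":
        """Sequence starting at position ``offset`` of this circle."""
        if self.topology != "circular":
            raise StructureError("cannot rotate a linear sequence")
        L = len(self.residues)
        offset %= L
        return CircularSequence(
            self.residues[offset:] + self.residues[:offset], "circular"
        )

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(revcomp(self.residues), self.topology)


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC / IRb / SSC / IRa spans on a circular plastome.

    The four spans are pairwise disjoint on the circle, tile it completely,
    and occur in the cyclic order LSC, IRb, SSC, IRa.  ``ir_mismatches``
    counts positions where reverse-complement(IRa) differs from IRb.
    """

    lsc: Span
    irb: Span
    ssc: Span
    ira: Span
    ir_length: int
    ir_mismatches: int
    genome_length: int

    def __post_init__(self):
        total = sum(s.length for s in (self.lsc, self.irb, self.ssc, self.ira))
        if total != self.genome_length:
            raise StructureError(
                f"regions sum to {total}, genome is {self.genome_length}"
            )
        if self.irb.length != self.ira.length:
            raise StructureError("IR arms differ in length")
        if self.ir_length != self.irb.length:
            raise StructureError("ir_length disagrees with IR spans")
        if self.lsc.length <= self.ssc.length:
            raise StructureError("LSC not longer than SSC")
        L = self.genome_length
        order = [self.lsc, self.irb, self.ssc, self.ira]
        for a, b in zip(order, order[1:]):
            if a.end % L != b.start % L:
                raise StructureError("regions are not contiguous in LSC,IRb,SSC,IRa order")
        if order[-1].end % L != order[0].start % L:
            raise StructureError("regions do not close the circle")

    @property
    def region_lengths(self) -> dict:
        return {
            "LSC": self.lsc.length,
            "IRb": self.irb.length,
            "SSC": self.ssc.length,
            "IRa": self.ira.length,
        }


def _circular_gap(a_end: int, b_start: int, L: int) -> int:
    """Length of the gap from position a_end forward to b_start on the circle."""
    return (b_start - a_end) % L


def _verify_pair(doubled: str, i: int, j: int, m: int) -> bool:
    a = doubled[i : i + m]
    b = doubled[j : j + m]
    return set(a) <= set("ACGT") and set(b) <= set("ACGT") and revcomp(b) == a


def _rc_hashers(seq: str):
    """Window hashers for the doubled sequence and its doubled reverse
    complement, built once and reused across repeat-length queries."""
    vals_s = encode_unique_ambiguous(seq + seq, salt=0)
    t = revcomp(seq)
    vals_t = encode_unique_ambiguous(t + t, salt=len(seq))
    return WindowHasher(vals_s), WindowHasher(vals_t)


def _find_rc_repeats(seq: str, m: int, limit: Optional[int] = 1, hashers=None):
    """All (up to ``limit``) verified disjoint rc-repeat pairs of length m.

    Returns a list of (i, j) circle positions with
    revcomp(seq[j:j+m]) == seq[i:i+m] and the two spans disjoint on the
    circle.
    """
    L = len(seq)
    if 2 * m > L:
        return []
    hasher_s, hasher_t = hashers if hashers is not None else _rc_hashers(seq)
    hs = hasher_s.window_hashes(m, L)
    ht = hasher_t.window_hashes(m, L)
    # rc of the window at circle position j in seq is the window of t at
    # (L - j - m) mod L; so pair windows of equal hash.
    j_of_t = (np.uint64(L) - np.arange(L, dtype=np.uint64) - np.uint64(m)) % np.uint64(L)
    # ht indexed by t-window start; build lookup from hash -> j positions
    order = np.argsort(ht, kind="stable")
    ht_sorted = ht[order]
    lo = np.searchsorted(ht_sorted, hs, side="left")
    hi = np.searchsorted(ht_sorted, hs, side="right")
    hit_rows = np.nonzero(hi > lo)[0]
    doubled = seq + seq
    pairs = []
    seen = set()
    for i in hit_rows:
        i = int(i)
        for t_idx in order[lo[i] : hi[i]]:
            j = int((L - int(t_idx) - m) % L)
            # disjoint on the circle and not the same span
            if (j - i) % L < m or (i - j) % L < m:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            if _verify_pair(doubled, i, j, m):
                pairs.append((i, j))
                if limit is not None and len(pairs) >= limit:
                    return pairs
    return pairs


def detect_inverted_repeat(
    seq: CircularSequence, min_ir_len: int = 1000
) -> Optional[QuadripartitePartition]:
    """Find the longest pair of disjoint, exactly reverse-complementary
    repeats and derive the quadripartite partition.

    The search is rotation-invariant (windows are taken on the doubled
    sequence) and exact: ambiguity codes never match, and the reported
    arms carry zero internal mismatches by construction.  The longer of
    the two single-copy gaps is labelled LSC.  Returns ``None`` when no
    repeat pair of at least ``min_ir_len`` exists.

    Parameters
    ----------
    seq : CircularSequence
        Circular genome to scan.
    min_ir_len : int
        Minimum arm length, at least 100 bp (default 1000 bp — plastome
        IRs in the target taxa are far longer; this avoids tRNA-scale
        false hits).
    """
    if seq.topology != "circular":
        raise InputError("inverted-repeat detection requires a circular sequence")
    if min_ir_len < 100:
        raise ParameterError("min_ir_len must be >= 100")
    s = seq.residues
    L = len(s)
    if 2 * min_ir_len > L:
        return None
    hashers = _rc_hashers(s)
    if not _find_rc_repeats(s, min_ir_len, limit=1, hashers=hashers):
        return None
    lo, hi = min_ir_len, L // 2  # check(lo) is True
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _find_rc_repeats(s, mid, limit=1, hashers=hashers):
            lo = mid
        else:
            hi = mid - 1
    m = lo
    pairs = _find_rc_repeats(s, m, limit=None, hashers=hashers)
    if not pairs:  # pragma: no cover - binary search guarantees a pair
        raise StructureError("repeat vanished during refinement")
    best = None
    for i, j in pairs:
        for a, b in ((i, j), (j, i)):
            # interpret arm at `a` as IRb and arm at `b` as IRa: then
            # LSC is the gap ending at a, SSC the gap from a+m to b.
            lsc_len = _circular_gap(b + m, a, L)
            ssc_len = _circular_gap(a + m, b, L)
            if lsc_len <= ssc_len:
                continue
            lsc_start = (b + m) % L
            cand = (lsc_start, a, b, lsc_len, ssc_len)
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        # equal gaps: no LSC/SSC distinction possible
        raise StructureError("single-copy gaps are equal; cannot label LSC/SSC")
    lsc_start, irb_start, ira_start, lsc_len, ssc_len = best
    # build spans walking the circle from the LSC start
    pos = lsc_start
    spans = []
    for length in (lsc_len, m, ssc_len, m):
        spans.append(Span(pos % L, pos % L + length))
        pos += length
    lsc, irb, ssc, ira = spans
    irb_seq = seq.region(irb)
    ira_seq = seq.region(ira)
    mismatches = sum(1 for x, y in zip(revcomp(ira_seq), irb_seq) if x != y)
    return QuadripartitePartition(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira,
        ir_length=m, ir_mismatches=mismatches, genome_length=L,
    )


def region_sequences(seq: CircularSequence, partition: QuadripartitePartition):
    """The four region sequences (LSC, IRb, SSC, IRa) of ``seq``.

    Their concatenation in canonical order reconstructs the rotation of
    ``seq`` that starts at the LSC.
    """
    if partition.genome_length != len(seq):
        raise StructureError("partition does not belong to this sequence")
    return (
        seq.region(partition.lsc),
        seq.region(partition.irb),
        seq.region(partition.ssc),
        seq.region(partition.ira),
    )


def _ssc_orientation_score(ssc: str, reference: CircularSequence) -> int:
    """Edit distance of ``ssc`` against its best match in the reference."""
    import edlib

    ref = reference.residues
    target = ref + ref[: len(ssc)] if reference.topology == "circular" else ref
    res = edlib.align(ssc, target, mode="HW", task="distance")
    return res["editDistance"]


def canonicalize(
    seq: CircularSequence,
    partition: QuadripartitePartition,
    reference: Optional[CircularSequence] = None,
) -> CircularSequence:
    """Rotate to the LSC start and homogenize the SSC orientation.

    The output starts at base 1 of the LSC with region order
    LSC→IRb→SSC→IRa.  The SSC orientation is the one with the smaller
    edit distance to the reference (when given) and otherwise the
    lexicographically smaller of the two orientations.  Idempotent: all
    rotation and SSC-isomer variants of one genome map to one string.
    """
    lsc, irb, ssc, ira = region_sequences(seq, partition)
    ssc_rc = revcomp(ssc)
    if reference is not None:
        d_fwd = _ssc_orientation_score(ssc, reference)
        d_rev = _ssc_orientation_score(ssc_rc, reference)
        if d_fwd < d_rev:
            chosen = ssc
        elif d_rev < d_fwd:
            chosen = ssc_rc
        else:
            chosen = min(ssc, ssc_rc)
    else:
        chosen = min(ssc, ssc_rc)
    return CircularSequence(lsc + irb + chosen + ira, "circular")
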