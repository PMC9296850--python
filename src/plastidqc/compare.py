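"""Pairwise assembly comparison: alignment-based SNP/indel counts,
per-region length differences, distance matrices, and principal
coordinates analysis centered on a designated final assembly.

Four pairwise metrics are produced for any two canonicalized assemblies
of the same genome: SNPcount (substitution columns), and LSClendif /
SSClendif / IRlendif (absolute region length differences).  Because
single-base indels between near-identical assemblies are biologically as
informative as substitutions, the record also carries an indel event
count and a headline ``total_diff_count`` = substitutions + indel events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .errors import DivergenceError, ParameterError
from .structure import CircularSequence, QuadripartitePartition

__all__ = [
    "Alignment",
    "DistanceRecord",
    "pairwise_align",
    "count_differences",
    "region_length_difference",
    "compare_assemblies",
    "distance_matrix",
    "pcoa",
    "PCoAResult",
    "METRICS",
]

METRICS = ("SNPcount", "LSClendif", "SSClendif", "IRlendif", "totaldiff")

#: IUPAC nucleotide -> set of compatible bases (for the lenient mode)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment as two equal-length gapped strings."""

    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ParameterError("alignment rows differ in length")


@dataclass(frozen=True)
class DistanceRecord:
    """Pairwise assembly differences.

    snp_count counts substitution columns (gap columns excluded);
    indel_event_count counts maximal single-row gap runs; the three
    length fields are absolute region length differences in bases.
    """

    snp_count: int
    indel_event_count: int
    lsc_len_dif: int = 0
    ssc_len_dif: int = 0
    ir_len_dif: int = 0

    @property
    def total_diff_count(self) -> int:
        return self.snp_count + self.indel_event_count

    def metric(self, name: str) -> int:
        try:
            return {
                "SNPcount": self.snp_count,
                "LSClendif": self.lsc_len_dif,
                "SSClendif": self.ssc_len_dif,
                "IRlendif": self.ir_len_dif,
                "totaldiff": self.total_diff_count,
            }[name]
        except KeyError:
            raise ParameterError(f"unknown metric {name!r}") from None


def _unique_positions(s: str, k: int) -> dict:
    pos: dict = {}
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        pos[kmer] = -1 if kmer in pos else i
    return {kmer: p for kmer, p in pos.items() if p >= 0}


def _anchor_chain(sa: str, sb: str, k: int = 21):
    """Colinear chain of exact match blocks from shared unique k-mers.

    Returns a list of (a_start, b_start, length) blocks, strictly
    increasing and non-overlapping in both sequences.
    """
    ua = _unique_positions(sa, k)
    ub = _unique_positions(sb, k)
    anchors = sorted(
        (pa, ub[kmer]) for kmer, pa in ua.items() if kmer in ub
    )
    if not anchors:
        return []
    # longest chain with b-position strictly increasing (patience LIS)
    import bisect

    tails: list = []  # last b of chains of each length
    back: list = []
    idx_of_len: list = []
    for i, (_, pb) in enumerate(anchors):
        j = bisect.bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            idx_of_len.append(i)
        else:
            tails[j] = pb
            idx_of_len[j] = i
        back.append(idx_of_len[j - 1] if j > 0 else -1)
    chain = []
    i = idx_of_len[len(tails) - 1]
    while i >= 0:
        chain.append(anchors[i])
        i = back[i]
    chain.reverse()
    # merge same-diagonal runs into blocks; drop anchors that overlap the
    # previous block inconsistently
    blocks = []
    for pa, pb in chain:
        if blocks:
            ba, bb, ln = blocks[-1]
            if pa - ba == pb - bb and pa <= ba + ln:
                blocks[-1] = (ba, bb, pa + k - ba)
                continue
            if pa < ba + ln or pb < bb + ln:
                continue
        blocks.append((pa, pb, k))
    return blocks


def _align_segment(sa: str, sb: str) -> Tuple[str, str]:
    """Exact DP alignment of one inter-anchor segment."""
    if not sa and not sb:
        return "", ""
    if not sa:
        return "-" * len(sb), sb
    if not sb:
        return sa, "-" * len(sa)
    res = edlib.align(sa, sb, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, sa, sb)
    return nice["query_aligned"], nice["target_aligned"]


def pairwise_align(
    a: CircularSequence | str,
    b: CircularSequence | str,
    max_divergence: float = 0.30,
    anchor_k: int = 21,
) -> Alignment:
    """Globally align two canonicalized assemblies.

    Identical inputs yield a gapless alignment.  Near-identical inputs
    are aligned by shared-unique-anchor chaining with exact dynamic-
    programming fill between anchors; anchoring keeps large insertions
    and deletions as single contiguous gap runs instead of scattering
    them across coincidental matches.  Conspecific assemblies are
    near-identical, so inputs whose edit distance exceeds
    ``max_divergence`` of the longer sequence are refused with
    :class:`DivergenceError`.
    """
    sa = a.residues if isinstance(a, CircularSequence) else a.upper()
    sb = b.residues if isinstance(b, CircularSequence) else b.upper()
    if sa == sb:
        return Alignment(sa, sb)
    limit = int(max_divergence * max(len(sa), len(sb)))
    probe = edlib.align(sa, sb, mode="NW", task="distance", k=limit)
    if probe["editDistance"] < 0:
        raise DivergenceError(
            f"edit distance exceeds {max_divergence:.0%} of the sequence length"
        )
    blocks = _anchor_chain(sa, sb, k=anchor_k)
    rows_a = []
    rows_b = []
    pa = pb = 0
    for ba, bb, ln in blocks:
        seg_a, seg_b = _align_segment(sa[pa:ba], sb[pb:bb])
        rows_a.append(seg_a)
        rows_b.append(seg_b)
        rows_a.append(sa[ba : ba + ln])
        rows_b.append(sb[bb : bb + ln])
        pa, pb = ba + ln, bb + ln
    seg_a, seg_b = _align_segment(sa[pa:], sb[pb:])
    rows_a.append(seg_a)
    rows_b.append(seg_b)
    return Alignment("".join(rows_a), "".join(rows_b))


def count_differences(alignment: Alignment, ambiguity: str = "strict") -> DistanceRecord:
    """Count substitution columns and indel events in an alignment.

    In strict mode (default) any pair of unequal symbols is a difference,
    ambiguity codes included; lenient mode treats overlapping IUPAC sets
    as compatible.  Gap columns never count as SNPs; each maximal
    single-row gap run counts as one indel event.
    """
    if ambiguity not in ("strict", "lenient"):
        raise ParameterError("ambiguity must be 'strict' or 'lenient'")
    snp = 0
    events = 0
    in_gap_a = in_gap_b = False
    for x, y in zip(alignment.row_a, alignment.row_b):
        ga, gb = x == "-", y == "-"
        if ga and not in_gap_a:
            events += 1
        if gb and not in_gap_b:
            events += 1
        in_gap_a, in_gap_b = ga, gb
        if ga or gb:
            continue
        if x == y:
            continue
        if ambiguity == "lenient" and set(_IUPAC.get(x, x)) & set(_IUPAC.get(y, y)):
            continue
        snp += 1
    return DistanceRecord(snp_count=snp, indel_event_count=events)


def region_length_difference(
    pa: QuadripartitePartition, pb: QuadripartitePartition
) -> Tuple[int, int, int]:
    """Absolute LSC, SSC, and single-IR length differences between two
    partitions.  IR arms within one partition have equal length by
    construction; should they not, their mean is used and a warning
    raised."""
    import warnings

    def ir_len(p: QuadripartitePartition) -> float:
        if p.irb.length != p.ira.length:  # pragma: no cover - defensive
            warnings.warn("unequal IR arms; using their mean length")
            return (p.irb.length + p.ira.length) / 2
        return p.irb.length

    return (
        abs(pa.lsc.length - pb.lsc.length),
        abs(pa.ssc.length - pb.ssc.length),
        int(abs(ir_len(pa) - ir_len(pb))),
    )


def compare_assemblies(
    a: CircularSequence,
    b: CircularSequence,
    pa: Optional[QuadripartitePartition] = None,
    pb: Optional[QuadripartitePartition] = None,
    ambiguity: str = "strict",
) -> DistanceRecord:
    """Full pairwise record: alignment differences plus region length
    differences (when both partitions are supplied)."""
    rec = count_differences(pairwise_align(a, b), ambiguity=ambiguity)
    if pa is not None and pb is not None:
        lsc, ssc, ir = region_length_difference(pa, pb)
        rec = DistanceRecord(rec.snp_count, rec.indel_event_count, lsc, ssc, ir)
    return rec


def distance_matrix(
    assemblies: Dict[str, Tuple[CircularSequence, Optional[QuadripartitePartition]]],
    metric: str = "SNPcount",
    ambiguity: str = "strict",
) -> pd.DataFrame:
    """Symmetric pairwise distance matrix for one metric.

    ``assemblies`` maps labels to (sequence, partition) pairs; partitions
    may be None for the pure sequence metrics.  The diagonal is zero.
    These are raw difference counts; the triangle inequality is not
    guaranteed and not asserted.
    """
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}")
    labels = list(assemblies)
    n = len(labels)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            (sa, pa), (sb, pb) = assemblies[labels[i]], assemblies[labels[j]]
            rec = compare_assemblies(sa, sb, pa, pb, ambiguity=ambiguity)
            mat[i, j] = mat[j, i] = rec.metric(metric)
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class PCoAResult:
    """Classical-scaling embedding of a distance matrix.

    ``raw_coordinates`` are the unscaled principal coordinates (their
    pairwise Euclidean distances reproduce the input for Euclidean-
    realizable matrices); ``coordinates`` are translated so the chosen
    center sits at the origin, with the first two axes scaled to
    [-1, 1].  ``absolute_variance`` is the per-axis eigenvalue divided by
    (n - 1), in squared metric units; ``percent_variance`` sums to at
    most 100 and is non-increasing.
    """

    raw_coordinates: pd.DataFrame
    coordinates: pd.DataFrame
    absolute_variance: np.ndarray
    percent_variance: np.ndarray
    negative_eigenvalue_magnitude: float


def pcoa(matrix: pd.DataFrame, center_on: Optional[str] = None) -> PCoAResult:
    """Principal coordinates analysis (classical metric scaling).

    Squared distances are double-centered, eigendecomposed, and the
    coordinates are eigenvectors scaled by the square roots of the
    non-negative eigenvalues; negative eigenvalues are truncated to zero
    and their total magnitude reported.  When ``center_on`` is given the
    projection is translated so that assembly sits at the origin and the
    first two axes are divided by their maximum absolute value.
    """
    D = np.asarray(matrix, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ParameterError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ParameterError("matrix must be symmetric with zero diagonal")
    labels = list(matrix.index)
    if center_on is not None and center_on not in labels:
        raise ParameterError(f"center_on {center_on!r} not among assemblies")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg = float(-eigval[eigval < 0].sum())
    eigval_pos = np.clip(eigval, 0, None)
    # axes with numerically zero eigenvalues carry no signal; zero them
    # so the [-1, 1] axis scaling does not amplify round-off noise
    tol = 1e-9 * max(eigval_pos.max(), 1.0)
    eigval_pos[eigval_pos < tol] = 0.0
    raw = eigvec * np.sqrt(eigval_pos)
    axes = [f"PCo{i + 1}" for i in range(n)]
    raw_df = pd.DataFrame(raw, index=labels, columns=axes)
    coords = raw.copy()
    if center_on is not None:
        coords = coords - coords[labels.index(center_on)]
    for ax in range(min(2, n)):
        m = np.abs(coords[:, ax]).max()
        if m > 0:
            coords[:, ax] = coords[:, ax] / m
    total = eigval_pos.sum()
    pct = 100 * eigval_pos / total if total > 0 else np.zeros(n)
    return PCoAResult(
        raw_coordinates=raw_df,
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        absolute_variance=eigval_pos / max(n - 1, 1),
        percent_variance=pct,
        negative_eigenvalue_magnitude=neg,
    )
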