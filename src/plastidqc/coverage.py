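"""Coverage operations: k-mer-based soft capping of paired reads, windowed
coverage summaries, low-coverage flagging, and SNP/low-coverage
co-localization.

The soft cap is a one-tailed normalization of sequencing coverage: read
pairs whose estimated local depth is at or below the target are always
kept, pairs above it are kept with probability target/depth.  High-depth
regions are thereby down-sampled toward the target while low-depth regions
are untouched, producing a coverage distribution shaped like empirical
data rather than a hard ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seqnum import encode_bases
from .errors import InputError, ParameterError

__all__ = [
    "ReadPair",
    "CapLevel",
    "CoverageProfile",
    "KmerTable",
    "build_kmer_table",
    "estimate_pair_depth",
    "soft_cap",
    "windowed_coverage",
    "flag_low_windows",
    "snp_low_coverage_enrichment",
    "EnrichmentResult",
    "STUDY_CAP_LEVELS",
]

#: the cap grid evaluated in the study design this package supports
STUDY_CAP_LEVELS = (2000, 1000, 500, 250, 100, 50)


@dataclass(frozen=True)
class ReadPair:
    """A paired read with per-base phred qualities (ASCII-33 strings)."""

    id: str
    mate1: str
    mate2: str
    qual1: str = ""
    qual2: str = ""

    def __post_init__(self):
        if not self.mate1 or not self.mate2:
            raise InputError(f"read pair {self.id}: empty mate")
        for mate, qual in ((self.mate1, self.qual1), (self.mate2, self.qual2)):
            if qual and len(qual) != len(mate):
                raise InputError(f"read pair {self.id}: quality length mismatch")


@dataclass(frozen=True)
class CapLevel:
    """Target fold-coverage of a soft cap (any positive value)."""

    target_depth: float

    def __post_init__(self):
        if not self.target_depth > 0:
            raise ParameterError("target_depth must be positive")


@dataclass
class CoverageProfile:
    """Per-base depth over a canonical genome."""

    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or len(self.depth) == 0:
            raise InputError("depth must be a non-empty 1-D vector")
        if (self.depth < 0).any():
            raise InputError("negative depth")

    @property
    def genome_wide_depth(self) -> float:
        return float(self.depth.mean())

    def __len__(self) -> int:
        return len(self.depth)


def _read_kmer_codes(read: str, k: int):
    """Canonical (strand-collapsed) k-mer codes of one read.

    Returns a uint64 array of valid k-mer codes; windows containing a
    non-ACGT symbol are dropped.
    """
    b = encode_bases(read)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = (b < 0).astype(np.int64)
    bad = np.cumsum(np.concatenate([[0], invalid]))
    valid = (bad[k:] - bad[:-k]) == 0
    bu = np.where(b < 0, 0, b).astype(np.uint64)
    sw = np.lib.stride_tricks.sliding_window_view(bu, k)
    powers = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    fwd = sw @ powers
    rc_sw = np.uint64(3) - sw
    rc = rc_sw @ powers[::-1]
    canonical = np.minimum(fwd, rc)
    return canonical[valid]


class KmerTable:
    """Counts of canonical k-mers over a read set."""

    def __init__(self, codes: np.ndarray, counts: np.ndarray, k: int):
        self.codes = codes
        self.counts = counts
        self.k = k

    def count(self, codes: np.ndarray) -> np.ndarray:
        """Multiplicity of each query k-mer in the table (0 when absent)."""
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, len(self.codes) - 1) if len(self.codes) else idx
        if len(self.codes) == 0:
            return np.zeros(len(codes), dtype=np.int64)
        hit = self.codes[idx] == codes
        out = np.where(hit, self.counts[idx], 0)
        return out


def build_kmer_table(readpairs: Sequence[ReadPair], k: int = 31) -> KmerTable:
    """Canonical k-mer count table over both mates of every pair.

    ``k`` must be odd (no k-mer is then its own reverse complement, so
    strand collapsing is unambiguous) and at most 31 (2-bit packing into
    a 64-bit word).  Depth estimation uses k around 15-31; tiny k is
    allowed for didactic examples.  Reads shorter than k contribute zero
    k-mers.
    """
    if k % 2 == 0 or not (3 <= k <= 31):
        raise ParameterError("k must be odd and within [3, 31]")
    chunks = []
    for pair in readpairs:
        chunks.append(_read_kmer_codes(pair.mate1, k))
        chunks.append(_read_kmer_codes(pair.mate2, k))
    if chunks:
        allcodes = np.concatenate(chunks)
    else:
        allcodes = np.empty(0, dtype=np.uint64)
    codes, counts = np.unique(allcodes, return_counts=True)
    return KmerTable(codes, counts.astype(np.int64), k)


def estimate_pair_depth(pair: ReadPair, table: KmerTable, k: Optional[int] = None) -> float:
    """Fold-coverage proxy for one pair: min over mates of the median
    k-mer count, corrected to base coverage.

    A position sequenced at depth d is covered by roughly d*(L-k+1)/L
    k-mer copies for reads of length L, so the median count is scaled by
    L/(L-k+1).  Returns 0 when both mates are shorter than k.
    """
    k = table.k if k is None else k
    estimates = []
    for mate in (pair.mate1, pair.mate2):
        codes = _read_kmer_codes(mate, k)
        if len(codes):
            scale = len(mate) / (len(mate) - k + 1)
            estimates.append(float(np.median(table.count(codes))) * scale)
    if not estimates:
        return 0.0
    return min(estimates)


def pair_depths(readpairs: Sequence[ReadPair], table: KmerTable) -> np.ndarray:
    """Vectorized :func:`estimate_pair_depth` over a read set."""
    return np.array([estimate_pair_depth(p, table) for p in readpairs])


def soft_cap(
    readpairs: Sequence[ReadPair],
    cap: CapLevel,
    k: int = 31,
    seed: int = 0,
    table: Optional[KmerTable] = None,
) -> list:
    """One-tailed down-sampling of read pairs to a target depth.

    Pairs with estimated depth d <= target are always retained; pairs
    above the target are retained independently with probability
    target/d.  Mates are kept or discarded together, input order is
    preserved, and the output is deterministic for a given seed.
    """
    readpairs = list(readpairs)
    if not readpairs:
        return []
    if table is None:
        table = build_kmer_table(readpairs, k)
    depths = pair_depths(readpairs, table)
    target = cap.target_depth
    rng = np.random.default_rng(seed)
    u = rng.random(len(readpairs))
    prob = np.where(depths > target, target / np.maximum(depths, 1e-300), 1.0)
    keep = u < prob
    keep |= depths <= target  # one-tailed guarantee, independent of u
    return [p for p, kf in zip(readpairs, keep) if kf]


def windowed_coverage(profile: CoverageProfile, window: int = 250) -> np.ndarray:
    """Mean depth in consecutive non-overlapping windows from position 0.

    The final partial window, if any, is averaged over its actual length.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    depth = profile.depth
    starts = np.arange(0, len(depth), window)
    sums = np.add.reduceat(depth, starts)
    sizes = np.minimum(starts + window, len(depth)) - starts
    return sums / sizes


def flag_low_windows(
    window_depths: np.ndarray, genome_wide_depth: float, fraction: float = 0.5
) -> np.ndarray:
    """Flag windows at or below ``fraction`` of the genome-wide depth.

    The bound is inclusive: a window at exactly 50% of the mean is
    flagged.
    """
    window_depths = np.asarray(window_depths, dtype=float)
    return window_depths <= fraction * genome_wide_depth


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the SNP/low-coverage co-localization test."""

    observed_fraction: Optional[float]
    p_value: Optional[float]
    n_snps: int
    applicable: bool


def snp_low_coverage_enrichment(
    snp_positions: Sequence[int],
    flags: np.ndarray,
    window: int,
    n_perm: int = 999,
    seed: int = 0,
    genome_length: Optional[int] = None,
) -> EnrichmentResult:
    """Permutation test for SNPs falling into low-coverage windows.

    The null hypothesis places SNPs uniformly over the genome; the
    p-value is (1 + #permutations with fraction >= observed)/(1+n_perm).
    This test is an add-on formalization of the visual association
    between SNP location and coverage dips; it is not itself a coverage
    statistic.
    """
    if n_perm < 999:
        raise ParameterError("n_perm must be >= 999")
    flags = np.asarray(flags, dtype=bool)
    snp_positions = np.asarray(list(snp_positions), dtype=np.int64)
    n = len(snp_positions)
    if n == 0:
        return EnrichmentResult(None, None, 0, applicable=False)
    if genome_length is None:
        genome_length = len(flags) * window
    obs = float(flags[snp_positions // window].mean())
    rng = np.random.default_rng(seed)
    perm_pos = rng.integers(0, genome_length, size=(n_perm, n))
    perm_frac = flags[perm_pos // window].mean(axis=1)
    p = (1 + int((perm_frac >= obs).sum())) / (1 + n_perm)
    return EnrichmentResult(obs, p, n, applicable=True)
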