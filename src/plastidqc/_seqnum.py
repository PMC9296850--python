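"""Numeric sequence utilities shared across modules.

DNA strings are kept as plain Python ``str``; these helpers provide fast
numpy encodings for k-mer and rolling-hash work.  Ambiguity codes (IUPAC)
are valid input everywhere but are encoded so that they never compare equal
to anything, including themselves, in exact-match contexts.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

#: prime modulus and base for polynomial rolling hashes (products of two
#: residues fit in uint64: (2**31)**2 < 2**64)
HASH_MOD = np.uint64(2_147_483_647)
HASH_BASE = np.uint64(1_000_003)


def revcomp(s: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return s.translate(_COMPLEMENT)[::-1]


def validate_dna(s: str, context: str = "sequence") -> None:
    from .errors import InputError

    bad = set(s.upper()) - DNA_ALPHABET
    if bad:
        raise InputError(f"non-DNA symbols in {context}: {sorted(bad)!r}")


def encode_bases(s: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and every other symbol as -1 (int64)."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return lut[arr]


def encode_unique_ambiguous(s: str, salt: int = 0) -> np.ndarray:
    """Encode bases 1..4; ambiguous positions get a unique value.

    The unique values depend on position and ``salt`` so that ambiguous
    symbols never match anything across two differently salted encodings.
    Output dtype uint64, all values already reduced modulo HASH_MOD.
    """
    base = encode_bases(s)
    out = (base + 1).astype(np.uint64)
    amb = base < 0
    if amb.any():
        idx = np.nonzero(amb)[0].astype(np.uint64)
        out[amb] = (np.uint64(5) + np.uint64(salt) + idx) % HASH_MOD
    return out


class WindowHasher:
    """Rolling hashes of all fixed-length windows of a value array.

    Precomputes doubling levels so that the hash of every window of an
    arbitrary length ``m`` can be produced with O(log m) vector operations.
    Used for exact inverted-repeat search where ``m`` is found by binary
    search.
    """

    def __init__(self, values: np.ndarray):
        self.n = len(values)
        self.levels = [values % HASH_MOD]
        self.pow2 = [HASH_BASE % HASH_MOD]  # p^(2^0)
        j = 0
        while (1 << (j + 1)) <= self.n:
            half = 1 << j
            prev = self.levels[j]
            p = self.pow2[j]
            nxt = (prev[: len(prev) - half] * p + prev[half:]) % HASH_MOD
            self.levels.append(nxt)
            self.pow2.append((p * p) % HASH_MOD)
            j += 1

    def window_hashes(self, m: int, n_windows: int) -> np.ndarray:
        """Hashes of windows [i, i+m) for i in range(n_windows)."""
        if m < 1 or n_windows + m > self.n + 1:
            raise ValueError("window request out of range")
        cur = None
        t = 0
        for j in range(len(self.levels) - 1, -1, -1):
            if not m & (1 << j):
                continue
            size = 1 << j
            block = self.levels[j][t : t + n_windows]
            if cur is None:
                cur = block.copy()
            else:
                cur = (cur * self.pow2[j] + block) % HASH_MOD
            t += size
        assert cur is not None
        return cur
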