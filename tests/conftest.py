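"""Shared fixtures: a desk-scale synthetic plastome and derived objects.

The small plastome (LSC 30 kb, IRs 9 kb, SSC 6 kb, 40 genes) keeps the
suite fast while preserving every structural property of the full-size
genome; module-scoped fixtures avoid recomputing the IR detection, which
dominates runtime.
"""

import numpy as np
import pytest

from plastidqc.simulate import PlastomeSpec, generate_plastome
from plastidqc.structure import detect_inverted_repeat

SMALL_SPEC = PlastomeSpec(lsc_len=30_000, ssc_len=6_000, ir_len=9_000, n_genes=40, seed=1)


@pytest.fixture(scope="session")
def small_plastome():
    return generate_plastome(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_partition(small_plastome):
    part = detect_inverted_repeat(small_plastome.genome)
    assert part is not None
    return part


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
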