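"""Finish a fragmented assembly into a circular genome.

Slices a synthetic plastome into six overlapping contigs (some
reverse-complemented, with a 40 bp duplicated endpoint), then runs the
finishing pipeline: filter short fragments, order against the structural
reference, merge exact overlaps of >= 15 bp, trim the duplicated
endpoint, circularize, and canonicalize.  The result is byte-identical
to the truth genome.
"""

import numpy as np

from plastidqc import canonicalize, detect_inverted_repeat
from plastidqc._seqnum import revcomp
from plastidqc.postprocess import (
    Contig,
    filter_short,
    merge_overlaps,
    order_contigs,
    trim_duplicate_endpoints,
)
from plastidqc.simulate import PlastomeSpec, generate_plastome

plastome = generate_plastome(
    PlastomeSpec(lsc_len=30_000, ssc_len=6_000, ir_len=9_000, n_genes=40, seed=1)
)
genome = plastome.genome

rng = np.random.default_rng(42)
lin = genome.residues + genome.residues[:40]  # 40 bp duplicated endpoint
cuts = sorted(int(c) for c in rng.choice(np.arange(2_000, len(lin) - 2_000), 5, replace=False))
pieces, prev = [], 0
for cut in cuts + [len(lin)]:
    start = max(0, prev - int(rng.integers(20, 200)))
    pieces.append(lin[start:cut])
    prev = cut
contigs = [Contig(f"c{i}", s if i % 2 == 0 else revcomp(s)) for i, s in enumerate(pieces)]
print(f"assembler output: {len(contigs)} contigs, "
      f"{min(len(c) for c in contigs):,}-{max(len(c) for c in contigs):,} bp")

ordered, unplaced = order_contigs(filter_short(contigs), genome)
merged = merge_overlaps(ordered)
print(f"after ordering and merging: {len(merged)} super-contig(s), {len(unplaced)} unplaced")

circular = trim_duplicate_endpoints(merged[0])
partition = detect_inverted_repeat(circular)
finished = canonicalize(circular, partition)
print(f"finished circular genome: {len(finished):,} bp")
print("byte-identical to truth:", finished.residues == genome.residues)
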